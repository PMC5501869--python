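"""Evidence engine: exact enumeration oracle, power-posterior sampler,
thermodynamic integration and posterior summaries."""

import numpy as np
import pytest
from scipy.special import expit

import rvbayes as rv
from rvbayes.exact import exact_log_evidence
from rvbayes.likelihood import baseline_log_evidence, conditional_log_likelihood
from rvbayes.likelihood import pathogenic_configurations
from rvbayes.mcmc import (
    MCMCSettings,
    TemperatureLadder,
    estimate_log_evidence,
    posterior_summaries,
    run_power_posterior,
)

from conftest import random_instance

DOM = rv.ModeOfInheritance.DOMINANT
REC = rv.ModeOfInheritance.RECESSIVE
HP = rv.Hyperparameters()


def _flat_instance(N=12, k=2):
    """No carriers at all: the likelihood is independent of z."""
    d = rv.GenotypeData(np.zeros((N, k), dtype=int), np.full(N, 2))
    y = rv.Phenotype(np.r_[np.ones(4, int), np.zeros(N - 4, int)])
    return d, y


class TestLadder:
    def test_endpoints_enforced(self):
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.1, 1.0]))
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.0, 0.5, 0.5, 1.0]))

    def test_default_concentrates_near_zero(self):
        t = TemperatureLadder.default().temperatures
        assert t[0] == 0.0 and t[-1] == 1.0
        assert np.all(np.diff(np.diff(t)) > 0)  # spacing widens toward t=1


class TestExactEvidence:
    def test_no_carriers_reduces_to_baseline(self):
        d, y = _flat_instance()
        hp = rv.Hyperparameters(tau_prior=(1, 1), tau0_prior=(1, 1))
        got = exact_log_evidence(d, y, None, DOM, hp)
        assert got == pytest.approx(baseline_log_evidence(y.y, (1, 1)), abs=1e-10)

    def test_stable_under_quadrature_refinement(self, rng):
        d, y = random_instance(rng, k=2, N=20, af=0.2)
        cd = rv.center_weights(rng.normal(size=2))
        coarse = exact_log_evidence(d, y, cd, DOM, HP, n_omega=48, n_phi=24)
        fine = exact_log_evidence(d, y, cd, DOM, HP, n_omega=96, n_phi=48)
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_case_carrier_beats_control_carrier(self):
        G = np.zeros((20, 1), dtype=int)
        G[0, 0] = 1
        d = rv.GenotypeData(G, np.full(20, 2))
        y_case = np.zeros(20, int)
        y_case[:5] = 1  # carrier (index 0) is a case
        y_ctrl = np.zeros(20, int)
        y_ctrl[1:6] = 1  # same case count, carrier is a control
        ev_case = exact_log_evidence(d, rv.Phenotype(y_case), None, DOM, HP)
        ev_ctrl = exact_log_evidence(d, rv.Phenotype(y_ctrl), None, DOM, HP)
        assert ev_case > ev_ctrl

    def test_k_guard(self):
        d = rv.GenotypeData(np.zeros((2, 21), dtype=int), np.array([2, 2]))
        with pytest.raises(ValueError, match="k <= 20"):
            exact_log_evidence(d, rv.Phenotype([1, 0]), None, DOM, HP)

    def test_uncarried_variant_leaves_evidence_unchanged(self, rng):
        """Appending an all-zero genotype column does not move the evidence."""
        d, y = random_instance(rng, k=2, N=30, af=0.2)
        ev = exact_log_evidence(d, None or None, None, DOM, HP) if False else (
            exact_log_evidence(d, y, None, DOM, HP)
        )
        G3 = np.column_stack([d.allele_counts, np.zeros(30, int)])
        d3 = rv.GenotypeData(G3, d.ploidy)
        ev3 = exact_log_evidence(d3, y, None, DOM, HP)
        assert ev3 == pytest.approx(ev, abs=1e-9)

    def test_penetrance_prior_concentration_raises_evidence(self, rng):
        """Sharper pi prior near 1 favours data where all carriers are cases."""
        G = rng.binomial(2, 0.2, size=(40, 2))
        while not G.any():
            G = rng.binomial(2, 0.2, size=(40, 2))
        d = rv.GenotypeData(G, np.full(40, 2))
        f = pathogenic_configurations(d, np.array([1, 1]), DOM)
        y = rv.Phenotype(np.where(f == 1, 1, (rng.random(40) < 0.2).astype(int)))
        weak = rv.Hyperparameters(pi_prior=(6, 1))
        sharp = rv.Hyperparameters(pi_prior=(60, 1))
        assert exact_log_evidence(d, y, None, DOM, sharp) > exact_log_evidence(
            d, y, None, DOM, weak
        )


class TestSampler:
    def test_fixed_seed_bit_identical(self, rng):
        d, y = random_instance(rng, k=3, N=50)
        s = MCMCSettings(100, 20, seed=11, ladder=TemperatureLadder.default(5))
        a = run_power_posterior(d, y, None, DOM, HP, s)
        b = run_power_posterior(d, y, None, DOM, HP, s)
        assert np.array_equal(a.log_likelihood, b.log_likelihood)
        assert np.array_equal(a.z_posterior, b.z_posterior)
        assert np.array_equal(a.phi, b.phi)

    def test_degenerate_phenotype_rejected(self):
        d = rv.GenotypeData(np.ones((3, 1), dtype=int), np.full(3, 2))
        with pytest.raises(ValueError, match="case and one control"):
            run_power_posterior(
                d, rv.Phenotype([1, 1, 1]), None, DOM, HP, MCMCSettings(10, 2)
            )

    def test_prior_recovery_at_zero_temperature(self, rng):
        """At t=0 the z marginals match the prior mean of expit(omega + phi c)."""
        d, y = random_instance(rng, k=3, N=40)
        cd = rv.center_weights([1.0, 0.0, 0.0])
        store = run_power_posterior(
            d, y, cd, DOM, HP,
            MCMCSettings(4000, 500, seed=5, ladder=TemperatureLadder.default(3)),
        )
        t0 = 0  # first rung has t = 0
        assert store.temperatures[t0] == 0.0
        om = store.omega[t0]
        ph = store.phi[t0]
        want = np.array(
            [expit(om + ph * c).mean() for c in cd.scaled_weights]
        )
        # z samples are only stored at t=1; use the analytic prior instead:
        # E[expit(omega + phi c_j)] under prior draws of (omega, phi)
        mu, s2 = HP.phi_lognormal_params
        g = np.random.default_rng(0)
        om_prior = np.log(g.beta(2, 8, 200000)) - np.log1p(-g.beta(2, 8, 200000))
        ph_prior = g.lognormal(mu, np.sqrt(s2), 200000)
        want_prior = np.array(
            [expit(om_prior + ph_prior * c).mean() for c in cd.scaled_weights]
        )
        np.testing.assert_allclose(want, want_prior, atol=0.02)

    def test_recorded_loglik_consistent_with_z_samples(self, rng):
        """The incrementally-maintained likelihood equals a full recomputation
        from the stored z samples at t=1."""
        d, y = random_instance(rng, k=4, N=60, mode=REC, af=0.15)
        store = run_power_posterior(
            d, y, None, REC, HP,
            MCMCSettings(50, 10, seed=3, ladder=TemperatureLadder.default(3)),
        )
        for s in range(0, 50, 7):
            z = store.z_posterior[s]
            f = pathogenic_configurations(d, z, REC)
            ll = conditional_log_likelihood(y.y, f, HP.tau_prior, HP.pi_prior)
            assert store.log_likelihood[-1, s] == pytest.approx(ll, abs=1e-9)
            assert store.explained_cases[-1, s] == (y.y * f).sum()


class TestEstimator:
    def test_constant_likelihood_recovered_exactly(self):
        d, y = _flat_instance()
        store = run_power_posterior(d, y, None, DOM, HP, MCMCSettings(50, 10, 1))
        est, se = estimate_log_evidence(store)
        assert se == 0.0
        assert est == pytest.approx(
            baseline_log_evidence(y.y, HP.tau_prior), abs=1e-12
        )

    def test_requires_two_rungs(self):
        d, y = _flat_instance()
        store = run_power_posterior(d, y, None, DOM, HP, MCMCSettings(20, 5, 1))
        store.temperatures = store.temperatures[:1]
        store.log_likelihood = store.log_likelihood[:1]
        with pytest.raises(ValueError):
            estimate_log_evidence(store)

    def test_matches_exact_oracle_small_k(self, rng):
        d, y = random_instance(rng, k=2, N=60)
        exact = exact_log_evidence(d, y, None, DOM, HP)
        store = run_power_posterior(
            d, y, None, DOM, HP, MCMCSettings(1500, 300, seed=9)
        )
        est, se = estimate_log_evidence(store)
        assert abs(est - exact) <= 3 * se + 1e-9

    def test_standard_error_shrinks_with_iterations(self, rng):
        d, y = random_instance(rng, k=3, N=80)
        ses = []
        for iters, seed_base in ((400, 0), (6400, 100)):
            vals = [
                estimate_log_evidence(
                    run_power_posterior(
                        d, y, None, DOM, HP, MCMCSettings(iters, 100, seed=s)
                    )
                )[1]
                for s in range(seed_base, seed_base + 3)
            ]
            ses.append(np.mean(vals))
        # 16x the iterations should shrink the SE by roughly 4x
        assert ses[1] < ses[0] / 2.0


class TestSummaries:
    def test_strong_single_variant_signal(self):
        """One variant carried by 8 cases and no controls: near-certain
        pathogenicity, ~8 cases explained (checked against k=1 enumeration)."""
        N = 1000
        G = np.zeros((N, 1), dtype=int)
        y = np.zeros(N, dtype=int)
        G[:8, 0] = 1
        y[:8] = 1
        d = rv.GenotypeData(G, np.full(N, 2))
        store = run_power_posterior(
            d, rv.Phenotype(y), None, DOM, HP, MCMCSettings(2000, 300, 2)
        )
        res = posterior_summaries(store, rv.Phenotype(y), d, DOM)
        # exact posterior inclusion at k=1 by enumeration over z in {0, 1}
        from scipy.special import logsumexp

        l1 = conditional_log_likelihood(y, (G[:, 0] > 0).astype(int),
                                        HP.tau_prior, HP.pi_prior)
        l0 = baseline_log_evidence(y, HP.tau_prior)
        # prior P(z=1) under the logit-beta(2, 8) intercept = E[expit(omega)]
        p1 = 0.2
        post = np.exp(l1 + np.log(p1) - logsumexp(
            [l1 + np.log(p1), l0 + np.log(1 - p1)]
        ))
        assert post > 0.99
        assert res.z_marginals[0] > 0.95
        assert res.expected_explained_cases == pytest.approx(8.0, abs=0.5)

    def test_all_zero_z_gives_zero_summaries(self):
        d, y = _flat_instance(N=20, k=3)
        # with a strong negative intercept and no signal z stays ~0 a.s.
        store = run_power_posterior(d, y, None, DOM, HP, MCMCSettings(100, 20, 4))
        res = posterior_summaries(store, y, d, DOM)
        assert res.expected_pathogenic_count == 0.0  # no variant is carried
        assert res.expected_explained_cases == 0.0

    def test_summaries_invariant_to_variant_permutation(self, rng):
        d, y = random_instance(rng, k=4, N=80)
        s = MCMCSettings(400, 100, 7)
        res = posterior_summaries(run_power_posterior(d, y, None, DOM, HP, s), y, d, DOM)
        perm = np.array([2, 0, 3, 1])
        d2 = rv.GenotypeData(d.allele_counts[:, perm], d.ploidy)
        res2 = posterior_summaries(
            run_power_posterior(d2, y, None, DOM, HP, s), y, d2, DOM
        )
        np.testing.assert_allclose(
            res2.z_marginals, res.z_marginals[perm], atol=0.06
        )
        assert res2.expected_explained_cases == pytest.approx(
            res.expected_explained_cases, abs=0.5
        )


def test_evidence_invariant_under_individual_permutation(rng):
    d, y = random_instance(rng, k=2, N=50)
    perm = rng.permutation(50)
    d2 = rv.GenotypeData(d.allele_counts[perm], d.ploidy[perm])
    y2 = rv.Phenotype(y.y[perm])
    a = exact_log_evidence(d, y, None, REC, HP)
    b = exact_log_evidence(d2, y2, None, REC, HP)
    assert a == pytest.approx(b, abs=1e-10)
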