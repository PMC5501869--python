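"""Synthetic case/control cohorts and the simulation study machinery.

The generator emulates a rare-disease cohort study design: allele counts at
k rare variant sites are drawn binomially at a fixed allele frequency (the
defaults are 0.0017 for dominant and 0.03 for recessive scenarios), the
first ``n_pathogenic`` variants are truly pathogenic, and case labels are
drawn with probability pi for individuals with a pathogenic configuration
and tau otherwise.  Null datasets are made by permuting the labels of an
associated dataset, which breaks the genotype-phenotype link while
preserving the case count.

The evaluation machinery ranks mixtures of associated and permuted
datasets and reports the mean positive predictive value (PPV) at a target
power, plus pooled ROC curves for variant-pathogenicity classification, a
co-data weighting grid and a Fisher's-exact-test comparator (CAST).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import fisher_exact

from .association import association_test
from .data import (
    CoData,
    GenotypeData,
    Hyperparameters,
    ModeOfInheritance,
    Phenotype,
)
from .likelihood import pathogenic_configurations
from .mcmc import MCMCSettings

DOMINANT_AF = 0.0017
RECESSIVE_AF = 0.03


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design.

    ``allele_frequency`` defaults to the mode-specific study value when not
    given: 0.0017 (dominant) or 0.03 (recessive).  The first
    ``n_pathogenic`` variants are truly pathogenic.
    """

    mode: ModeOfInheritance
    tau: float
    pi: float
    n_individuals: int = 1000
    n_variants: int = 25
    n_pathogenic: int = 5
    allele_frequency: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pi > self.tau:
            raise ValueError("pi must exceed tau")
        if self.n_pathogenic > self.n_variants:
            raise ValueError("n_pathogenic must not exceed n_variants")
        if self.allele_frequency is None:
            af = (
                DOMINANT_AF
                if self.mode is ModeOfInheritance.DOMINANT
                else RECESSIVE_AF
            )
            object.__setattr__(self, "allele_frequency", af)
        if not 0.0 < self.allele_frequency < 0.5:
            raise ValueError("allele_frequency must lie in (0, 0.5)")

    @property
    def z_true(self) -> np.ndarray:
        z = np.zeros(self.n_variants, dtype=np.int64)
        z[: self.n_pathogenic] = 1
        return z


def simulate_genotypes(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> GenotypeData:
    """Draw an allele-count matrix: each entry Binomial(2, allele_frequency)."""
    rng = rng or np.random.default_rng(scenario.seed)
    G = rng.binomial(
        2, scenario.allele_frequency, size=(scenario.n_individuals, scenario.n_variants)
    )
    return GenotypeData(G, np.full(scenario.n_individuals, 2))


def simulate_phenotype(
    data: GenotypeData,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> Phenotype:
    """Draw case labels: P(case) = pi given a pathogenic configuration, tau otherwise."""
    rng = rng or np.random.default_rng(scenario.seed + 1)
    f = pathogenic_configurations(data, scenario.z_true, scenario.mode)
    p = np.where(f == 1, scenario.pi, scenario.tau)
    return Phenotype((rng.random(data.n_individuals) < p).astype(np.int64))


def simulate_dataset(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[GenotypeData, Phenotype]:
    rng = rng or np.random.default_rng(scenario.seed)
    data = simulate_genotypes(scenario, rng)
    return data, simulate_phenotype(data, scenario, rng)


def permute_labels(
    y: Phenotype, seed: int | np.random.Generator = 0
) -> Phenotype:
    """Uniform random permutation of the labels; preserves the case count."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Phenotype(rng.permutation(y.y))


def ppv_at_power(
    scores_true,
    scores_null,
    power_level: float = 0.8,
    tie_order: np.ndarray | None = None,
) -> float:
    """Positive predictive value at the rank cutoff achieving a target power.

    All scores are ranked in descending order (ties broken deterministically
    by position in ``tie_order``, defaulting to input order with true
    datasets first); the smallest rank threshold recovering
    ceil(power_level * n_true) true datasets is found and PPV is the
    fraction of true datasets above it.  Equals 1 - FDR at that cutoff.
    """
    st = np.asarray(scores_true, dtype=float)
    sn = np.asarray(scores_null, dtype=float)
    if st.size == 0 or sn.size == 0:
        raise ValueError("score vectors must be non-empty")
    if not 0.0 < power_level <= 1.0:
        raise ValueError("power_level must lie in (0, 1]")
    scores = np.concatenate([st, sn])
    labels = np.concatenate([np.ones(st.size, bool), np.zeros(sn.size, bool)])
    order_key = np.arange(scores.size) if tie_order is None else np.asarray(tie_order)
    order = np.lexsort((order_key, -scores))
    need = math.ceil(power_level * st.size)
    cum_true = np.cumsum(labels[order])
    threshold = int(np.searchsorted(cum_true, need) + 1)  # 1-based rank
    return need / threshold


def cast_test(
    data: GenotypeData, y: Phenotype, mode: ModeOfInheritance
) -> float:
    """Two-sided Fisher's exact p value on collapsed carrier status.

    Carrier status is >= 1 rare allele across the locus under a dominant
    model and >= ploidy rare alleles under a recessive model.
    """
    totals = data.allele_counts.sum(axis=1)
    thr = 1 if mode is ModeOfInheritance.DOMINANT else data.ploidy
    carrier = totals >= thr
    yv = y.y.astype(bool)
    table = [
        [int(np.sum(carrier & yv)), int(np.sum(carrier & ~yv))],
        [int(np.sum(~carrier & yv)), int(np.sum(~carrier & ~yv))],
    ]
    if carrier.all() or not carrier.any() or yv.all() or not yv.any():
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def variant_classification_roc(
    marginals, truth
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoidal AUC over pooled (marginal, truth) pairs.

    Scores tied at the same value move along the curve together (one ROC
    vertex per distinct score), so ties cost diagonal segments rather than
    arbitrary orderings.
    """
    s = np.asarray(marginals, dtype=float).ravel()
    t = np.asarray(truth, dtype=bool).ravel()
    if t.all() or not t.any():
        raise ValueError("truth must contain both classes")
    order = np.argsort(-s, kind="stable")
    s, t = s[order], t[order]
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(t)[idx]
    fps = np.cumsum(~t)[idx]
    tpr = np.r_[0.0, tps / t.sum()]
    fpr = np.r_[0.0, fps / (~t).sum()]
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def roc_tpr_at_fpr(fpr: np.ndarray, tpr: np.ndarray, at: float) -> float:
    """Linear interpolation of the ROC at a given false positive rate."""
    return float(np.interp(at, fpr, tpr))


# ---------------------------------------------------------------------------
# scoring and mixture machinery


def bayes_score(
    data: GenotypeData,
    y: Phenotype,
    codata: CoData | None,
    hp: Hyperparameters,
    settings: MCMCSettings,
):
    """Posterior probability of association (and the full locus result)."""
    res = association_test(data, y, codata=codata, hp=hp, settings=settings)
    return res.prob_association, res


def cast_score(data: GenotypeData, y: Phenotype, mode: ModeOfInheritance) -> float:
    """Negative log p value from the CAST comparator, for ranking."""
    p = cast_test(data, y, mode)
    return -math.log(max(p, 1e-300))


@dataclass
class ScorePools:
    """Scored pools of associated and label-permuted datasets."""

    assoc_scores: np.ndarray
    null_scores: np.ndarray
    assoc_extras: list  # per-dataset LocusResult or None


def build_score_pools(
    scenario: SimulationScenario,
    n_assoc: int,
    n_null: int,
    method: str = "bayes",
    codata_raw=None,
    hp: Hyperparameters | None = None,
    settings: MCMCSettings | None = None,
    seed: int = 0,
    keep_extras: bool = False,
    match_mode: bool = True,
) -> ScorePools:
    """Generate and score pools of associated and permuted datasets.

    Each pool entry is an independently simulated dataset; null entries are
    permuted-label copies of further independent datasets.  ``method`` is
    "bayes" (posterior probability of association) or "cast" (negative log
    Fisher p, with the collapsing rule matched to the scenario mode).

    By default the Bayesian score conditions on the scenario's inheritance
    mode (``match_mode``), mirroring an evaluation design with separate
    dominant and recessive panels; pass ``match_mode=False`` to integrate
    over modes with the prior in ``hp``.
    """
    hp = hp or Hyperparameters()
    if match_mode and method == "bayes":
        hp = replace(
            hp,
            p_dominant_given_assoc=(
                1.0 if scenario.mode is ModeOfInheritance.DOMINANT else 0.0
            ),
        )
    settings = settings or MCMCSettings()
    rng = np.random.default_rng(seed)
    codata = None if codata_raw is None else CoData(np.asarray(codata_raw, float))

    def score_one(permute: bool):
        data, y = simulate_dataset(
            replace(scenario, seed=int(rng.integers(2**31))), rng
        )
        if permute:
            y = permute_labels(y, rng)
        if method == "bayes":
            run_settings = replace(settings, seed=int(rng.integers(2**31)))
            s, res = bayes_score(data, y, codata, hp, run_settings)
            return s, (res if keep_extras else None)
        if method == "cast":
            return cast_score(data, y, scenario.mode), None
        raise ValueError(f"unknown method {method!r}")

    assoc = [score_one(False) for _ in range(n_assoc)]
    null = [score_one(True) for _ in range(n_null)]
    return ScorePools(
        assoc_scores=np.array([a[0] for a in assoc]),
        null_scores=np.array([a[0] for a in null]),
        assoc_extras=[a[1] for a in assoc],
    )


def mixture_ppv(
    pools: ScorePools,
    n_true: int = 10,
    n_null: int = 990,
    n_repetitions: int = 100,
    power_level: float = 0.8,
    seed: int = 0,
) -> float:
    """Mean PPV at the target power over repeated random mixtures.

    Each repetition draws ``n_true`` associated and ``n_null`` permuted
    scores from the pools (with replacement when a pool is smaller than the
    draw) and ranks them together; ties are broken by a random but seeded
    mixture order.
    """
    rng = np.random.default_rng(seed)

    def draw(pool: np.ndarray, m: int) -> np.ndarray:
        return rng.choice(pool, size=m, replace=pool.size < m)

    ppvs = np.empty(n_repetitions)
    for r in range(n_repetitions):
        st = draw(pools.assoc_scores, n_true)
        sn = draw(pools.null_scores, n_null)
        tie = rng.permutation(n_true + n_null)
        ppvs[r] = ppv_at_power(st, sn, power_level, tie_order=tie)
    return float(ppvs.mean())


def codata_cell(
    n_path_up: int,
    n_nonpath_up: int,
    scenario: SimulationScenario,
) -> np.ndarray:
    """Binary raw weights for one cell of the co-data weighting grid.

    ``n_path_up`` of the pathogenic and ``n_nonpath_up`` of the
    non-pathogenic variants receive raw weight 1, the rest 0.
    """
    if n_path_up > scenario.n_pathogenic:
        raise ValueError("cannot up-weight more pathogenic variants than exist")
    if n_nonpath_up > scenario.n_variants - scenario.n_pathogenic:
        raise ValueError("cannot up-weight more non-pathogenic variants than exist")
    w = np.zeros(scenario.n_variants)
    w[:n_path_up] = 1.0
    w[scenario.n_pathogenic : scenario.n_pathogenic + n_nonpath_up] = 1.0
    return w


def codata_grid_experiment(
    scenario: SimulationScenario,
    cells: list[tuple[int, int]] | None = None,
    n_assoc: int = 50,
    n_null: int = 200,
    n_repetitions: int = 100,
    hp: Hyperparameters | None = None,
    settings: MCMCSettings | None = None,
    seed: int = 0,
) -> list[dict]:
    """PPV at 80% power and posterior mean of phi per co-data grid cell.

    The full design varies the number of up-weighted pathogenic variants
    over 0..5 and of up-weighted non-pathogenic variants over 0..20 in
    steps of 4; ``cells`` selects a subset of (n_path_up, n_nonpath_up)
    pairs to run.
    """
    if cells is None:
        cells = [(p, q) for p in range(6) for q in range(0, 21, 4)]
    out = []
    for idx, (p_up, q_up) in enumerate(cells):
        w = codata_cell(p_up, q_up, scenario)
        pools = build_score_pools(
            scenario,
            n_assoc,
            n_null,
            method="bayes",
            codata_raw=w,
            hp=hp,
            settings=settings,
            seed=seed + 7919 * idx,
            keep_extras=True,
        )
        ppv = mixture_ppv(
            pools, n_repetitions=n_repetitions, seed=seed + 7919 * idx + 1
        )
        mode_key = (
            "dominant" if scenario.mode is ModeOfInheritance.DOMINANT
            else "recessive"
        )
        phis = [
            r.per_model[0]["results"][mode_key].posterior_mean_phi
            for r in pools.assoc_extras
            if r is not None
        ]
        out.append(
            {
                "n_path_up": p_up,
                "n_nonpath_up": q_up,
                "ppv": ppv,
                "mean_phi": float(np.mean(phis)),
            }
        )
    return out


__all__ = [
    "SimulationScenario",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "permute_labels",
    "ppv_at_power",
    "cast_test",
    "cast_score",
    "bayes_score",
    "variant_classification_roc",
    "roc_tpr_at_fpr",
    "ScorePools",
    "build_score_pools",
    "mixture_ppv",
    "codata_cell",
    "codata_grid_experiment",
    "DOMINANT_AF",
    "RECESSIVE_AF",
]
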