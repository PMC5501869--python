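"""Exact evidence for small numbers of variants, by enumeration + quadrature.

The association-model evidence is a sum over all 2^k pathogenicity
indicator vectors z, integrated over the intercept omega and the co-data
coefficient phi.  For small k the sum can be enumerated and the 2-D
integral evaluated by Gaussian quadrature, giving an independent check for
the tempered-MCMC estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from .data import CoData, GenotypeData, Hyperparameters, ModeOfInheritance, Phenotype
from .likelihood import conditional_log_likelihood, pathogenic_configurations

_MAX_K = 20


def _enumerate_z(k: int) -> np.ndarray:
    bits = np.arange(2**k, dtype=np.int64)
    return ((bits[:, None] >> np.arange(k)) & 1).astype(np.int64)


def exact_log_evidence(
    data: GenotypeData,
    y: Phenotype,
    codata: CoData | None,
    mode: ModeOfInheritance,
    hp: Hyperparameters,
    n_omega: int = 48,
    n_phi: int = 24,
) -> float:
    """Log evidence under the association model, exactly (small k only).

    Enumerates all 2^k values of z, computes the conjugate marginal
    likelihood for each, and integrates the z-prior over omega (Gauss-
    Legendre on the Beta scale) and phi (Gauss-Hermite on the log scale).

    Parameters ``n_omega`` and ``n_phi`` set the quadrature orders; the
    result is stable to refinement well below 1e-6 at the defaults.
    """
    k = data.n_variants
    if k > _MAX_K:
        raise ValueError(f"exact evidence requires k <= {_MAX_K}, got {k}")
    c = np.zeros(k) if codata is None else codata.scaled_weights
    if c.size != k:
        raise ValueError("codata length must match number of variants")

    Z = _enumerate_z(k)
    loglik = np.array(
        [
            conditional_log_likelihood(
                y.y,
                pathogenic_configurations(data, z, mode),
                hp.tau_prior,
                hp.pi_prior,
            )
            for z in Z
        ]
    )

    # omega nodes: expit(omega) ~ Beta(a, b), integrate over q in (0, 1)
    a_om, b_om = hp.omega_prior
    xq, wq = np.polynomial.legendre.leggauss(n_omega)
    q = 0.5 * (xq + 1.0)
    log_wq = np.log(wq * 0.5) + beta_dist.logpdf(q, a_om, b_om)
    omega_nodes = np.log(q) - np.log1p(-q)

    # phi nodes: log(phi) ~ Normal(mu, sigma2), Gauss-Hermite
    mu, sigma2 = hp.phi_lognormal_params
    xh, wh = np.polynomial.hermite.hermgauss(n_phi)
    phi_nodes = np.exp(mu + np.sqrt(2.0 * sigma2) * xh)
    log_wh = np.log(wh) - 0.5 * np.log(np.pi)

    # eta[node, j] for the full (omega, phi) product grid
    om_grid = np.repeat(omega_nodes, n_phi)
    ph_grid = np.tile(phi_nodes, n_omega)
    log_w = (np.repeat(log_wq, n_phi) + np.tile(log_wh, n_omega))
    eta = om_grid[:, None] + ph_grid[:, None] * c[None, :]

    # log p(z | node) = z . eta - sum_j log(1 + exp(eta_j))
    norm = np.sum(np.logaddexp(0.0, eta), axis=1)
    log_inner = logsumexp(loglik[:, None] + Z @ eta.T - norm[None, :], axis=0)
    return float(logsumexp(log_inner + log_w))


__all__ = ["exact_log_evidence"]
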