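"""Closed-form probability computations of the association model.

Under the baseline model every individual is a case with probability tau0.
Under an association model an individual is a case with probability pi if
they carry a pathogenic configuration of alleles (as judged by the latent
indicator vector z and the mode of inheritance) and tau otherwise.  All risk
parameters carry conjugate Beta priors, so the likelihood of the labels
given z marginalises to a product of beta-binomial factors.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, expit, log_expit

from .data import CoData, GenotypeData, ModeOfInheritance


def pathogenic_configuration(
    genotype_row,
    z,
    ploidy: int,
    mode: ModeOfInheritance,
    phase: tuple | None = None,
) -> int:
    """Whether one individual's genotypes form a pathogenic configuration.

    Dominant: at least one pathogenic allele.  Recessive: at least ``ploidy``
    pathogenic alleles; if ``phase`` (a pair of haplotype allele-count
    vectors) is given, the pathogenic alleles must additionally fall on
    distinct haplotypes, which excludes e.g. two variants in cis.
    """
    g = np.asarray(genotype_row, dtype=np.int64)
    zv = np.asarray(z, dtype=np.int64)
    if g.shape != zv.shape:
        raise ValueError("genotype row and z must have equal length")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    total = int(g @ zv)
    if mode is ModeOfInheritance.DOMINANT:
        return int(total >= 1)
    if phase is not None:
        h1 = np.asarray(phase[0], dtype=np.int64)
        h2 = np.asarray(phase[1], dtype=np.int64)
        if ((h1 + h2) != g).any():
            raise ValueError("phase inconsistent with allele counts")
        if ploidy == 1:
            return int(total >= 1)
        return int(int(h1 @ zv) >= 1 and int(h2 @ zv) >= 1)
    return int(total >= ploidy)


def pathogenic_configurations(
    data: GenotypeData, z, mode: ModeOfInheritance
) -> np.ndarray:
    """Vectorised pathogenic-configuration indicator over all individuals."""
    zv = np.asarray(z, dtype=np.int64)
    totals = data.allele_counts @ zv
    if mode is ModeOfInheritance.DOMINANT:
        return (totals >= 1).astype(np.int64)
    if data.phase is not None:
        h1 = data.phase[0] @ zv
        h2 = data.phase[1] @ zv
        diploid = (h1 >= 1) & (h2 >= 1)
        return np.where(data.ploidy == 1, totals >= 1, diploid).astype(np.int64)
    return (totals >= data.ploidy).astype(np.int64)


def _log_beta_binomial(successes: int, trials: int, alpha: float, beta: float) -> float:
    # marginal of a Bernoulli sequence under a conjugate Beta prior
    return float(
        betaln(alpha + successes, beta + trials - successes) - betaln(alpha, beta)
    )


def baseline_log_evidence(y, tau0_prior: tuple[float, float]) -> float:
    """Log marginal likelihood of the labels under the baseline model.

    The Bernoulli(tau0) likelihood integrates against Beta(alpha0, beta0) to
    B(alpha0 + sum(y), beta0 + N - sum(y)) / B(alpha0, beta0).
    """
    y = np.asarray(y, dtype=np.int64)
    return _log_beta_binomial(int(y.sum()), y.size, *tau0_prior)


def conditional_log_likelihood(y, f, tau_prior, pi_prior) -> float:
    """Log p(y | z, m) with tau and pi integrated out by conjugacy.

    Individuals split by their pathogenic-configuration indicator f: the
    f=0 stratum integrates against Beta(tau_prior), the f=1 stratum against
    Beta(pi_prior); each contributes a beta-binomial factor.
    """
    y = np.asarray(y, dtype=np.int64)
    f = np.asarray(f, dtype=np.int64)
    if y.shape != f.shape:
        raise ValueError("y and f must have equal length")
    n1 = int(f.sum())
    y1 = int(y[f == 1].sum())
    return _log_beta_binomial(
        int(y.sum()) - y1, y.size - n1, *tau_prior
    ) + _log_beta_binomial(y1, n1, *pi_prior)


def log_prior_z(z, omega: float, phi: float, codata: CoData | None) -> float:
    """Log prior of the pathogenicity indicators given omega, phi.

    Independent Bernoulli components with logit p_j = omega + phi * c_j,
    where c are the standardized (centered, unit-variance) weights.
    """
    z = np.asarray(z, dtype=np.int64)
    c = np.zeros(z.size) if codata is None else codata.scaled_weights
    if c.size != z.size:
        raise ValueError("codata length must match z")
    eta = omega + phi * c
    # z*log(p) + (1-z)*log(1-p) = z*eta - log(1 + exp(eta)), stably
    return float(np.sum(z * eta + log_expit(-eta)))


def log_prior_omega(omega: float, omega_prior: tuple[float, float]) -> float:
    """Log density of the logit-beta prior on omega.

    expit(omega) ~ Beta(a, b); the change of variables contributes the
    Jacobian expit(omega) * (1 - expit(omega)).
    """
    a, b = omega_prior
    if a <= 0 or b <= 0:
        raise ValueError("omega prior shapes must be positive")
    # Beta log-density at expit(omega) plus log Jacobian, all via log_expit
    return float(
        a * log_expit(omega) + b * log_expit(-omega) - betaln(a, b)
    )


def log_prior_phi(phi: float, mean: float, variance: float) -> float:
    """Log density of the log-normal prior on phi.

    Parameterised by the mean and variance of phi itself: sigma^2 =
    log(1 + variance / mean^2), mu = log(mean) - sigma^2 / 2.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    sigma2 = np.log1p(variance / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    lphi = np.log(phi)
    return float(
        -0.5 * np.log(2.0 * np.pi * sigma2) - lphi - (lphi - mu) ** 2 / (2.0 * sigma2)
    )


__all__ = [
    "pathogenic_configuration",
    "pathogenic_configurations",
    "baseline_log_evidence",
    "conditional_log_likelihood",
    "log_prior_z",
    "log_prior_omega",
    "log_prior_phi",
]
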