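"""Core domain containers for rare-variant association testing.

The model works on an N x k matrix of rare-variant allele counts (0/1/2), a
per-individual ploidy vector (2 for autosomes and the female X, 1 for the
male X outside the pseudoautosomal regions), a binary case/control phenotype
and, optionally, per-variant "co-data" weights carrying prior information on
pathogenicity.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np


class ModeOfInheritance(enum.Enum):
    """Mode of inheritance at a locus.

    Dominant: one pathogenic allele suffices for a pathogenic configuration.
    Recessive: the individual needs as many pathogenic alleles as their
    ploidy (two on autosomes, one for hemizygous males on the X), which
    covers homozygous, compound-heterozygous and X-linked inheritance.
    """

    DOMINANT = "dominant"
    RECESSIVE = "recessive"


@dataclass(frozen=True)
class GenotypeData:
    """Rare-variant allele counts for N individuals at k variant sites.

    Parameters
    ----------
    allele_counts
        Integer matrix of shape (N, k) with entries in {0, 1, 2}; missing
        genotypes must be imputed (to 0) before construction.
    ploidy
        Integer vector of length N with entries in {1, 2}.
    variant_ids
        Optional identifiers, length k.
    phase
        Optional pair of (N, k) haplotype allele-count matrices summing to
        ``allele_counts``; used by the recessive configuration rule to
        require pathogenic alleles on distinct haplotypes.
    """

    allele_counts: np.ndarray
    ploidy: np.ndarray
    variant_ids: tuple[str, ...] = ()
    phase: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        G = np.asarray(self.allele_counts)
        if G.ndim != 2 or G.shape[0] < 1 or G.shape[1] < 1:
            raise ValueError("allele_counts must be a non-empty N x k matrix")
        if np.ma.isMaskedArray(G) or np.issubdtype(G.dtype, np.floating):
            Gf = np.asarray(G, dtype=float)
            if np.isnan(Gf).any():
                warnings.warn(
                    "missing genotypes imputed to 0 (homozygous reference)",
                    stacklevel=2,
                )
                Gf = np.nan_to_num(Gf, nan=0.0)
            if not np.all(Gf == np.round(Gf)):
                raise ValueError("allele counts must be integers")
            G = Gf.astype(np.int64)
        else:
            G = G.astype(np.int64)
        s = np.asarray(self.ploidy, dtype=np.int64)
        if s.shape != (G.shape[0],):
            raise ValueError("ploidy must be a vector of length N")
        if not np.isin(s, (1, 2)).all():
            raise ValueError("ploidy entries must be 1 or 2")
        if G.min() < 0 or (G > s[:, None]).any():
            raise ValueError("allele counts must lie in [0, ploidy]")
        object.__setattr__(self, "allele_counts", G)
        object.__setattr__(self, "ploidy", s)
        if self.variant_ids:
            if len(self.variant_ids) != G.shape[1]:
                raise ValueError("variant_ids length must equal k")
            object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        else:
            object.__setattr__(
                self, "variant_ids", tuple(f"v{j}" for j in range(G.shape[1]))
            )
        if self.phase is not None:
            h1 = np.asarray(self.phase[0], dtype=np.int64)
            h2 = np.asarray(self.phase[1], dtype=np.int64)
            if h1.shape != G.shape or h2.shape != G.shape:
                raise ValueError("phase matrices must match allele_counts shape")
            if ((h1 + h2) != G).any() or h1.min() < 0 or h2.min() < 0:
                raise ValueError("phase matrices are inconsistent with allele counts")
            object.__setattr__(self, "phase", (h1, h2))

    @property
    def n_individuals(self) -> int:
        return self.allele_counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.allele_counts.shape[1]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeData":
        """Restrict to the variant columns selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        phase = None
        if self.phase is not None:
            phase = (self.phase[0][:, mask], self.phase[1][:, mask])
        ids = tuple(v for v, m in zip(self.variant_ids, mask) if m)
        return GenotypeData(self.allele_counts[:, mask], self.ploidy, ids, phase)


@dataclass(frozen=True)
class Phenotype:
    """Binary case (1) / control (0) labels of length N."""

    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.int64)
        if y.ndim != 1 or y.size < 1:
            raise ValueError("y must be a non-empty vector")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y entries must be 0 or 1")
        object.__setattr__(self, "y", y)

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_individuals(self) -> int:
        return self.y.size


@dataclass(frozen=True)
class CoData:
    """Per-variant prior weights: raw, mean-centered and standardized.

    Centering makes the intercept of the pathogenicity regression
    interpretable as the global mean log-odds of pathogenicity, so the
    weights act as prior shifts in log-odds relative to that mean.  The
    regression itself consumes the standardized weights (centered and
    scaled to unit variance), which keeps the coefficient phi on a common
    scale across weighting schemes; constant weights standardize to zero
    and carry no discriminating information.
    """

    raw_weights: np.ndarray
    centered_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    scaled_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_weights, dtype=float)
        if raw.ndim != 1 or raw.size < 1:
            raise ValueError("weights must be a non-empty vector")
        if not np.isfinite(raw).all():
            raise ValueError("weights must be finite")
        centered = raw - raw.mean()
        sd = centered.std()
        scaled = centered / sd if sd > 0 else np.zeros_like(centered)
        object.__setattr__(self, "raw_weights", raw)
        object.__setattr__(self, "centered_weights", centered)
        object.__setattr__(self, "scaled_weights", scaled)

    @property
    def k(self) -> int:
        return self.raw_weights.size


def center_weights(raw_weights) -> CoData:
    """Center raw co-data weights to sum to zero, preserving order."""
    return CoData(np.asarray(raw_weights, dtype=float))


@dataclass(frozen=True)
class PathogenicityState:
    """A point in the latent space: variant indicators and regression terms.

    ``z`` flags which variants are pathogenic; ``omega`` is the global mean
    log-odds of pathogenicity and ``phi`` the (positive) coefficient scaling
    the centered co-data.
    """

    z: np.ndarray
    omega: float
    phi: float

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.int64)
        if not np.isin(z, (0, 1)).all():
            raise ValueError("z entries must be 0 or 1")
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters of the association and baseline models.

    Defaults: uniform Beta(1,1) priors on the baseline risk tau0 and the
    non-carrier risk tau; Beta(6,1) on the carrier risk pi (mean 6/7,
    reflecting high penetrance of pathogenic configurations); logit-Beta(2,8)
    on omega (prior expectation that 20% of variants are pathogenic, with
    only 1% prior mass on the proportion exceeding 0.54); log-normal prior on
    phi with mean 1 and variance 0.35; equal prior odds on dominant vs
    recessive inheritance; prior probability of association 0.01.
    """

    tau0_prior: tuple[float, float] = (1.0, 1.0)
    tau_prior: tuple[float, float] = (1.0, 1.0)
    pi_prior: tuple[float, float] = (6.0, 1.0)
    omega_prior: tuple[float, float] = (2.0, 8.0)
    phi_prior_mean: float = 1.0
    phi_prior_variance: float = 0.35
    p_dominant_given_assoc: float = 0.5
    p_association: float = 0.01

    def __post_init__(self) -> None:
        for pair in (self.tau0_prior, self.tau_prior, self.pi_prior, self.omega_prior):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("Beta shape parameters must be positive")
        if self.phi_prior_mean <= 0 or self.phi_prior_variance <= 0:
            raise ValueError("phi prior moments must be positive")
        for p in (self.p_dominant_given_assoc, self.p_association):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def phi_lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma^2) of log(phi) matching the stated mean and variance."""
        m, v = self.phi_prior_mean, self.phi_prior_variance
        sigma2 = np.log1p(v / m**2)
        mu = np.log(m) - sigma2 / 2.0
        return float(mu), float(sigma2)
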