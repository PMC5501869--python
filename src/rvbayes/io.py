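"""File-format ingestion and variant-class model configuration.

Inputs are a VCF with GT fields, a sample sheet (TSV: sample id,
case/control status, sex) and a variant-class table assigning each variant
to annotation classes from {high, moderate, utr5, utr3}.  Frequency and
consequence filtering is assumed to have happened upstream; the class
table is taken as given.  Only unrelated individuals should be included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combine import AssociationModel, AssociationModelSet
from .data import CoData, GenotypeData, Hyperparameters, Phenotype

CLASS_NAMES = ("high", "moderate", "utr5", "utr3")
DEFAULT_CODING_PRIORS = {"high": 0.004, "moderate": 0.003, "utr5": 0.002, "utr3": 0.001}
DEFAULT_NONCODING_MODERATE_PRIOR = 0.01

# GRCh38 X-chromosome pseudoautosomal regions (1-based inclusive)
_PAR = ((10001, 2781479), (155701383, 156030895))


@dataclass(frozen=True)
class LocusDefinition:
    """A locus's variants with their annotation-class memberships."""

    locus_id: str
    variant_ids: tuple[str, ...]
    classes: tuple[frozenset, ...]  # per variant, subset of CLASS_NAMES
    coding: bool = True
    class_priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.variant_ids) != len(self.classes):
            raise ValueError("one class set required per variant")
        for cs in self.classes:
            if not cs <= set(CLASS_NAMES):
                raise ValueError(f"unknown variant class in {set(cs)}")
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(
            self, "classes", tuple(frozenset(c) for c in self.classes)
        )


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV with columns sample_id, status (case/control/1/0), sex (M/F)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "status"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    status = df["status"].str.lower().map(
        {"case": 1, "control": 0, "1": 1, "0": 0}
    )
    if status.isna().any():
        raise ValueError("status entries must be case/control or 1/0")
    df["y"] = status.astype(int)
    if "sex" in df.columns:
        sex = df["sex"].str.upper().map({"M": "M", "MALE": "M", "1": "M",
                                         "F": "F", "FEMALE": "F", "2": "F"})
        if sex.isna().any():
            raise ValueError("sex entries must be M/F")
        df["sex"] = sex
    else:
        df["sex"] = "F"
    return df.set_index("sample_id")


def _is_x(chrom: str) -> bool:
    return chrom.lstrip("chr").upper() == "X"


def _in_par(pos: int) -> bool:
    return any(lo <= pos <= hi for lo, hi in _PAR)


def read_genotypes(
    vcf_path,
    sample_sheet,
    variant_ids: list[str] | None = None,
    region: str | None = None,
) -> tuple[GenotypeData, Phenotype]:
    """Read allele counts per variant per sample from a VCF.

    Variant identifiers are "CHROM:POS:REF:ALT" (or the VCF ID if set); a
    ``variant_ids`` list restricts to the matching records.  Multiallelic
    records must be split upstream and are rejected.  Males are treated as
    haploid at X variants outside the pseudoautosomal regions: their
    allele count is 1 if they carry any alternate allele.  Missing
    genotypes are imputed to homozygous reference with a warning.
    """
    from cyvcf2 import VCF

    sheet = sample_sheet if isinstance(sample_sheet, pd.DataFrame) else (
        read_sample_sheet(sample_sheet)
    )
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sheet.index]
    if missing:
        raise ValueError(f"samples in VCF absent from sheet: {missing[:5]}")
    male = sheet.loc[samples, "sex"].values == "M"
    y = sheet.loc[samples, "y"].values.astype(np.int64)

    wanted = None if variant_ids is None else set(variant_ids)
    cols, ids, is_x_nonpar = [], [], []
    any_missing = False
    for v in vcf(region) if region else vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS}; split upstream"
            )
        vid = v.ID if v.ID not in (None, ".") else (
            f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        )
        if wanted is not None and vid not in wanted:
            continue
        hemi = _is_x(v.CHROM) and not _in_par(v.POS)
        counts = np.zeros(len(samples), dtype=np.int64)
        for i, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1] if a != -2]  # -2 pads haploid calls
            if any(a == -1 for a in alleles):
                any_missing = True
                alleles = [0 if a == -1 else a for a in alleles]
            n_alt = sum(1 for a in alleles if a > 0)
            if hemi and male[i]:
                n_alt = min(n_alt, 1)
            counts[i] = n_alt
        cols.append((counts, hemi))
        ids.append(vid)
    if any_missing:
        warnings.warn("missing GT calls imputed to homozygous reference")
    if not cols:
        raise ValueError("no variants read from VCF")
    if wanted is not None:
        absent = wanted - set(ids)
        if absent:
            raise ValueError(f"variants not found in VCF: {sorted(absent)[:5]}")
        order = [ids.index(v) for v in variant_ids]
        cols = [cols[i] for i in order]
        ids = [ids[i] for i in order]
    G = np.column_stack([c for c, _ in cols])
    # ploidy is a per-individual property of the locus: 1 for males when any
    # variant is X non-PAR (mixed autosome/X loci are not supported)
    hemi_flags = {h for _, h in cols}
    if len(hemi_flags) > 1:
        raise ValueError("locus mixes X non-PAR and diploid variants")
    ploidy = np.where(male & hemi_flags.pop(), 1, 2).astype(np.int64)
    data = GenotypeData(np.minimum(G, ploidy[:, None]), ploidy, tuple(ids))
    return data, Phenotype(y)


def read_variant_classes(path) -> pd.DataFrame:
    """TSV with columns locus_id, variant_id, classes (comma-separated),
    and optionally coding (1/0)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"locus_id", "variant_id", "classes"}
    if not need <= set(df.columns):
        raise ValueError(f"variant table must have columns {sorted(need)}")
    return df


def loci_from_table(df: pd.DataFrame) -> list[LocusDefinition]:
    out = []
    for locus_id, sub in df.groupby("locus_id", sort=True):
        coding = True
        if "coding" in sub.columns:
            coding = sub["coding"].iloc[0] in ("1", "true", "True")
        classes = [
            frozenset(s.strip() for s in cs.split(",") if s.strip())
            for cs in sub["classes"]
        ]
        out.append(
            LocusDefinition(
                locus_id=str(locus_id),
                variant_ids=tuple(sub["variant_id"]),
                classes=tuple(classes),
                coding=coding,
            )
        )
    return out


def build_model_set(
    locus: LocusDefinition, hp: Hyperparameters | None = None
) -> AssociationModelSet:
    """One association model per non-empty annotation class of the locus.

    Coding loci get class priors 0.004 (high), 0.003 (moderate), 0.002
    (5' UTR), 0.001 (3' UTR); non-coding loci get a single moderate-class
    model with prior 0.01, so the total prior probability of association is
    0.01 either way.  The high-class model uses a logit-Beta(2, 1) prior on
    the pathogenicity intercept (most high-impact variants are expected
    pathogenic); the moderate-class model up-weights variants that are also
    in the high class through binary co-data.
    """
    hp = hp or Hyperparameters()
    k = len(locus.variant_ids)
    if k == 0:
        raise ValueError("empty locus")
    members = {
        name: np.array([name in cs for cs in locus.classes]) for name in CLASS_NAMES
    }
    if locus.coding:
        priors = dict(DEFAULT_CODING_PRIORS)
        class_order = CLASS_NAMES
    else:
        priors = {"moderate": DEFAULT_NONCODING_MODERATE_PRIOR}
        class_order = ("moderate",)
    priors.update(locus.class_priors)
    total = sum(priors[c] for c in class_order if members.get(c, np.zeros(k, bool)).any())
    if total > 0.05:
        warnings.warn(
            f"total prior probability of association {total:.3g} exceeds 0.05; "
            "locus rankings assume consistent priors"
        )
    models = []
    for name in class_order:
        inc = members.get(name)
        if inc is None or not inc.any():
            continue
        model_hp = hp
        codata = None
        if name == "high":
            model_hp = Hyperparameters(
                tau0_prior=hp.tau0_prior,
                tau_prior=hp.tau_prior,
                pi_prior=hp.pi_prior,
                omega_prior=(2.0, 1.0),
                phi_prior_mean=hp.phi_prior_mean,
                phi_prior_variance=hp.phi_prior_variance,
                p_dominant_given_assoc=hp.p_dominant_given_assoc,
                p_association=hp.p_association,
            )
        elif name == "moderate" and members["high"].any():
            raw = members["high"][inc].astype(float)
            if raw.std() > 0:
                codata = CoData(raw)
        models.append(
            AssociationModel(
                inclusion=inc,
                prior_prob=priors[name],
                codata=codata,
                hyperparameters=model_hp,
                name=name,
            )
        )
    if not models:
        raise ValueError(f"locus {locus.locus_id} has no variants in any class")
    return AssociationModelSet(tuple(models))


# ---------------------------------------------------------------------------
# plain-matrix fixtures


def write_matrix(path, data: GenotypeData, y: Phenotype) -> None:
    """Write genotypes + phenotype as a TSV fixture (one row per individual)."""
    df = pd.DataFrame(data.allele_counts, columns=list(data.variant_ids))
    df.insert(0, "ploidy", data.ploidy)
    df.insert(0, "y", y.y)
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> tuple[GenotypeData, Phenotype]:
    """Read a TSV fixture written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t")
    y = Phenotype(df.pop("y").values)
    ploidy = df.pop("ploidy").values
    data = GenotypeData(df.values, ploidy, tuple(df.columns))
    return data, y


def locus_result_row(locus_id: str, res) -> dict:
    """One summary-TSV row per locus."""
    return {
        "locus_id": locus_id,
        "prob_association": res.prob_association,
        "prob_dominant": res.prob_dominant_given_assoc,
        "modal_model": res.modal_model,
        "expected_explained_cases": res.expected_explained_cases,
        "expected_pathogenic_variants": res.expected_pathogenic_count,
        "n_variants": res.n_variants,
    }


def variant_result_rows(locus, res) -> list[dict]:
    """Per-variant TSV rows: class membership and averaged marginal."""
    rows = []
    for j, vid in enumerate(locus.variant_ids):
        rows.append(
            {
                "locus_id": locus.locus_id,
                "variant_id": vid,
                "classes": ",".join(sorted(locus.classes[j])),
                "pathogenicity_marginal": res.averaged_z_marginals[j],
                "never_modeled": bool(res.never_modeled[j]),
            }
        )
    return rows


__all__ = [
    "LocusDefinition",
    "read_sample_sheet",
    "read_genotypes",
    "read_variant_classes",
    "loci_from_table",
    "build_model_set",
    "write_matrix",
    "read_matrix",
    "locus_result_row",
    "variant_result_rows",
    "CLASS_NAMES",
]
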