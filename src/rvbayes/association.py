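"""Locus-level association testing: composition of sampler and combiner."""

from __future__ import annotations

import numpy as np

from .combine import (
    AssociationModel,
    AssociationModelSet,
    LocusResult,
    posterior_association,
)
from .data import CoData, GenotypeData, Hyperparameters, ModeOfInheritance, Phenotype
from .likelihood import baseline_log_evidence
from .mcmc import MCMCSettings, model_evidence


def run_locus(
    data: GenotypeData,
    y: Phenotype,
    model_set: AssociationModelSet,
    settings: MCMCSettings,
) -> LocusResult:
    """Full inference at one locus over all (model, mode) pairs.

    The evidence is estimated conditionally on each inheritance mode and
    each association model, on the model's variant subset with its own
    co-data and hyperparameters; modes are then integrated out and models
    compared by posterior probability.  Distinct sub-seeds derived from the
    settings seed keep the run deterministic.
    """
    hp0 = model_set.models[0].hyperparameters
    log_ev0 = baseline_log_evidence(y.y, hp0.tau0_prior)
    per_model = []
    for u, model in enumerate(model_set.models):
        sub = data.subset_variants(model.inclusion)
        hp = model.hyperparameters
        res: dict = {}
        modes = []
        if hp.p_dominant_given_assoc > 0.0:
            modes.append(("dominant", ModeOfInheritance.DOMINANT))
        if hp.p_dominant_given_assoc < 1.0:
            modes.append(("recessive", ModeOfInheritance.RECESSIVE))
        for w, (key, mode) in enumerate(modes):
            sub_settings = MCMCSettings(
                iterations_per_rung=settings.iterations_per_rung,
                burn_in=settings.burn_in,
                seed=(settings.seed * 1000003 + u * 2 + w) % 2**31,
                ladder=settings.ladder,
            )
            res[key] = model_evidence(sub, y, model.codata, mode, hp, sub_settings)
        per_model.append(res)
    return posterior_association(model_set, log_ev0, per_model)


def association_test(
    data: GenotypeData,
    y: Phenotype,
    codata: CoData | None = None,
    hp: Hyperparameters | None = None,
    settings: MCMCSettings | None = None,
) -> LocusResult:
    """Single-model association test over all variants at a locus.

    Convenience wrapper: one association model including every variant,
    with prior probability ``hp.p_association``, modes integrated out with
    prior weight ``hp.p_dominant_given_assoc`` on dominance.
    """
    hp = hp or Hyperparameters()
    settings = settings or MCMCSettings()
    model = AssociationModel(
        inclusion=np.ones(data.n_variants, dtype=bool),
        prior_prob=hp.p_association,
        codata=codata,
        hyperparameters=hp,
        name="all-variants",
    )
    return run_locus(data, y, AssociationModelSet((model,)), settings)


__all__ = ["run_locus", "association_test"]
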