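"""Combining evidences into posterior probabilities of association.

Evidence is estimated conditionally on each inheritance mode and each
variant-class association model; modes are integrated out by summation,
models compete through their prior probabilities, and per-variant
pathogenicity marginals are averaged over models weighted by posterior
model probability.  All arithmetic is on the log scale until output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data import CoData, Hyperparameters
from .mcmc import EvidenceResult


@dataclass(frozen=True)
class AssociationModel:
    """One competing association model over a subset of a locus's variants."""

    inclusion: np.ndarray  # boolean over the locus's variants
    prior_prob: float  # P(gamma = u)
    codata: CoData | None = None  # over the included variants only
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    name: str = ""

    def __post_init__(self) -> None:
        inc = np.asarray(self.inclusion, dtype=bool)
        if inc.sum() < 1:
            raise ValueError("every association model must include >= 1 variant")
        if not 0.0 < self.prior_prob < 1.0:
            raise ValueError("model prior probability must lie in (0, 1)")
        if self.codata is not None and self.codata.k != int(inc.sum()):
            raise ValueError("codata must cover exactly the included variants")
        object.__setattr__(self, "inclusion", inc)


@dataclass(frozen=True)
class AssociationModelSet:
    """The competing association models at one locus."""

    models: tuple[AssociationModel, ...]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("need at least one association model")
        if sum(m.prior_prob for m in self.models) > 1.0 + 1e-12:
            raise ValueError("model prior probabilities must sum to <= 1")
        object.__setattr__(self, "models", tuple(self.models))

    @property
    def prior_no_association(self) -> float:
        return 1.0 - sum(m.prior_prob for m in self.models)


@dataclass
class LocusResult:
    """Posterior summary of one locus."""

    prob_association: float
    prob_dominant_given_assoc: float
    model_posteriors: np.ndarray  # P(gamma = u | gamma > 0, y), length g
    averaged_z_marginals: np.ndarray  # over all locus variants; 0 if never modeled
    never_modeled: np.ndarray  # variants excluded from every model
    expected_explained_cases: float
    expected_pathogenic_count: float
    per_model: list  # per-model dict with per-mode EvidenceResult and posteriors
    n_variants: int = 0
    modal_model: str = ""


def combine_modes(
    log_evidence_dom: float, log_evidence_rec: float, p_dominant: float
) -> tuple[float, tuple[float, float]]:
    """Integrate the mode of inheritance out of a model's evidence.

    Returns the mode-marginal log evidence and the posterior probabilities
    of (dominant, recessive) given the model.
    """
    if not 0.0 <= p_dominant <= 1.0:
        raise ValueError("p_dominant must lie in [0, 1]")
    if p_dominant == 1.0:
        return log_evidence_dom, (1.0, 0.0)
    if p_dominant == 0.0:
        return log_evidence_rec, (0.0, 1.0)
    terms = np.array(
        [
            log_evidence_dom + np.log(p_dominant),
            log_evidence_rec + np.log1p(-p_dominant),
        ]
    )
    marginal = float(logsumexp(terms))
    post = np.exp(terms - marginal)
    return marginal, (float(post[0]), float(post[1]))


def posterior_association(
    model_set: AssociationModelSet,
    baseline_log_evidence: float,
    per_model_results: list[dict],
) -> LocusResult:
    """Posterior probability of association and model-averaged summaries.

    ``per_model_results`` carries, for each model u, the per-mode
    ``EvidenceResult`` objects under the keys "dominant" and "recessive"
    (either may be omitted when the mode prior excludes it).  The locus
    posterior is P(gamma > 0 | y) = sum_u BF_u P(gamma=u) / (P(gamma=0) +
    sum_u BF_u P(gamma=u)) computed on the log scale, and variant-level
    summaries are averaged over models (and modes within model) with
    weights proportional to posterior model probability.
    """
    g = len(model_set.models)
    if len(per_model_results) != g:
        raise ValueError("one result dict required per model")
    k_locus = model_set.models[0].inclusion.size

    log_terms = np.empty(g)  # log [P(y|gamma=u) P(gamma=u)]
    mode_posts = []
    for u, (model, res) in enumerate(zip(model_set.models, per_model_results)):
        hp = model.hyperparameters
        dom = res.get("dominant")
        rec = res.get("recessive")
        if dom is not None and rec is not None:
            marg, post = combine_modes(
                dom.log_evidence, rec.log_evidence, hp.p_dominant_given_assoc
            )
        elif dom is not None:
            marg, post = dom.log_evidence, (1.0, 0.0)
        elif rec is not None:
            marg, post = rec.log_evidence, (0.0, 1.0)
        else:
            raise ValueError("each model needs at least one mode's evidence")
        log_terms[u] = marg + np.log(model.prior_prob)
        mode_posts.append(post)

    p0 = model_set.prior_no_association
    if p0 > 0.0:
        log_p0_term = baseline_log_evidence + np.log(p0)
        log_denom = float(logsumexp(np.append(log_terms, log_p0_term)))
    else:
        log_denom = float(logsumexp(log_terms))
    log_num = float(logsumexp(log_terms))
    prob_assoc = float(np.exp(log_num - log_denom))

    # posterior over models given association
    model_post = np.exp(log_terms - log_num)
    model_post /= model_post.sum()

    averaged = np.zeros(k_locus)
    modeled = np.zeros(k_locus, dtype=bool)
    expl = 0.0
    npath = 0.0
    p_dom = 0.0
    per_model_out = []
    for u, (model, res) in enumerate(zip(model_set.models, per_model_results)):
        w_dom, w_rec = mode_posts[u]
        z_u = np.zeros(int(model.inclusion.sum()))
        expl_u = 0.0
        npath_u = 0.0
        for mode_key, w in (("dominant", w_dom), ("recessive", w_rec)):
            r = res.get(mode_key)
            if r is None or w == 0.0:
                continue
            z_u += w * r.z_marginals
            expl_u += w * r.expected_explained_cases
            npath_u += w * r.expected_pathogenic_count
        averaged[model.inclusion] += model_post[u] * z_u
        modeled |= model.inclusion
        expl += model_post[u] * expl_u
        npath += model_post[u] * npath_u
        p_dom += model_post[u] * w_dom
        per_model_out.append(
            {
                "name": model.name or f"model{u}",
                "posterior_prob": float(model_post[u]),
                "mode_posterior": mode_posts[u],
                "results": res,
            }
        )

    modal = int(np.argmax(model_post))
    return LocusResult(
        prob_association=prob_assoc,
        prob_dominant_given_assoc=float(p_dom),
        model_posteriors=model_post,
        averaged_z_marginals=averaged,
        never_modeled=~modeled,
        expected_explained_cases=float(expl),
        expected_pathogenic_count=float(npath),
        per_model=per_model_out,
        n_variants=k_locus,
        modal_model=model_set.models[modal].name or f"model{modal}",
    )


__all__ = [
    "AssociationModel",
    "AssociationModelSet",
    "LocusResult",
    "combine_modes",
    "posterior_association",
]
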