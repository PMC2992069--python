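"""Two-condition domain comparison by fixed-parameter transfer decoding.

The second condition's scores (e.g. neural-progenitor cells) are normalised
against the reference condition (e.g. embryonic stem cells), the reference
model's parameters are held fixed, and the second condition is re-decoded
with Viterbi — no re-estimation.  A reference domain is "changed" if at least
one of its genes decodes to a different state in the second condition; the
alternative path segments each reference domain into sub-domains annotated
with their ordered state-pair transition type (e.g. "non-active->active"),
or "unchanged".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .domains import DomainCall, segment
from .hmm import HMMParams, viterbi
from .scores import GeneScoreMatrix

__all__ = [
    "ConditionComparison",
    "DomainChange",
    "normalize_condition",
    "transfer_decode",
    "call_domain_changes",
]


@dataclass
class DomainChange:
    """Per-reference-domain change record."""

    domain_id: int
    changed: bool
    subdomains: list[tuple[int, int, int, int]]  # (start, end incl., ref_state, alt_state)
    transition_types: list[str]

    @property
    def n_subdomains(self) -> int:
        return len(self.subdomains)


@dataclass
class ConditionComparison:
    ref_states: np.ndarray
    alt_states: np.ndarray
    changed_genes: np.ndarray  # indices with ref != alt
    domain_changes: list[DomainChange] = field(default_factory=list)

    @property
    def n_changed_domains(self) -> int:
        return sum(dc.changed for dc in self.domain_changes)


def normalize_condition(
    alt_scores: GeneScoreMatrix,
    ref_scores: GeneScoreMatrix,
    method: str = "median_ratio",
) -> GeneScoreMatrix:
    """Remove per-mark depth differences between conditions.

    ``median_ratio``: per mark, divide by the median alt/ref ratio over genes
    with positive reference signal (robust, the default).  ``nb_regression``:
    per mark, fit an intercept-only negative-binomial regression of the
    alternative scores with the log reference score as offset, so the fitted
    intercept is the log mean alt/ref scale; divide by that scale.  ``none``:
    pass-through.  The method is recorded in the result's ``meta``.
    """
    if alt_scores.gene_ids != ref_scores.gene_ids or alt_scores.marks != ref_scores.marks:
        raise ValueError("conditions must share the same genes and marks, in order")
    A, R = alt_scores.scores, ref_scores.scores
    if method == "none":
        out = A.copy()
        scales = np.ones(A.shape[1])
    elif method in ("median_ratio", "nb_regression"):
        scales = np.empty(A.shape[1])
        for j in range(A.shape[1]):
            ok = R[:, j] > 0
            if not ok.any() or not np.any(A[:, j] > 0):
                raise ValueError(f"mark {alt_scores.marks[j]!r} has no positive signal")
            if method == "median_ratio":
                scales[j] = float(np.median(A[ok, j] / R[ok, j]))
            else:
                scales[j] = _nb_scale(A[ok, j], R[ok, j])
            if scales[j] <= 0:
                raise ValueError(f"non-positive scale for mark {alt_scores.marks[j]!r}")
        out = A / scales
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return GeneScoreMatrix(
        gene_ids=list(alt_scores.gene_ids),
        marks=list(alt_scores.marks),
        scores=out,
        chrom_breaks=alt_scores.chrom_breaks.copy(),
        chrom_names=list(alt_scores.chrom_names) if alt_scores.chrom_names else None,
        meta={**alt_scores.meta, "normalization": method,
              "normalization_scales": scales.tolist()},
    )


def _nb_scale(alt: np.ndarray, ref: np.ndarray) -> float:
    """Mean alt/ref scale from an intercept-only NB regression with log-ref
    offset: alt_i ~ NB(mean = scale * ref_i)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NB family with non-integer response
        model = sm.GLM(
            alt,
            np.ones((len(alt), 1)),
            family=sm.families.NegativeBinomial(alpha=1.0),
            offset=np.log(ref),
        )
        res = model.fit()
    return float(np.exp(res.params[0]))


def transfer_decode(alt_scores: GeneScoreMatrix, ref_model: HMMParams) -> np.ndarray:
    """Viterbi path of the alternative condition under the reference model's
    parameters (no re-estimation)."""
    if alt_scores.n_marks != ref_model.n_marks:
        raise ValueError("mark dimension mismatch between scores and model")
    if ref_model.marks is not None and list(alt_scores.marks) != list(ref_model.marks):
        raise ValueError("mark names/order differ between scores and model")
    return viterbi(alt_scores, ref_model)


def call_domain_changes(
    ref_domains: list[DomainCall],
    ref_states: np.ndarray,
    alt_states: np.ndarray,
    state_labels: list[str] | None = None,
) -> ConditionComparison:
    """Apply the domain-change rule to every reference domain.

    A domain is changed iff >= 1 of its genes has a different state in the
    alternative condition.  Within each reference domain the alternative path
    is segmented into sub-domains (a refinement of the reference span); each
    sub-domain carries a transition type "ref_label->alt_label", or
    "unchanged" when the states agree.
    """
    ref_states = np.asarray(ref_states)
    alt_states = np.asarray(alt_states)
    if ref_states.shape != alt_states.shape:
        raise ValueError("state vectors must be aligned and equally long")

    def lab(s: int) -> str:
        return state_labels[s] if state_labels else f"state{s}"

    changes: list[DomainChange] = []
    for dom in ref_domains:
        lo, hi = dom.start_gene_index, dom.end_gene_index
        sub = segment(alt_states[lo : hi + 1])
        subdomains, types = [], []
        for s in sub:
            a, b = lo + s.start_gene_index, lo + s.end_gene_index
            alt_state = int(s.state)
            subdomains.append((a, b, dom.state, alt_state))
            types.append(
                "unchanged" if alt_state == dom.state else f"{lab(dom.state)}->{lab(alt_state)}"
            )
        changed = bool(np.any(alt_states[lo : hi + 1] != ref_states[lo : hi + 1]))
        changes.append(
            DomainChange(
                domain_id=dom.domain_id,
                changed=changed,
                subdomains=subdomains,
                transition_types=types,
            )
        )
    return ConditionComparison(
        ref_states=ref_states,
        alt_states=alt_states,
        changed_genes=np.flatnonzero(ref_states != alt_states),
        domain_changes=changes,
    )
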