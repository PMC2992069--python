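"""Coherence validation of called domains by genomic-neighbourhood permutation.

The null model for every test preserves local genomic autocorrelation:
instead of scattering genes at random, each permutation round draws one
contiguous run of genes ("random section of the genome") per observed
significant domain, matched in gene count, uniformly over all valid start
positions across chromosomes.  With B rounds the smallest attainable p-value
is exactly 1/B (0.001 at the default B = 1000), because the observed
configuration always counts at least once.

Three statistics are tested:

* within-domain variance of each mark's summary score (coherent domains give
  variances *lower* than chance: left tail);
* within-domain variance of a per-gene expression Z-statistic, the focal cell
  line normalised against the panel of cell lines (left tail);
* mean Fleiss' kappa of Gene Ontology membership within a domain, treating
  the domain's genes as raters each rating every GO term of a fixed slim
  vocabulary as annotated / not annotated (accordant domains give kappa
  *higher* than chance: right tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import DomainCall

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "random_neighbor_sets",
    "within_domain_variance_test",
    "expression_z",
    "fleiss_kappa",
    "go_accordance_test",
]


@dataclass
class PermutationResult:
    """An observed statistic against its permutation null."""

    observed: float
    null_sample: np.ndarray
    p_value: float
    direction: str  # "less" or "greater"
    B: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("less", "greater"):
            raise ValueError("direction must be 'less' or 'greater'")


def _empirical_p(observed: float, null: np.ndarray, direction: str) -> float:
    if direction == "less":
        count = int(np.sum(null <= observed))
    else:
        count = int(np.sum(null >= observed))
    # the observed arrangement always counts once: the floor is 1/B
    return max(count, 1) / len(null)


def random_neighbor_sets(
    chrom_breaks: np.ndarray,
    n_genes: int,
    sizes: list[int],
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Draw B rounds of contiguous gene-index windows size-matched to
    ``sizes``.

    Returns an integer array (B, len(sizes), 2) of [start, end) row windows,
    each placed uniformly over every valid start in every chromosome long
    enough to hold it.  A size that fits on no chromosome raises.
    """
    breaks = np.asarray(chrom_breaks, dtype=np.int64)
    bounds = list(breaks) + [n_genes]
    chains = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    rng = np.random.default_rng(seed)
    out = np.empty((B, len(sizes), 2), dtype=np.int64)
    for j, size in enumerate(sizes):
        starts = np.concatenate(
            [np.arange(lo, hi - size + 1) for lo, hi in chains if hi - lo >= size]
            or [np.empty(0, dtype=np.int64)]
        )
        if not len(starts):
            raise ValueError(f"no chromosome can hold a window of {size} genes")
        draws = rng.choice(starts, size=B, replace=True)
        out[:, j, 0] = draws
        out[:, j, 1] = draws + size
    return out


def _domain_windows(domains: list[DomainCall], min_size: int = 2) -> list[tuple[int, int]]:
    wins = [
        (d.start_gene_index, d.end_gene_index + 1)
        for d in domains
        if d.significant and d.n_genes >= min_size
    ]
    return wins


def within_domain_variance_test(
    domains: list[DomainCall],
    values: np.ndarray,
    chrom_breaks: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    names: list[str] | None = None,
) -> list[PermutationResult]:
    """Are score (or expression) values more homogeneous inside domains than
    in random same-size gene neighbourhoods?

    ``values`` is (n,) or (n, m); one result per column.  The statistic is the
    mean over significant multi-gene domains of the unbiased within-domain
    variance; the null repeats it on size-matched contiguous windows;
    direction is "less" (coherence lowers variance).
    """
    V = np.asarray(values, dtype=float)
    squeeze = V.ndim == 1
    V = V.reshape(len(V), -1)
    wins = _domain_windows(domains)
    if not wins:
        raise ValueError("no significant domain with >= 2 genes to evaluate")
    sizes = [b - a for a, b in wins]
    null_windows = random_neighbor_sets(chrom_breaks, len(V), sizes, B=B, seed=seed)

    def stat(windows) -> np.ndarray:
        return np.mean([V[a:b].var(axis=0, ddof=1) for a, b in windows], axis=0)

    observed = stat(wins)
    null = np.array([stat(null_windows[b]) for b in range(B)])  # (B, m)
    results = []
    for j in range(V.shape[1]):
        results.append(
            PermutationResult(
                observed=float(observed[j]),
                null_sample=null[:, j].copy(),
                p_value=_empirical_p(float(observed[j]), null[:, j], "less"),
                direction="less",
                B=B,
                name=names[j] if names else f"col{j}",
            )
        )
    return results if not squeeze else results[:1]


def expression_z(expr: pd.DataFrame, focal_line: str) -> pd.Series:
    """Z-normalise each gene's focal-line expression against all cell lines.

    z_g = (x_g,focal - mean_l x_g,l) / sd_l x_g,l  (unbiased sd).  Genes with
    zero across-line sd are dropped with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 cell lines")
    if focal_line not in expr.columns:
        raise KeyError(f"focal line {focal_line!r} not in expression matrix")
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    bad = sd <= 0
    if bad.any():
        logger.warning("dropping %d genes with zero expression variance", int(bad.sum()))
    z = (expr[focal_line] - mu) / sd
    return z[~bad]


def fleiss_kappa(table: np.ndarray) -> float:
    """Fleiss' kappa for N subjects rated into k categories by n raters.

    ``table`` is an (N, k) count matrix whose rows each sum to the common
    rater count n >= 2.  Returns (P_bar - Pe_bar) / (1 - Pe_bar); raises when
    every rating falls in one category (Pe_bar = 1, kappa undefined).
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] < 1 or T.shape[1] < 2:
        raise ValueError("table must be (subjects x categories) with >= 2 categories")
    n_raters = T[0].sum()
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    if not np.allclose(T.sum(axis=1), n_raters):
        raise ValueError("every subject must be rated by the same number of raters")
    N = T.shape[0]
    p_cat = T.sum(axis=0) / (N * n_raters)
    P_i = (np.sum(T**2, axis=1) - n_raters) / (n_raters * (n_raters - 1))
    P_bar = P_i.mean()
    Pe_bar = float(np.sum(p_cat**2))
    if np.isclose(Pe_bar, 1.0):
        raise ValueError("all ratings in one category: kappa is undefined")
    return float((P_bar - Pe_bar) / (1.0 - Pe_bar))


def _window_kappa(
    gene_ids: list[str],
    window: tuple[int, int],
    go: dict[str, frozenset[str]],
    vocabulary: list[str],
) -> float:
    """GO-accordance Y for one gene window: Fleiss' kappa with the window's
    annotated genes as raters, GO terms as subjects, categories
    annotated/not-annotated.  NaN when undefined or < 2 annotated genes."""
    members = [g for g in gene_ids[window[0] : window[1]] if go.get(g)]
    n = len(members)
    if n < 2:
        return np.nan
    counts = np.array(
        [sum(1 for g in members if term in go[g]) for term in vocabulary], dtype=float
    )
    table = np.column_stack([counts, n - counts])
    try:
        return fleiss_kappa(table)
    except ValueError:
        return np.nan


def go_accordance_test(
    domains: list[DomainCall],
    go: dict[str, frozenset[str]],
    gene_ids: list[str],
    chrom_breaks: np.ndarray,
    vocabulary: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Is GO membership more accordant inside domains than in random
    same-size gene neighbourhoods?

    Observed = mean per-domain kappa Y_j over significant domains with >= 2
    annotated genes; null = the same mean on size-matched contiguous windows
    (so locally shared annotation of neighbouring genes is preserved under the
    null); direction "greater".
    """
    if vocabulary is None:
        vocabulary = sorted({t for terms in go.values() for t in terms})
    if not vocabulary:
        raise ValueError("empty GO vocabulary")
    wins = _domain_windows(domains)
    if not wins:
        raise ValueError("no significant domain with >= 2 genes to evaluate")
    per_domain = np.array([_window_kappa(gene_ids, w, go, vocabulary) for w in wins])
    usable = np.isfinite(per_domain)
    if not usable.any():
        raise ValueError("no domain with >= 2 annotated genes")
    if not usable.all():
        logger.warning("skipping %d domains without evaluable GO kappa", int((~usable).sum()))
    observed = float(per_domain[usable].mean())

    sizes = [b - a for a, b in wins]
    null_windows = random_neighbor_sets(chrom_breaks, len(gene_ids), sizes, B=B, seed=seed)
    null = np.empty(B)
    for b in range(B):
        ys = np.array(
            [_window_kappa(gene_ids, (int(a), int(e)), go, vocabulary)
             for a, e in null_windows[b]]
        )
        null[b] = np.nanmean(ys) if np.isfinite(ys).any() else -np.inf
    return PermutationResult(
        observed=observed,
        null_sample=null,
        p_value=_empirical_p(observed, null, "greater"),
        direction="greater",
        B=B,
        name="go_accordance",
    )
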