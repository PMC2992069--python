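"""Domain segmentation, likelihood-ratio significance and FDR control.

A domain is a maximal run of consecutive genes decoded to the same hidden
state within one chromosome.  Each domain j with genes x_1..x_{n_j} is scored
with the likelihood-ratio statistic

    lambda_j = -2 * sum_i [ log N(x_i; mu_0, Sigma_0) - log N(x_i; mu_s, Sigma_s) ],

comparing the global diagonal-Gaussian model (mu_0, Sigma_0: mean and
diagonal variance of the entire dataset) against the domain's decoded state's
emission model.  lambda_j is referred to a chi-square with
df = 2*S*m - 2*m degrees of freedom (S states, m marks): all 2*S*m state
parameters counted as free against the 2*m global ones.  Note this df is
anti-conservative under standard large-sample LRT theory, since only one
state's 2*m parameters enter any single domain's likelihood; it is used as
the method defines it.  Multiple testing is controlled by Benjamini-Hochberg,
keeping domains at q <= FDR (default 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hmm import HMMParams, _log_emissions
from .scores import GeneScoreMatrix

__all__ = [
    "GlobalModel",
    "DomainCall",
    "segment",
    "global_model",
    "lrt_statistic",
    "lrt_df",
    "score_domains",
    "summarize_domains",
]


@dataclass
class GlobalModel:
    """Null emission model: mean and diagonal variance of the whole dataset."""

    mu0: np.ndarray
    sigma0: np.ndarray  # variances (diagonal), MLE (divide by n)

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.sigma0 = np.asarray(self.sigma0, dtype=float)
        if np.any(self.sigma0 <= 0):
            raise ValueError("global variances must be strictly positive")

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return -0.5 * np.sum(
            np.log(2 * np.pi * self.sigma0) + (X - self.mu0) ** 2 / self.sigma0, axis=1
        )


@dataclass
class DomainCall:
    """One maximal same-state gene run with its significance assessment."""

    domain_id: int
    chrom: str | None
    start_gene_index: int  # inclusive, global row index
    end_gene_index: int  # inclusive
    state: int
    state_label: str
    lambda_stat: float = np.nan
    df: int = 0
    p_value: float = np.nan
    q_value: float = np.nan
    significant: bool = False

    @property
    def n_genes(self) -> int:
        return self.end_gene_index - self.start_gene_index + 1


def segment(
    path: np.ndarray,
    chrom_breaks: np.ndarray | None = None,
    chrom_names: list[str] | None = None,
    state_labels: list[str] | None = None,
) -> list[DomainCall]:
    """Split a decoded state path into maximal same-state runs per chromosome."""
    path = np.asarray(path)
    n = len(path)
    breaks = np.asarray(chrom_breaks if chrom_breaks is not None else [0], dtype=np.int64)
    bounds = list(breaks) + [n]
    calls: list[DomainCall] = []
    for c in range(len(bounds) - 1):
        lo, hi = bounds[c], bounds[c + 1]
        start = lo
        for i in range(lo + 1, hi + 1):
            if i == hi or path[i] != path[start]:
                state = int(path[start])
                calls.append(
                    DomainCall(
                        domain_id=len(calls),
                        chrom=chrom_names[c] if chrom_names else None,
                        start_gene_index=int(start),
                        end_gene_index=int(i - 1),
                        state=state,
                        state_label=(
                            state_labels[state] if state_labels else f"state{state}"
                        ),
                    )
                )
                start = i
    return calls


def global_model(scores) -> GlobalModel:
    """Per-mark mean and MLE variance over all retained genes."""
    X = scores.scores if isinstance(scores, GeneScoreMatrix) else np.atleast_2d(np.asarray(scores, float))
    if len(X) < 2:
        raise ValueError("need at least 2 genes for a global model")
    sigma0 = X.var(axis=0)
    if np.any(sigma0 <= 0):
        raise ValueError("a mark has zero variance; cannot form the null model")
    return GlobalModel(mu0=X.mean(axis=0), sigma0=sigma0)


def lrt_statistic(
    domain_scores: np.ndarray, state: int, params: HMMParams, g: GlobalModel
) -> float:
    """lambda_j for one domain: -2 * (null loglik - state loglik), summed over
    the domain's genes."""
    X = np.atleast_2d(np.asarray(domain_scores, dtype=float))
    log_state = _log_emissions(X, params)[:, state]
    log_null = g.logpdf(X)
    lam = float(-2.0 * (log_null.sum() - log_state.sum()))
    if not np.isfinite(lam):
        raise ValueError("non-finite likelihood ratio")
    return lam


def lrt_df(S: int, m: int) -> int:
    """Degrees of freedom 2*S*m - 2*m for the domain likelihood-ratio test."""
    if S < 1 or m < 1:
        raise ValueError("S and m must be >= 1")
    df = 2 * S * m - 2 * m
    if df == 0:
        warnings.warn("S = 1 gives df = 0: the likelihood-ratio test is degenerate")
    return df


def score_domains(
    domains: list[DomainCall],
    scores,
    params: HMMParams,
    g: GlobalModel | None = None,
    fdr: float = 0.01,
) -> list[DomainCall]:
    """Attach lambda, chi-square p, BH q and the significance flag to calls.

    p is the upper chi-square tail at df = 2*S*m - 2*m; q-values are
    Benjamini-Hochberg over all domains; ``significant`` iff q <= ``fdr``.
    """
    if not 0 < fdr <= 1:
        raise ValueError("fdr must be in (0, 1]")
    X = scores.scores if isinstance(scores, GeneScoreMatrix) else np.atleast_2d(np.asarray(scores, float))
    g = g or global_model(X)
    df = lrt_df(params.n_states, params.n_marks)
    if df == 0:
        raise ValueError("df = 0: significance is undefined for a one-state model")
    lams = np.array(
        [
            lrt_statistic(X[d.start_gene_index : d.end_gene_index + 1], d.state, params, g)
            for d in domains
        ]
    )
    pvals = stats.chi2.sf(lams, df)
    qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.empty(0)
    return [
        replace(
            d,
            lambda_stat=float(lam),
            df=df,
            p_value=float(p),
            q_value=float(q),
            significant=bool(q <= fdr),
        )
        for d, lam, p, q in zip(domains, lams, pvals, qvals)
    ]


def summarize_domains(calls: list[DomainCall], significant_only: bool = True) -> pd.DataFrame:
    """Per-state size summary (count, min/max/mean/unbiased variance) plus a
    Total row, over significant domains by default."""
    pool = [c for c in calls if c.significant] if significant_only else list(calls)
    groups: dict[str, list[int]] = {}
    for c in pool:
        groups.setdefault(c.state_label, []).append(c.n_genes)
    rows = {}
    for label in sorted(groups) + ["Total"]:
        sizes = (
            np.asarray(groups.get(label, []), dtype=float)
            if label != "Total"
            else np.asarray([c.n_genes for c in pool], dtype=float)
        )
        if len(sizes) == 0:
            rows[label] = dict(count=0, min_size=np.nan, max_size=np.nan,
                               mean_size=np.nan, var_size=np.nan)
        else:
            rows[label] = dict(
                count=len(sizes),
                min_size=sizes.min(),
                max_size=sizes.max(),
                mean_size=sizes.mean(),
                var_size=sizes.var(ddof=1) if len(sizes) > 1 else np.nan,
            )
    return pd.DataFrame.from_dict(rows, orient="index")


def calls_to_frame(calls: list[DomainCall]) -> pd.DataFrame:
    """Flatten calls to a DataFrame mirroring the DomainCall fields."""
    return pd.DataFrame(
        [
            dict(
                domain_id=c.domain_id, chrom=c.chrom,
                start_gene_index=c.start_gene_index, end_gene_index=c.end_gene_index,
                n_genes=c.n_genes, state=c.state, state_label=c.state_label,
                lambda_stat=c.lambda_stat, df=c.df, p_value=c.p_value,
                q_value=c.q_value, significant=c.significant,
            )
            for c in calls
        ]
    )
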