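"""Diagonal-covariance multivariate Gaussian hidden Markov model.

The hidden state of each gene is its domain type; the emission is the gene's
m-dimensional summary-score vector, modelled as m independent Gaussians per
state (no covariance structure).  One global parameter set is shared by all
chromosomes; each chromosome is an independent chain, and EM accumulates
sufficient statistics across chains.

Parameter estimation is by EM.  Initialisation is either from a fitted
k-means partition (cluster means/variances; the recommended route) or by
drawing state parameters from a semi-conjugate hierarchical prior

    mu_ks | sigma2_ks ~ N(theta_k, s2_k),   sigma2_ks ~ scaled-Inv-chi2(nu_k)

scaled so that E[sigma2_ks] = s2_k, where theta_k and s2_k are the sample
mean and variance of mark k.  Decoding is by Viterbi (joint-MLE path) or by
the scaled forward-backward recursions (per-gene MAP from posteriors).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster import ClusterModel
from .scores import GeneScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "PriorHyperparams",
    "Decoding",
    "emission_logdensity",
    "init_from_clusters",
    "init_from_prior",
    "em_fit",
    "viterbi",
    "forward_backward",
    "decode",
    "decode_agreement",
    "assign_state_labels",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class HMMParams:
    """Emission, transition and initial-state parameters for S hidden states."""

    means: np.ndarray  # (S, m)
    variances: np.ndarray  # (S, m), strictly positive
    transition: np.ndarray  # (S, S) row-stochastic
    initial: np.ndarray  # (S,)
    state_labels: list[str] | None = None
    marks: list[str] | None = None

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.initial = np.asarray(self.initial, dtype=float)
        S, m = self.means.shape
        if self.variances.shape != (S, m):
            raise ValueError("means and variances must have the same (S, m) shape")
        if self.transition.shape != (S, S):
            raise ValueError("transition must be S x S")
        if self.initial.shape != (S,):
            raise ValueError("initial must have length S")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial probabilities must sum to 1")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_marks(self) -> int:
        return self.means.shape[1]

    def label_of(self, state: int) -> str:
        if self.state_labels is not None:
            return self.state_labels[state]
        return f"state{state}"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "state_labels": self.state_labels,
            "marks": self.marks,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMParams":
        d = json.loads(Path(path).read_text())
        return cls(
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            transition=np.asarray(d["transition"]),
            initial=np.asarray(d["initial"]),
            state_labels=d.get("state_labels"),
            marks=d.get("marks"),
        )


@dataclass
class PriorHyperparams:
    """Hyperparameters of the semi-conjugate initialisation prior, per mark."""

    theta: np.ndarray  # sample means
    s2: np.ndarray  # sample variances
    nu: np.ndarray  # degrees of freedom, > 2 each

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if np.any(self.nu <= 2):
            raise ValueError("nu must exceed 2 for E[sigma2] to be finite")

    @classmethod
    def from_scores(cls, scores, nu: float = 10.0) -> "PriorHyperparams":
        X = _as_matrix(scores)[0]
        m = X.shape[1]
        return cls(theta=X.mean(axis=0), s2=X.var(axis=0), nu=np.full(m, float(nu)))


@dataclass
class Decoding:
    """Joint result of both decoders for one dataset."""

    viterbi_path: np.ndarray
    posterior: np.ndarray  # (n, S), rows sum to 1
    map_path: np.ndarray
    loglik: float


def _as_matrix(scores) -> tuple[np.ndarray, np.ndarray]:
    """Accept a GeneScoreMatrix or a bare array (treated as one chain)."""
    if isinstance(scores, GeneScoreMatrix):
        return scores.scores, scores.chrom_breaks
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    return X, np.array([0], dtype=np.int64)


def _chain_slices(n: int, breaks: np.ndarray) -> list[slice]:
    bounds = list(breaks) + [n]
    return [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _log_emissions(X: np.ndarray, params: HMMParams) -> np.ndarray:
    """(n, S) matrix of per-gene per-state log emission densities."""
    if not np.isfinite(X).all():
        raise ValueError("score matrix contains non-finite values")
    diff = X[:, None, :] - params.means[None, :, :]  # (n, S, m)
    return -0.5 * np.sum(
        _LOG2PI + np.log(params.variances)[None] + diff**2 / params.variances[None],
        axis=2,
    )


def emission_logdensity(x, state: int, params: HMMParams) -> float:
    """Log density of one score vector under one state: the sum of univariate
    Gaussian log densities over marks (diagonal covariance)."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    return float(_log_emissions(x, params)[0, state])


def init_from_clusters(model: ClusterModel, self_transition: float = 0.9,
                       var_floor: float = 1e-6) -> HMMParams:
    """HMM initial guess from a k-means partition.

    Means/variances are copied from the clusters (variances floored), the
    transition matrix is sticky (diagonal ``self_transition``, uniform
    off-diagonal) because domains are multi-gene, and the initial distribution
    is the cluster occupancy.
    """
    S = model.K
    counts = np.bincount(model.assignments, minlength=S)
    if np.any(counts == 0):
        raise ValueError("cannot initialise from a partition with an empty cluster")
    variances = np.maximum(model.per_cluster_variance, var_floor)
    transition = _sticky_transition(S, self_transition)
    return HMMParams(
        means=model.centers.copy(),
        variances=variances,
        transition=transition,
        initial=counts / counts.sum(),
    )


def _sticky_transition(S: int, self_transition: float) -> np.ndarray:
    if S == 1:
        return np.ones((1, 1))
    T = np.full((S, S), (1.0 - self_transition) / (S - 1))
    np.fill_diagonal(T, self_transition)
    return T


def init_from_prior(
    scores,
    S: int,
    hyper: PriorHyperparams | None = None,
    seed: int = 0,
    self_transition: float = 0.9,
    max_retries: int = 100,
) -> HMMParams:
    """Random HMM initial guess from the semi-conjugate hierarchical prior.

    Per state and mark, sigma2 ~ scaled-Inv-chi2(nu_k) with E[sigma2] = s2_k,
    then mu ~ N(theta_k, s2_k).  Deterministic given ``seed``.
    """
    X = _as_matrix(scores)[0]
    hyper = hyper or PriorHyperparams.from_scores(X)
    m = X.shape[1]
    rng = np.random.default_rng(seed)
    # scaled-Inv-chi2(nu, tau2) == nu * tau2 / chi2(nu); E = nu*tau2/(nu-2)
    tau2 = hyper.s2 * (hyper.nu - 2.0) / hyper.nu
    variances = np.empty((S, m))
    for _ in range(max_retries):
        draws = hyper.nu * tau2 / rng.chisquare(hyper.nu, size=(S, m))
        if np.all(draws > 0):
            variances = draws
            break
    else:  # pragma: no cover - chi-square draws are a.s. positive
        raise RuntimeError("could not draw positive variances from the prior")
    means = rng.normal(hyper.theta, np.sqrt(hyper.s2), size=(S, m))
    return HMMParams(
        means=means,
        variances=variances,
        transition=_sticky_transition(S, self_transition),
        initial=np.full(S, 1.0 / S),
    )


def _forward_backward_chain(logB: np.ndarray, params: HMMParams):
    """Scaled forward-backward on one chain.

    Returns (gamma, xi_sum, loglik): posteriors (L, S), summed two-slice
    posteriors (S, S), and the chain log-likelihood from the scaling factors.
    """
    L, S = logB.shape
    T, pi = params.transition, params.initial
    shift = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - shift)  # row-rescaled emission likelihoods

    alpha = np.empty((L, S))
    c = np.empty(L)  # scaling factors (include the per-row shift separately)
    a = pi * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise FloatingPointError("zero forward mass; emissions underflowed")
    alpha[0] = a / c[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ T) * B[t]
        c[t] = a.sum()
        if c[t] <= 0:
            raise FloatingPointError("zero forward mass; emissions underflowed")
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shift.sum())

    beta = np.empty((L, S))
    beta[-1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(L - 2, -1, -1):
        beta[t] = (T @ (B[t + 1] * beta[t + 1])) / c[t + 1]
        xi_sum += np.outer(alpha[t], B[t + 1] * beta[t + 1] / c[t + 1]) * T
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, xi_sum, loglik


def forward_backward(scores, params: HMMParams) -> tuple[np.ndarray, float]:
    """Posterior state probabilities and total log-likelihood.

    Chains (chromosomes) are decoded independently; the returned posterior
    stacks them in gene order and every row sums to 1.
    """
    X, breaks = _as_matrix(scores)
    logB = _log_emissions(X, params)
    posts, loglik = [], 0.0
    for sl in _chain_slices(len(X), breaks):
        gamma, _, ll = _forward_backward_chain(logB[sl], params)
        posts.append(gamma)
        loglik += ll
    return np.vstack(posts), loglik


def viterbi(scores, params: HMMParams) -> np.ndarray:
    """Most probable joint state path, per chain, in log space."""
    X, breaks = _as_matrix(scores)
    logB = _log_emissions(X, params)
    with np.errstate(divide="ignore"):
        logT = np.log(params.transition)
        logpi = np.log(params.initial)
    path = np.empty(len(X), dtype=np.int64)
    for sl in _chain_slices(len(X), breaks):
        chunk = logB[sl]
        L, S = chunk.shape
        delta = logpi + chunk[0]
        back = np.empty((L, S), dtype=np.int64)
        for t in range(1, L):
            cand = delta[:, None] + logT  # (from, to)
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(S)] + chunk[t]
        states = np.empty(L, dtype=np.int64)
        states[-1] = int(np.argmax(delta))
        for t in range(L - 2, -1, -1):
            states[t] = back[t + 1][states[t + 1]]
        path[sl] = states
    return path


def em_fit(
    scores,
    init: HMMParams,
    tol: float = 1e-4,
    max_iter: int = 500,
    var_floor: float = 1e-6,
) -> tuple[HMMParams, np.ndarray]:
    """Baum-Welch EM for the diagonal-Gaussian HMM.

    Sufficient statistics are pooled across chains; chains shorter than two
    genes are skipped with a warning.  Stops when the total log-likelihood
    improves by less than ``tol`` or after ``max_iter`` iterations.  Returns
    the fitted parameters and the per-iteration log-likelihood trace (which is
    non-decreasing up to floating-point slack).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    X, breaks = _as_matrix(scores)
    slices = []
    for sl in _chain_slices(len(X), breaks):
        if sl.stop - sl.start < 2:
            warnings.warn(f"skipping chain of length {sl.stop - sl.start} in EM")
            continue
        slices.append(sl)
    if not slices:
        raise ValueError("no chain with >= 2 genes to fit")

    params = init
    S = params.n_states
    trace: list[float] = []
    for _ in range(max_iter):
        logB = _log_emissions(X, params)
        gamma_all = np.zeros((len(X), S))
        xi_sum = np.zeros((S, S))
        start_gamma = np.zeros(S)
        loglik = 0.0
        for sl in slices:
            gamma, xi, ll = _forward_backward_chain(logB[sl], params)
            gamma_all[sl] = gamma
            xi_sum += xi
            start_gamma += gamma[0]
            loglik += ll
        trace.append(loglik)

        weights = gamma_all.sum(axis=0)  # (S,)
        means = (gamma_all.T @ X) / weights[:, None]
        ex2 = (gamma_all.T @ (X**2)) / weights[:, None]
        variances = np.maximum(ex2 - means**2, var_floor)
        transition = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        initial = start_gamma / start_gamma.sum()
        params = HMMParams(
            means=means, variances=variances, transition=transition,
            initial=initial, state_labels=params.state_labels, marks=params.marks,
        )
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            break
    return params, np.asarray(trace)


def decode(scores, params: HMMParams) -> Decoding:
    """Run both decoders and package their joint result."""
    posterior, loglik = forward_backward(scores, params)
    return Decoding(
        viterbi_path=viterbi(scores, params),
        posterior=posterior,
        map_path=np.argmax(posterior, axis=1),
        loglik=loglik,
    )


def decode_agreement(path_a: np.ndarray, path_b: np.ndarray) -> float:
    """Fraction of positions where two decodings assign the same state."""
    path_a, path_b = np.asarray(path_a), np.asarray(path_b)
    if path_a.shape != path_b.shape:
        raise ValueError("paths must have equal length")
    return float(np.mean(path_a == path_b))


def assign_state_labels(params: HMMParams, marks: list[str] | None = None) -> HMMParams:
    """Attach semantic labels to fitted states by their mark profile.

    "active": largest H3K4me3 mean; "null": smallest total mean; remaining
    states are "non-active" (largest H3K27me3 among them when S = 3).  With
    marks unnamed, positional indices 1 (H3K4me3) and 2 (H3K27me3) are used,
    matching the canonical five-mark ordering.
    """
    marks = marks or params.marks
    if marks is not None:
        k4 = marks.index("H3K4me3") if "H3K4me3" in marks else 1
    else:
        k4 = 1 if params.n_marks > 1 else 0
    S = params.n_states
    labels = [""] * S
    active = int(np.argmax(params.means[:, k4]))
    labels[active] = "active"
    rest = [s for s in range(S) if s != active]
    if rest:
        null = min(rest, key=lambda s: params.means[s].sum())
        if S > 2:
            labels[null] = "null"
            for s in rest:
                if not labels[s]:
                    labels[s] = "non-active"
        else:
            labels[null] = "non-active"
    params.state_labels = labels
    return params
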