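"""Synthetic data generation and the state-recovery simulation study.

The generator's reference emission parameters are the per-state means and
variances of the five histone marks (H3K4me2, H3K4me3, H3K27me3, H3K9me3,
H3K36me3) estimated from mouse embryonic-stem-cell ChIP-seq data for the two-
and three-state models: an "active" state (high H3K4me2/3, low H3K27me3), a
"non-active" state (high H3K27me3) and, in the three-state model, a "null"
state with uniformly low signal.

The accuracy experiment reproduces the pipeline's self-check: simulate
domain-structured scores from those parameters, run the full k-means -> EM ->
Viterbi inference blind to the truth, align the inferred labels to the true
ones by the accuracy-maximising permutation, and report the fraction of genes
whose state is recovered.  Doubling the emission variances probes robustness
to noisier data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cluster import kmeans_fit
from .hmm import HMMParams, em_fit, init_from_clusters, viterbi
from .io_formats import GeneAnnotation, write_gene_annotation_bed12
from .scores import GeneScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MARKS",
    "TWO_STATE_LABELS",
    "THREE_STATE_LABELS",
    "reference_params",
    "SimulationTruth",
    "AccuracyReport",
    "simulate_scores",
    "simulate_blobs",
    "match_states",
    "infer_states",
    "run_accuracy_experiment",
    "make_fixture_bundle",
]

MARKS = ["H3K4me2", "H3K4me3", "H3K27me3", "H3K9me3", "H3K36me3"]

TWO_STATE_LABELS = ("non-active", "active")
_TWO_STATE_MEANS = np.array(
    [
        [1.453, 3.580, 2.089, 0.416, 0.352],  # non-active
        [4.653, 14.586, 0.740, 0.398, 1.685],  # active
    ]
)
_TWO_STATE_VARIANCES = np.array(
    [
        [2.492, 18.538, 7.346, 0.112, 0.176],
        [4.836, 60.923, 0.209, 0.0297, 5.266],
    ]
)

THREE_STATE_LABELS = ("non-active", "null", "active")
_THREE_STATE_MEANS = np.array(
    [
        [2.844, 7.020, 3.623, 0.458, 0.391],  # non-active
        [0.216, 0.499, 0.743, 0.383, 0.367],  # null
        [4.523, 14.205, 0.695, 0.394, 1.615],  # active
    ]
)
_THREE_STATE_VARIANCES = np.array(
    [
        [2.106, 20.585, 10.534, 0.194, 0.241],
        [0.083, 0.186, 0.412, 0.038, 0.190],
        [4.934, 62.267, 0.130, 0.027, 5.232],
    ]
)


def reference_params(n_states: int, mean_domain_len: float = 10.0) -> HMMParams:
    """The reference mouse-ES emission parameters as an HMM.

    The transition matrix is geometric-run: self-transition 1 - 1/L for mean
    domain length L, off-diagonal mass uniform; initial distribution uniform.
    """
    if n_states == 2:
        means, variances, labels = _TWO_STATE_MEANS, _TWO_STATE_VARIANCES, TWO_STATE_LABELS
    elif n_states == 3:
        means, variances, labels = _THREE_STATE_MEANS, _THREE_STATE_VARIANCES, THREE_STATE_LABELS
    else:
        raise ValueError("reference parameters exist for 2 or 3 states only")
    if mean_domain_len <= 1:
        raise ValueError("mean_domain_len must exceed 1")
    S = n_states
    stay = 1.0 - 1.0 / mean_domain_len
    T = np.full((S, S), (1.0 - stay) / (S - 1))
    np.fill_diagonal(T, stay)
    return HMMParams(
        means=means.copy(),
        variances=variances.copy(),
        transition=T,
        initial=np.full(S, 1.0 / S),
        state_labels=list(labels),
        marks=list(MARKS),
    )


def simulate_blobs(
    n_points: int = 300, noise_sd: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Three well-separated spherical Gaussian blobs centred at the reference
    three-state mean vectors (cluster-number-selection fixture).

    Spherical unit noise keeps the blobs separable; the full per-state
    variances are deliberately not used here because their strong
    heterogeneity makes the within-cluster dispersion keep dropping as K
    grows, so no cluster-number criterion peaks at 3 on such data.

    Returns (points, true labels).
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=n_points)
    X = rng.normal(_THREE_STATE_MEANS[labels], noise_sd)
    return X, labels


@dataclass
class SimulationTruth:
    """Simulated scores paired with the generating states and parameters."""

    scores: GeneScoreMatrix
    true_states: np.ndarray
    generating_params: HMMParams
    variance_multiplier: float
    seed: int


@dataclass
class AccuracyReport:
    """Label-matched state-recovery accuracy, aggregated over replicates."""

    accuracy: float  # mean over replicates
    confusion: np.ndarray  # (S, S) counts summed over replicates, true x inferred
    n_genes: int  # total genes across replicates
    label_matching: list[tuple[int, ...]]  # per-replicate inferred->true permutation
    per_replicate: np.ndarray  # per-replicate accuracies


def simulate_scores(
    params: HMMParams,
    n_genes: int,
    mean_domain_len: float | None = None,
    variance_multiplier: float = 1.0,
    seed: int = 0,
    clip_at_zero: bool = False,
) -> SimulationTruth:
    """Simulate one chain of domain-structured scores from the model.

    True states follow the Markov chain (self-transition 1 - 1/L when
    ``mean_domain_len`` L is given, otherwise ``params.transition``); each
    gene's scores are independent Gaussians with its state's means and
    ``variance_multiplier`` times its state's variances.  ``clip_at_zero``
    optionally clips negative draws to 0 to mimic non-negative tag averages;
    the default leaves the Gaussian model exact.
    """
    if variance_multiplier < 0:
        raise ValueError("variance_multiplier must be non-negative")
    S, m = params.n_states, params.n_marks
    T = params.transition
    if mean_domain_len is not None:
        if mean_domain_len <= 1:
            raise ValueError("mean_domain_len must exceed 1")
        stay = 1.0 - 1.0 / mean_domain_len
        T = np.full((S, S), (1.0 - stay) / max(S - 1, 1))
        np.fill_diagonal(T, stay if S > 1 else 1.0)
    rng = np.random.default_rng(seed)
    states = np.empty(n_genes, dtype=np.int64)
    states[0] = rng.choice(S, p=params.initial)
    for t in range(1, n_genes):
        states[t] = rng.choice(S, p=T[states[t - 1]])
    sd = np.sqrt(params.variances * variance_multiplier)
    X = rng.normal(params.means[states], sd[states])
    if clip_at_zero:
        X = np.maximum(X, 0.0)
    matrix = GeneScoreMatrix(
        gene_ids=[f"g{i:06d}" for i in range(n_genes)],
        marks=list(params.marks or [f"mark{j}" for j in range(m)]),
        scores=X,
    )
    return SimulationTruth(matrix, states, params, variance_multiplier, seed)


def match_states(
    true_states: np.ndarray, inferred_states: np.ndarray, n_states: int
) -> tuple[tuple[int, ...], np.ndarray, float]:
    """Align inferred labels to true labels by the accuracy-maximising
    permutation (Hungarian assignment on the confusion matrix).

    Returns (permutation mapping inferred -> true, relabelled confusion matrix
    with rows = true and columns = matched inferred, accuracy).
    """
    true_states = np.asarray(true_states)
    inferred_states = np.asarray(inferred_states)
    if true_states.shape != inferred_states.shape:
        raise ValueError("state vectors must have equal length")
    C = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(C, (true_states, inferred_states), 1)
    rows, cols = linear_sum_assignment(-C)  # rows is arange(S)
    perm = np.empty(n_states, dtype=np.int64)
    perm[cols] = rows  # inferred label -> true label
    matched = C[:, cols]  # column j = inferred state matched to true state j
    accuracy = float(C[rows, cols].sum() / len(true_states))
    return tuple(int(p) for p in perm), matched, accuracy


def infer_states(
    scores: GeneScoreMatrix,
    n_states: int,
    seed: int = 0,
    n_restart: int = 10,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, HMMParams]:
    """The standard inference route: k-means init -> EM -> Viterbi."""
    km = kmeans_fit(scores, K=n_states, seed=seed, n_restart=n_restart)
    init = init_from_clusters(km)
    fitted, _ = em_fit(scores, init, tol=tol, max_iter=max_iter)
    return viterbi(scores, fitted), fitted


def run_accuracy_experiment(
    n_states: int,
    variance_multiplier: float = 1.0,
    n_genes: int = 5000,
    n_reps: int = 10,
    mean_domain_len: float = 10.0,
    seed: int = 0,
    max_em_retries: int = 3,
) -> AccuracyReport:
    """State-recovery accuracy of the full inference on simulated data.

    Each replicate simulates ``n_genes`` genes from the reference parameters
    (variances scaled by ``variance_multiplier``), infers states blind to the
    truth, label-matches, and scores accuracy; the report averages over
    ``n_reps`` replicates.  A failed EM fit in a replicate is retried with a
    fresh seed (logged).
    """
    params = reference_params(n_states, mean_domain_len)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_reps)]
    accs = np.empty(n_reps)
    confusion = np.zeros((n_states, n_states), dtype=np.int64)
    perms: list[tuple[int, ...]] = []
    for r, rep_seed in enumerate(child_seeds):
        for attempt in range(max_em_retries):
            try:
                truth = simulate_scores(
                    params, n_genes, mean_domain_len, variance_multiplier,
                    seed=rep_seed + attempt,
                )
                path, _ = infer_states(truth.scores, n_states, seed=rep_seed + attempt)
                break
            except (FloatingPointError, ValueError) as exc:  # pragma: no cover
                logger.warning("replicate %d attempt %d failed (%s); re-seeding", r, attempt, exc)
        else:  # pragma: no cover
            raise RuntimeError(f"replicate {r} failed {max_em_retries} times")
        perm, C, acc = match_states(truth.true_states, path, n_states)
        accs[r] = acc
        confusion += C
        perms.append(perm)
    return AccuracyReport(
        accuracy=float(accs.mean()),
        confusion=confusion,
        n_genes=n_genes * n_reps,
        label_matching=perms,
        per_replicate=accs,
    )


def make_fixture_bundle(outdir: str | Path, scale: str = "tiny", seed: int = 0) -> dict[str, Path]:
    """Write a self-consistent synthetic dataset for end-to-end runs.

    Genes on three chromosomes carry three-state domain structure; per-mark
    tag tracks are Poisson-scattered in each gene's scoring window at its
    state's mean rate per bin, so summary scoring recovers means near the
    generating ones.  Also writes a repeat mask covering a few promoters, an
    expression matrix whose focal ("ES") column tracks the active state, a GO
    table with domain-shared terms, and a truth table of the generating
    choices.  Byte-identical output for identical seeds.
    """
    sizes = {"tiny": 40, "small": 150, "full": 700}
    if scale not in sizes:
        raise ValueError(f"scale must be one of {sorted(sizes)}")
    per_chrom = sizes[scale]
    chroms = ["chr1", "chr2", "chr3"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    params = reference_params(3, mean_domain_len=8.0)

    gene_spacing, cds_len, flank = 10_000, 4_000, 2_000
    genes: list[GeneAnnotation] = []
    states_all: list[int] = []
    for chrom in chroms:
        # simulate the chain of true states for this chromosome
        s = np.empty(per_chrom, dtype=np.int64)
        s[0] = rng.choice(3, p=params.initial)
        for t in range(1, per_chrom):
            s[t] = rng.choice(3, p=params.transition[s[t - 1]])
        states_all.extend(int(v) for v in s)
        for i in range(per_chrom):
            start = 5_000 + i * gene_spacing
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else start + cds_len
            genes.append(
                GeneAnnotation(
                    gene_id=f"{chrom}_g{i:04d}", chrom=chrom, strand=strand,
                    tss=tss, cds_start=start, cds_end=start + cds_len,
                )
            )
    states = np.asarray(states_all)

    paths: dict[str, Path] = {}
    ann_path = outdir / "genes.bed"
    write_gene_annotation_bed12(genes, ann_path)
    paths["annotation"] = ann_path

    from .scores import coding_3prime_window, promoter_window

    bin_width = 100
    for j, mark in enumerate(MARKS):
        rows: list[tuple[str, int]] = []
        for gene, state in zip(genes, states):
            window = (
                coding_3prime_window(gene, flank)
                if mark == "H3K36me3"
                else promoter_window(gene, flank)
            )
            _, wstart, wend = window
            n_bins = (wend - wstart) // bin_width
            rate = max(params.means[state, j], 0.0)
            counts = rng.poisson(rate, size=n_bins)
            for b, c in enumerate(counts):
                if c:
                    offs = np.sort(rng.integers(0, bin_width, size=c))
                    rows.extend((gene.chrom, int(wstart + b * bin_width + o)) for o in offs)
        mark_path = outdir / f"{mark}.bed"
        with open(mark_path, "w") as fh:
            for chrom, pos in sorted(rows):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
        paths[mark] = mark_path

    # repeat mask: fully cover ~5% of promoters so the >50% rule fires
    rmsk_path = outdir / "rmsk.bed"
    n_masked = max(1, len(genes) // 20)
    masked_idx = sorted(rng.choice(len(genes), size=n_masked, replace=False))
    with open(rmsk_path, "w") as fh:
        for i in masked_idx:
            _, wstart, wend = promoter_window(genes[i], flank)
            fh.write(f"{genes[i].chrom}\t{wstart}\t{wend}\n")
    paths["repeats"] = rmsk_path

    # expression across 23 cell lines; the focal ES column follows the state
    lines = ["ES"] + [f"line{i:02d}" for i in range(1, 23)]
    state_shift = {0: -1.0, 1: -1.5, 2: 2.0}  # non-active, null, active
    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(lines) + "\n")
        for gene, state in zip(genes, states):
            base = rng.normal(0.0, 1.0, size=len(lines))
            base[0] += state_shift[int(state)]
            fh.write(gene.gene_id + "\t" + "\t".join(f"{v:.4f}" for v in base) + "\n")
    paths["expression"] = expr_path

    # GO: domains (same-state runs) share terms from a 20-term vocabulary
    vocab = [f"GO:{i:07d}" for i in range(1, 21)]
    go_path = outdir / "go.tsv"
    with open(go_path, "w") as fh:
        fh.write("gene_id\tgo_term\n")
        run_terms: list[str] = []
        prev = (None, None)
        for gene, state in zip(genes, states):
            if (gene.chrom, int(state)) != prev:
                run_terms = list(rng.choice(vocab, size=3, replace=False))
                prev = (gene.chrom, int(state))
            terms = set(run_terms)
            if rng.random() < 0.3:
                terms.add(str(rng.choice(vocab)))
            for t in sorted(terms):
                fh.write(f"{gene.gene_id}\t{t}\n")
    paths["go"] = go_path

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene_id\tchrom\ttrue_state\tstate_label\n")
        for gene, state in zip(genes, states):
            fh.write(f"{gene.gene_id}\t{gene.chrom}\t{int(state)}\t{THREE_STATE_LABELS[state]}\n")
    paths["truth"] = truth_path
    return paths
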