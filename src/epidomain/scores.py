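"""Gene-level summary scores from tag tracks.

Each gene is reduced to one scalar per histone-modification mark: the average
tag count per fixed-width bin over a mark-specific window.  Promoter-peaked
marks (H3K4me2/3, H3K9me3, H3K27me3) use a symmetric window around the TSS;
H3K36me3, which accumulates toward the 3' end of transcribed genes, uses the
terminal stretch of the coding region.  Genes whose promoter or 3'-coding
window is more than half repeat-masked are excluded, and the hidden Markov
chain runs over the retained genes only (excluded genes' neighbours become
adjacent).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, RepeatMask, TagTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScoreMatrix",
    "ScoreConfig",
    "promoter_window",
    "coding_3prime_window",
    "summarize",
    "repeat_fraction",
    "build_score_matrix",
]


@dataclass
class GeneScoreMatrix:
    """Per-gene summary-score vectors in chromosome order.

    ``chrom_breaks`` lists the row index at which each chromosome's chain
    starts (always beginning with 0); the HMM treats each chain independently.
    """

    gene_ids: list[str]
    marks: list[str]
    scores: np.ndarray  # (n_genes, n_marks), float
    chrom_breaks: np.ndarray = None  # chain start indices, first element 0
    chrom_names: list[str] | None = None  # one name per chain, optional
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D (genes x marks) array")
        n, m = self.scores.shape
        if len(self.gene_ids) != n or len(self.marks) != m:
            raise ValueError("gene_ids / marks lengths do not match the score array")
        if self.chrom_breaks is None:
            self.chrom_breaks = np.array([0], dtype=np.int64)
        self.chrom_breaks = np.asarray(self.chrom_breaks, dtype=np.int64)
        if n and (self.chrom_breaks[0] != 0 or np.any(np.diff(self.chrom_breaks) <= 0)):
            raise ValueError("chrom_breaks must start at 0 and strictly increase")
        if np.isnan(self.scores).any():
            raise ValueError("score matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_marks(self) -> int:
        return self.scores.shape[1]

    def chains(self) -> list[slice]:
        """Per-chromosome row slices, in order."""
        bounds = list(self.chrom_breaks) + [self.n_genes]
        return [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: gene_id, optional chrom column, one column per mark."""
        df = pd.DataFrame(self.scores, columns=self.marks)
        df.insert(0, "gene_id", self.gene_ids)
        if self.chrom_names is not None:
            chrom_col = np.empty(self.n_genes, dtype=object)
            for name, sl in zip(self.chrom_names, self.chains()):
                chrom_col[sl] = name
            df.insert(1, "chrom", chrom_col)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path | io.TextIOBase) -> "GeneScoreMatrix":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "gene_id":
            raise ValueError("score TSV must start with a gene_id column")
        gene_ids = df["gene_id"].astype(str).tolist()
        if len(df.columns) > 1 and df.columns[1] == "chrom":
            chroms = df["chrom"].astype(str).to_numpy()
            marks = list(df.columns[2:])
            breaks = [0] + [i for i in range(1, len(chroms)) if chroms[i] != chroms[i - 1]]
            chrom_names = [chroms[b] for b in breaks]
            values = df[marks].to_numpy(dtype=float)
            return cls(gene_ids, marks, values, np.asarray(breaks), chrom_names)
        marks = list(df.columns[1:])
        return cls(gene_ids, marks, df[marks].to_numpy(dtype=float))


@dataclass
class ScoreConfig:
    """Windowing parameters for summary scoring.

    flank: promoter half-width around the TSS (bp).
    span: length of the 3'-terminal coding window (bp).
    bin_width: averaging bin (bp); the score is mean tags per bin.
    three_prime_marks: marks scored over the 3'-coding window; all other
        marks use the promoter window.
    """

    flank: int = 2000
    span: int = 2000
    bin_width: int = 100
    three_prime_marks: tuple[str, ...] = ("H3K36me3",)
    max_repeat_fraction: float = 0.5


def promoter_window(gene: GeneAnnotation, flank: int = 2000) -> tuple[str, int, int]:
    """Window [tss - flank, tss + flank), clipped at 0 with a logged warning."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    start = gene.tss - flank
    if start < 0:
        logger.warning(
            "promoter window of %s clipped at chromosome start (tss=%d, flank=%d)",
            gene.gene_id, gene.tss, flank,
        )
        start = 0
    return gene.chrom, start, gene.tss + flank


def coding_3prime_window(gene: GeneAnnotation, span: int = 2000) -> tuple[str, int, int]:
    """The last min(span, CDS length) bp of the coding region on the
    transcribed strand."""
    if span <= 0:
        raise ValueError("span must be positive")
    length = min(span, gene.cds_end - gene.cds_start)
    if gene.strand == "+":
        return gene.chrom, gene.cds_end - length, gene.cds_end
    return gene.chrom, gene.cds_start, gene.cds_start + length


def summarize(tags: TagTrack, window: tuple[str, int, int], bin_width: int = 100) -> float:
    """Average tag count per ``bin_width`` bin over the window.

    Tags are assigned to bins by their start coordinate, so the mean over bins
    equals (tags in window) / (number of bins).  The last bin may be partial.
    """
    chrom, start, end = window
    if end <= start:
        raise ValueError(f"empty window [{start}, {end})")
    n_bins = int(np.ceil((end - start) / bin_width))
    starts = tags.starts(chrom)
    count = int(np.searchsorted(starts, end, "left") - np.searchsorted(starts, start, "left"))
    return count / n_bins


def repeat_fraction(window: tuple[str, int, int], mask: RepeatMask) -> float:
    """Fraction of the window covered by (merged) repeat intervals."""
    chrom, start, end = window
    if end <= start:
        raise ValueError(f"empty window [{start}, {end})")
    return mask.overlap(chrom, start, end) / (end - start)


def build_score_matrix(
    genes: list[GeneAnnotation],
    tracks: dict[str, TagTrack],
    mask: RepeatMask | None = None,
    config: ScoreConfig | None = None,
) -> tuple[GeneScoreMatrix, list[str]]:
    """Score every gene for every mark and apply the repeat-content filter.

    A gene is excluded iff more than ``max_repeat_fraction`` of either its
    promoter window or its 3'-coding window is repeat-masked.  Rows follow
    chromosome order (the input gene order); chain breaks are set at
    chromosome boundaries.  Returns the matrix and the excluded gene ids.
    """
    config = config or ScoreConfig()
    mask = mask or RepeatMask()
    marks = list(tracks)
    for mark in marks:
        if tracks[mark].mark_name != mark:
            raise ValueError(f"track registered under {mark!r} is named {tracks[mark].mark_name!r}")

    excluded: list[str] = []
    kept: list[GeneAnnotation] = []
    rows: list[np.ndarray] = []
    for gene in genes:
        prom = promoter_window(gene, config.flank)
        three = coding_3prime_window(gene, config.span)
        if (
            repeat_fraction(prom, mask) > config.max_repeat_fraction
            or repeat_fraction(three, mask) > config.max_repeat_fraction
        ):
            excluded.append(gene.gene_id)
            continue
        kept.append(gene)
        row = np.empty(len(marks))
        for j, mark in enumerate(marks):
            window = three if mark in config.three_prime_marks else prom
            row[j] = summarize(tracks[mark], window, config.bin_width)
        rows.append(row)

    if not kept:
        raise ValueError("all genes were excluded by the repeat filter")
    chroms = [g.chrom for g in kept]
    breaks = [0] + [i for i in range(1, len(kept)) if chroms[i] != chroms[i - 1]]
    matrix = GeneScoreMatrix(
        gene_ids=[g.gene_id for g in kept],
        marks=marks,
        scores=np.vstack(rows),
        chrom_breaks=np.asarray(breaks),
        chrom_names=[chroms[b] for b in breaks],
    )
    logger.info(
        "scored %d genes (%d excluded by repeat filter) for %d marks",
        matrix.n_genes, len(excluded), matrix.n_marks,
    )
    return matrix, excluded
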