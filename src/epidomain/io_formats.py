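"""Readers and writers for the interval and table formats the pipeline touches.

All coordinates are 0-based, half-open (the BED convention), both on disk and
in memory.  Gene order along a chromosome — the order the hidden Markov chain
runs in — is the order of transcription start sites (TSS).  Plain and
gzip-compressed (``.gz``) files are both accepted everywhere.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np

__all__ = [
    "GeneAnnotation",
    "TagTrack",
    "RepeatMask",
    "read_gene_annotation",
    "write_gene_annotation_bed12",
    "read_tag_track",
    "write_tag_track",
    "read_repeat_mask",
    "write_domains_bed",
    "read_expression_tsv",
    "read_go_annotation",
]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: identifier, location, strand and coding interval.

    ``tss`` is the strand-resolved transcription start site (5' end).
    ``order_index`` is the gene's rank along its chromosome when sorted by TSS.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tss: int
    cds_start: int
    cds_end: int
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_start < self.cds_end:
            raise ValueError(
                f"gene {self.gene_id}: cds_start must be < cds_end "
                f"({self.cds_start} >= {self.cds_end})"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint [start, end) covering the TSS and coding region."""
        return min(self.tss, self.cds_start), max(self.tss, self.cds_end)


@dataclass
class TagTrack:
    """Sequenced-tag positions for one histone-modification mark.

    Tags are stored per chromosome as (start, end) interval arrays sorted by
    start coordinate; each interval counts once.  Tag membership in a scoring
    window is decided by the tag's start coordinate.
    """

    mark_name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # (k, 2) int arrays

    def __post_init__(self) -> None:
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative coordinate in tag track on {chrom}")
            order = np.argsort(arr[:, 0], kind="stable")
            self.intervals[chrom] = arr[order]

    @property
    def total_count(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def starts(self, chrom: str) -> np.ndarray:
        arr = self.intervals.get(chrom)
        return arr[:, 0] if arr is not None else np.empty(0, dtype=np.int64)


@dataclass
class RepeatMask:
    """Repeat-masked intervals, merged to disjoint runs per chromosome."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.intervals.items():
            self.intervals[chrom] = merge_intervals(np.asarray(arr, dtype=np.int64))

    def overlap(self, chrom: str, start: int, end: int) -> int:
        """Total masked basepairs inside [start, end)."""
        arr = self.intervals.get(chrom)
        if arr is None or not len(arr):
            return 0
        clipped = np.clip(arr, start, end)
        return int(np.maximum(clipped[:, 1] - clipped[:, 0], 0).sum())


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping [start, end) intervals into disjoint ones."""
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    if not len(arr):
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _finalize_genes(records: list[GeneAnnotation]) -> list[GeneAnnotation]:
    seen: set[str] = set()
    for g in records:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    records.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    out: list[GeneAnnotation] = []
    rank, prev_chrom = 0, None
    for g in records:
        if g.chrom != prev_chrom:
            rank, prev_chrom = 0, g.chrom
        out.append(
            GeneAnnotation(g.gene_id, g.chrom, g.strand, g.tss, g.cds_start, g.cds_end, rank)
        )
        rank += 1
    return out


def read_gene_annotation(path: str | Path, dialect: str = "bed12") -> list[GeneAnnotation]:
    """Read gene models from a BED12 file or a six-column TSV.

    BED12: ``thickStart``/``thickEnd`` are taken as the coding interval and the
    strand-resolved interval end as the TSS.  TSV: a header row with columns
    ``gene_id, chrom, strand, tss, cds_start, cds_end``.

    Returns genes sorted by (chrom, tss) with ``order_index`` assigned as the
    per-chromosome TSS rank.  Malformed rows and duplicate gene identifiers
    raise :class:`ValueError` naming the offending line.
    """
    if dialect not in ("bed12", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[GeneAnnotation] = []
    with _open_text(path) as fh:
        header_skipped = dialect != "tsv"
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if not header_skipped:
                header_skipped = True
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed12":
                    if len(fields) < 8:
                        raise ValueError("expected >= 8 BED12 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name, strand = fields[3], fields[5]
                    thick_start, thick_end = int(fields[6]), int(fields[7])
                    tss = start if strand == "+" else end
                    records.append(
                        GeneAnnotation(name, chrom, strand, tss, thick_start, thick_end)
                    )
                else:
                    if len(fields) < 6:
                        raise ValueError("expected 6 TSV columns")
                    records.append(
                        GeneAnnotation(
                            fields[0], fields[1], fields[2],
                            int(fields[3]), int(fields[4]), int(fields[5]),
                        )
                    )
            except (ValueError, IndexError) as exc:
                if "duplicate" in str(exc):
                    raise
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return _finalize_genes(records)


def write_gene_annotation_bed12(genes: list[GeneAnnotation], path: str | Path) -> None:
    """Write genes as BED12 rows (round-trips with :func:`read_gene_annotation`)."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            start, end = g.span
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(start), str(end), g.gene_id, "0", g.strand,
                        str(g.cds_start), str(g.cds_end), "0", "1",
                        str(end - start), "0",
                    ]
                )
                + "\n"
            )


def read_tag_track(path: str | Path, mark_name: str) -> TagTrack:
    """Read a BED-like (>= 3 column) file of tag positions for one mark."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}: invalid interval at line {lineno}: [{start}, {end})")
            per_chrom.setdefault(chrom, []).append((start, end))
    intervals = {
        c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in per_chrom.items()
    }
    return TagTrack(mark_name=mark_name, intervals=intervals)


def write_tag_track(track: TagTrack, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in sorted(track.intervals):
            for s, e in track.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_repeat_mask(path: str | Path) -> RepeatMask:
    """Read repeat-masked intervals from a BED3+ file (merged on load)."""
    track = read_tag_track(path, mark_name="repeat")
    return RepeatMask(intervals=dict(track.intervals))


def write_domains_bed(domains, genes: list[GeneAnnotation], path: str | Path) -> None:
    """Write domain calls as BED6 rows.

    The row span covers the genomic footprints of the domain's first and last
    genes; ``score`` is ``-10*log10(q)`` capped at 1000; ``name`` is the state
    label.  ``genes`` must be aligned with the gene indexing used by the calls
    (the retained-gene, chromosome-ordered list).
    """
    with _open_text(path, "wt") as fh:
        for dom in domains:
            members = genes[dom.start_gene_index : dom.end_gene_index + 1]
            chroms = {g.chrom for g in members}
            if len(chroms) != 1:
                raise ValueError(f"domain {dom.domain_id} spans chromosomes {sorted(chroms)}")
            start = min(g.span[0] for g in members)
            end = max(g.span[1] for g in members)
            q = dom.q_value
            if q is None or not np.isfinite(q):
                score = 0
            elif q <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * math.log10(q))))
            fh.write(
                f"{members[0].chrom}\t{start}\t{end}\t{dom.state_label}\t{max(score, 0)}\t.\n"
            )


def read_expression_tsv(path: str | Path):
    """Read a genes x cell-lines expression matrix (first column gene_id)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 cell lines")
    return df


def read_go_annotation(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a gene -> GO-term table: two tab-separated columns, one row per
    (gene, term) pair, header required."""
    mapping: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        next(fh)  # header
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, term = line.split("\t")[:2]
            mapping.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in mapping.items()}
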