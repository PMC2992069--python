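"""End-to-end pipeline: score -> gap -> fit -> decode -> call -> validate.

``RunConfig`` declares every input path, stage parameter and seed; a run
reads nothing else, writes every intermediate under the output directory and
finishes with a machine-readable manifest (stage list, parameters, input
digests, tool version), so identical configs over identical inputs reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .cluster import gap_statistic, kmeans_fit
from .differential import call_domain_changes, normalize_condition, transfer_decode
from .domains import calls_to_frame, global_model, score_domains, segment, summarize_domains
from .hmm import assign_state_labels, decode, em_fit, init_from_clusters
from .io_formats import (
    read_expression_tsv,
    read_gene_annotation,
    read_go_annotation,
    read_repeat_mask,
    read_tag_track,
    write_domains_bed,
)
from .scores import GeneScoreMatrix, ScoreConfig, build_score_matrix
from .validate import expression_z, go_accordance_test, within_domain_variance_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs, stage parameters and seeds for one pipeline run."""

    # inputs: either a precomputed score matrix, or annotation + tag tracks
    scores_tsv: str | None = None
    annotation: str | None = None
    annotation_dialect: str = "bed12"
    tag_tracks: dict[str, str] = field(default_factory=dict)  # mark -> BED path
    repeats: str | None = None
    expression: str | None = None
    focal_line: str = "ES"
    go_table: str | None = None
    alt_scores_tsv: str | None = None  # second condition, optional

    # scoring
    flank: int = 2000
    span: int = 2000
    bin_width: int = 100

    # model selection / fitting
    run_gap: bool = False
    k_max: int = 6
    n_boot: int = 100
    gap_sample_size: int | None = 2000
    n_states: int = 3
    n_restart: int = 10
    tol: float = 1e-4
    max_iter: int = 500

    # significance and validation
    fdr: float = 0.01
    n_perm: int = 1000
    normalization: str = "median_ratio"

    # seeds per stochastic stage
    seed_cluster: int = 7
    seed_gap: int = 7
    seed_perm: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _load_scores(config: RunConfig) -> tuple[GeneScoreMatrix, list[str]]:
    if config.scores_tsv:
        return GeneScoreMatrix.from_tsv(config.scores_tsv), []
    if not (config.annotation and config.tag_tracks):
        raise ValueError("config must give scores_tsv, or annotation plus tag_tracks")
    genes = read_gene_annotation(config.annotation, config.annotation_dialect)
    tracks = {mark: read_tag_track(path, mark) for mark, path in config.tag_tracks.items()}
    mask = read_repeat_mask(config.repeats) if config.repeats else None
    sc = ScoreConfig(flank=config.flank, span=config.span, bin_width=config.bin_width)
    return build_score_matrix(genes, tracks, mask, sc)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages, writing intermediates and a manifest.

    Any stage failure raises with the stage name prefixed.  Returns the
    output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name: str, fn):
        logger.info("stage %s ...", name)
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        stages.append({"stage": name, "outputs": {k: _digest(v) for k, v in outputs.items()}})
        return outputs

    state: dict = {}

    def do_score():
        matrix, excluded = _load_scores(config)
        state["matrix"] = matrix
        matrix.to_tsv(outdir / "scores.tsv")
        (outdir / "excluded_genes.txt").write_text("\n".join(excluded) + ("\n" if excluded else ""))
        return {"scores": outdir / "scores.tsv", "excluded": outdir / "excluded_genes.txt"}

    stage("score", do_score)
    matrix = state["matrix"]

    if config.run_gap:
        def do_gap():
            gr = gap_statistic(
                matrix, range(1, config.k_max + 1), n_boot=config.n_boot,
                seed=config.seed_gap, n_restart=config.n_restart,
                sample_size=config.gap_sample_size,
            )
            import pandas as pd

            pd.DataFrame(
                {"k": gr.k_values, "gap": gr.gap,
                 "expected_logW": gr.expected_logW, "observed_logW": gr.observed_logW}
            ).to_csv(outdir / "gap.tsv", sep="\t", index=False)
            state["best_k"] = gr.best_k
            return {"gap": outdir / "gap.tsv"}

        stage("gap", do_gap)

    def do_fit():
        km = kmeans_fit(matrix, K=config.n_states, seed=config.seed_cluster,
                        n_restart=config.n_restart)
        fitted, trace = em_fit(matrix, init_from_clusters(km),
                               tol=config.tol, max_iter=config.max_iter)
        fitted.marks = list(matrix.marks)
        assign_state_labels(fitted)
        state["model"], state["trace"] = fitted, trace
        fitted.to_json(outdir / "model.json")
        np.savetxt(outdir / "loglik_trace.txt", trace)
        return {"model": outdir / "model.json", "trace": outdir / "loglik_trace.txt"}

    stage("fit", do_fit)
    model = state["model"]

    def do_decode():
        dec = decode(matrix, model)
        state["decoding"] = dec
        import pandas as pd

        pd.DataFrame(
            {"gene_id": matrix.gene_ids,
             "viterbi_state": dec.viterbi_path,
             "viterbi_label": [model.label_of(s) for s in dec.viterbi_path],
             "map_state": dec.map_path,
             **{f"posterior_{model.label_of(s)}": dec.posterior[:, s]
                for s in range(model.n_states)}}
        ).to_csv(outdir / "states.tsv", sep="\t", index=False, float_format="%.6g")
        return {"states": outdir / "states.tsv"}

    stage("decode", do_decode)
    dec = state["decoding"]

    def do_call():
        calls = segment(dec.viterbi_path, matrix.chrom_breaks, matrix.chrom_names,
                        model.state_labels)
        calls = score_domains(calls, matrix, model, global_model(matrix), fdr=config.fdr)
        state["calls"] = calls
        calls_to_frame(calls).to_csv(outdir / "domains.tsv", sep="\t", index=False,
                                     float_format="%.6g")
        summarize_domains(calls).to_csv(outdir / "domain_summary.tsv", sep="\t")
        return {"domains": outdir / "domains.tsv", "summary": outdir / "domain_summary.tsv"}

    stage("call", do_call)
    calls = state["calls"]

    def do_validate():
        import pandas as pd

        rows = []
        for r in within_domain_variance_test(
            calls, matrix.scores, matrix.chrom_breaks,
            B=config.n_perm, seed=config.seed_perm, names=matrix.marks,
        ):
            rows.append({"test": "score_variance", "name": r.name, "observed": r.observed,
                         "null_mean": float(r.null_sample.mean()), "p_value": r.p_value,
                         "direction": r.direction, "B": r.B})
        if config.expression:
            expr = read_expression_tsv(config.expression)
            z = expression_z(expr, config.focal_line).reindex(matrix.gene_ids)
            keep = z.notna().to_numpy()
            if keep.all():
                r = within_domain_variance_test(
                    calls, z.to_numpy(), matrix.chrom_breaks,
                    B=config.n_perm, seed=config.seed_perm + 1, names=["expression_z"],
                )[0]
                rows.append({"test": "expression_variance", "name": r.name,
                             "observed": r.observed, "null_mean": float(r.null_sample.mean()),
                             "p_value": r.p_value, "direction": r.direction, "B": r.B})
            else:
                logger.warning("expression matrix misses %d scored genes; skipping "
                               "expression coherence", int((~keep).sum()))
        if config.go_table:
            go = read_go_annotation(config.go_table)
            r = go_accordance_test(calls, go, matrix.gene_ids, matrix.chrom_breaks,
                                   B=config.n_perm, seed=config.seed_perm + 2)
            rows.append({"test": "go_accordance", "name": r.name, "observed": r.observed,
                         "null_mean": float(r.null_sample.mean()), "p_value": r.p_value,
                         "direction": r.direction, "B": r.B})
        pd.DataFrame(rows).to_csv(outdir / "validation.tsv", sep="\t", index=False,
                                  float_format="%.6g")
        return {"validation": outdir / "validation.tsv"}

    stage("validate", do_validate)

    if config.alt_scores_tsv:
        def do_compare():
            import pandas as pd

            alt = GeneScoreMatrix.from_tsv(config.alt_scores_tsv)
            alt = normalize_condition(alt, matrix, method=config.normalization)
            alt_path = transfer_decode(alt, model)
            comparison = call_domain_changes(
                [c for c in calls if c.significant], dec.viterbi_path, alt_path,
                model.state_labels,
            )
            recs = []
            for dc in comparison.domain_changes:
                for (a, b, rs, as_), t in zip(dc.subdomains, dc.transition_types):
                    recs.append({"domain_id": dc.domain_id, "changed": dc.changed,
                                 "sub_start": a, "sub_end": b,
                                 "ref_state": model.label_of(rs),
                                 "alt_state": model.label_of(as_), "transition": t})
            pd.DataFrame(recs).to_csv(outdir / "changes.tsv", sep="\t", index=False)
            return {"changes": outdir / "changes.tsv"}

        stage("compare", do_compare)

    if config.annotation:
        genes = read_gene_annotation(config.annotation, config.annotation_dialect)
        retained = {g for g in matrix.gene_ids}
        aligned = [g for g in genes if g.gene_id in retained]
        write_domains_bed([c for c in calls if c.significant], aligned, outdir / "domains.bed")

    manifest = {
        "tool": "epidomain",
        "version": _version,
        "config": asdict(config),
        "stages": stages,
        "inputs": {
            k: _digest(v)
            for k, v in {
                "scores_tsv": config.scores_tsv,
                "annotation": config.annotation,
                "repeats": config.repeats,
                "expression": config.expression,
                "go_table": config.go_table,
                "alt_scores_tsv": config.alt_scores_tsv,
                **{f"track:{m}": p for m, p in config.tag_tracks.items()},
            }.items()
            if v
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
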