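"""End-to-end run orchestration: preprocess -> bicluster -> enrich.

A run consumes a directory of per-study TSV triples
(``<sid>_expr.tsv``, ``<sid>_meta.tsv``, ``<sid>_annot.tsv``), writes
a merged fold-change matrix, bicluster JSON/GMT, enrichment tables and
a manifest into a write-once run directory. The manifest records the
full configuration (with a provenance note per default), the seed,
SHA-256 digests of all inputs and the library versions, so a run can
be reproduced bit-for-bit on the same platform.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io_preprocess import (
    PreprocessConfig,
    merge_studies,
    preprocess_study,
    read_expression_table,
    read_merged_matrix,
    write_merged_matrix,
)
from .biclustering import bicluster_both_directions, write_run_json
from .enrichment import enrich_all
from .gmt import biclusters_to_gmt_sets, read_gmt, write_gmt
from .synthetic import read_exposure_tsv

logger = logging.getLogger(__name__)

#: why each default is what it is (emitted into the manifest)
PROVENANCE = {
    "cutoff_fold": "two-fold up/down regulation cutoff for the binary matrices",
    "min_rows": "minimum genes per bicluster (15)",
    "min_cols": "minimum conditions per bicluster (5)",
    "max_cols": "maximum conditions per bicluster (15)",
    "log2_input": "inputs are assumed already log2; enable for raw-scale data",
    "quantile": "generic quantile normalization, off unless requested",
    "background": "enrichment background = all genes, set members included",
    "alternative": "two-sided Welch p-value",
    "adjust": "unadjusted p-values by default; BH optional",
    "collapse": "median collapse of technical replicates, probes per symbol and biological replicates",
}


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run.

    Defaults reproduce the standard settings: already-log2 input,
    median collapse, fold cutoff 2.0, bicluster minima 15 genes x 5
    conditions with a 15-condition maximum, Welch two-sample test with
    unadjusted p-values.
    """

    corpus_dir: str | None = None
    exposure_dir: str | None = None
    out_dir: str = "run"
    seed: int = 0
    log2_input: bool = False
    log2_epsilon: float = 1e-6
    quantile: bool = False
    cutoff_fold: float = 2.0
    min_rows: int = 15
    min_cols: int = 5
    max_cols: int = 15
    background: str = "all"
    alternative: str = "two-sided"
    adjust: str = "none"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.min_cols > self.max_cols:
            raise ValueError(
                f"min_cols ({self.min_cols}) must be <= max_cols ({self.max_cols})"
            )
        if not self.cutoff_fold > 1:
            raise ValueError("cutoff_fold must be > 1")
        if self.min_rows < 1 or self.min_cols < 1:
            raise ValueError("bicluster size minima must be >= 1")
        if self.background not in ("all", "complement"):
            raise ValueError("background must be 'all' or 'complement'")
        if self.alternative not in ("two-sided", "greater"):
            raise ValueError("alternative must be 'two-sided' or 'greater'")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _discover_studies(corpus_dir: Path) -> list[tuple[str, Path, Path, Path]]:
    triples = []
    for expr in sorted(corpus_dir.glob("*_expr.tsv")):
        sid = expr.name[: -len("_expr.tsv")]
        meta = corpus_dir / f"{sid}_meta.tsv"
        annot = corpus_dir / f"{sid}_annot.tsv"
        if meta.exists() and annot.exists():
            triples.append((sid, expr, meta, annot))
    return triples


def stage_preprocess(config: RunConfig, out: Path) -> Path:
    """Read, preprocess and merge all studies; write merged.tsv."""
    corpus = Path(config.corpus_dir)
    triples = _discover_studies(corpus)
    if len(triples) < 2:
        raise ValueError(
            f"preprocess: found {len(triples)} study triples in {corpus}; need >= 2"
        )
    pcfg = PreprocessConfig(
        log2_input=config.log2_input,
        log2_epsilon=config.log2_epsilon,
        quantile=config.quantile,
    )
    fold_changes = {}
    for sid, expr, meta, annot in triples:
        study = read_expression_table(expr, meta, annot, study_id=sid)
        fold_changes[sid] = preprocess_study(study, pcfg)
    merged = merge_studies(fold_changes)
    target = out / "merged.tsv"
    write_merged_matrix(merged, target)
    logger.info(
        "preprocess: merged %d genes x %d conditions -> %s",
        merged.shape[0],
        merged.shape[1],
        target,
    )
    return target


def stage_bicluster(config: RunConfig, out: Path, merged_path: Path) -> tuple[Path, Path]:
    """Run repeated Bimax in both directions; write JSON + GMT."""
    merged = read_merged_matrix(merged_path)
    runs = bicluster_both_directions(
        merged,
        cutoff_fold=config.cutoff_fold,
        min_rows=config.min_rows,
        min_cols=config.min_cols,
        max_cols=config.max_cols,
    )
    json_path = out / "biclusters.json"
    gmt_path = out / "biclusters.gmt"
    write_run_json(runs, json_path)
    sets = biclusters_to_gmt_sets(runs)
    if sets:
        write_gmt(sets, gmt_path)
    else:
        gmt_path.write_text("")
    logger.info(
        "bicluster: %d up + %d down biclusters",
        len(runs["up"]),
        len(runs["down"]),
    )
    return json_path, gmt_path


def stage_enrich(config: RunConfig, out: Path, gmt_path: Path) -> tuple[Path, Path]:
    """Score bicluster gene sets in every exposure study; write tables."""
    exposure = Path(config.exposure_dir)
    studies = []
    for expr in sorted(exposure.glob("*_expr.tsv")):
        sid = expr.name[: -len("_expr.tsv")]
        meta = exposure / f"{sid}_meta.tsv"
        if not meta.exists():
            logger.warning("enrich: %s lacks a metadata file; skipped", sid)
            continue
        try:
            studies.append(read_exposure_tsv(expr, meta, study_id=sid))
        except ValueError as exc:
            logger.warning("enrich: skipping %s (%s)", sid, exc)
    sets = {name: genes for name, (_, genes) in read_gmt(gmt_path).items()}
    if not studies or not sets:
        raise ValueError("enrich: need >= 1 exposure study and >= 1 gene set")
    long, matrix = enrich_all(
        studies,
        sets,
        adjust="BH" if config.adjust == "BH" else "none",
        background=config.background,
        alternative=config.alternative,
    )
    long_path = out / "enrichment.tsv"
    matrix_path = out / "enrichment_minus_log10_p.tsv"
    long.to_csv(long_path, sep="\t", index=False)
    matrix.to_csv(matrix_path, sep="\t")
    return long_path, matrix_path


def run_pipeline(config: RunConfig) -> Path:
    """Execute preprocess -> bicluster -> enrich and write a manifest.

    The run directory is write-once: an existing manifest there is a
    hard error. The enrich stage is skipped (with a log message) when
    no exposure directory is configured.
    """
    config.validate()
    if config.corpus_dir is None:
        raise ValueError("run_pipeline: corpus_dir is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        raise FileExistsError(
            f"{manifest_path} exists; runs are write-once, pick a fresh out_dir"
        )
    inputs = sorted(Path(config.corpus_dir).glob("*.tsv"))
    if config.exposure_dir:
        inputs += sorted(Path(config.exposure_dir).glob("*.tsv"))
    digests = {str(p): _sha256(p) for p in inputs}

    stages = []
    try:
        merged_path = stage_preprocess(config, out)
        stages.append({"name": "preprocess", "outputs": [merged_path.name]})
        json_path, gmt_path = stage_bicluster(config, out, merged_path)
        stages.append(
            {"name": "bicluster", "outputs": [json_path.name, gmt_path.name]}
        )
        if config.exposure_dir:
            long_path, matrix_path = stage_enrich(config, out, gmt_path)
            stages.append(
                {"name": "enrich", "outputs": [long_path.name, matrix_path.name]}
            )
        else:
            logger.info("run_pipeline: no exposure_dir configured; enrich skipped")
    except Exception as exc:
        stage = ["preprocess", "bicluster", "enrich"][len(stages)]
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    import numpy
    import scipy

    manifest = {
        "config": asdict(config),
        "provenance": PROVENANCE,
        "seed": config.seed,
        "inputs": digests,
        "stages": stages,
        "versions": {
            "bimaxgsea": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
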