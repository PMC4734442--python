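"""Seeded generators for a multi-study corpus and dose-response studies.

The corpus generator emulates a collection of ~11 mouse lung
microarray studies pooled into ~50 experimental conditions over a
shared universe of a few thousand gene symbols: per-study symbol
dropout stands in for platform differences, a per-study multiplicative
compression factor models cross-platform fold-change attenuation, and
co-expressed blocks of genes x conditions are planted at a chosen
log2 effect so the biclustering stage has a known ground truth.

Planted signal model: a planted gene x condition cell is guaranteed a
log2 fold change of at least ``compression x effect`` after the
preprocessing chain (replicate medians, control centring). Replicate
noise is symmetric on background cells; on planted cells any shortfall
below the floor is shifted up to it, so the planted effect is a
guaranteed minimum fold change. This makes survival of a block under
a fold cutoff a deterministic function of ``compression x effect``,
which the ground-truth registry records per condition.

The exposure generator emulates a nanomaterial inhalation study:
several dose levels plus control with a few replicates each, where the
genes of each planted set shift linearly with the dose index and all
other genes are flat.

All randomness flows from the single spec seed via
``numpy.random.SeedSequence``; identical specs give byte-identical
outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from math import log2
from typing import Sequence

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionStudy
from .enrichment import DoseResponseStudy


@dataclass
class PlantedBlock:
    """A co-expressed block to plant: genes x conditions at a log2 effect."""

    n_genes: int = 20
    n_conditions: int = 6
    direction: str = "up"
    effect: float = 1.5  # log2 units, pre-compression

    def __post_init__(self) -> None:
        if self.n_genes < 15:
            raise ValueError("planted blocks need >= 15 genes")
        if not 5 <= self.n_conditions <= 15:
            raise ValueError("planted blocks need 5-15 conditions")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.effect <= 0:
            raise ValueError("effect must be positive (log2 units)")


def _default_blocks() -> list[PlantedBlock]:
    return [
        PlantedBlock(direction="up"),
        PlantedBlock(direction="up"),
        PlantedBlock(direction="down"),
    ]


@dataclass
class CorpusSpec:
    """Study conditions for the synthetic multi-study corpus."""

    n_studies: int = 11
    total_conditions: int = 50
    conditions_per_study: tuple[int, int] = (2, 6)
    universe_size: int = 3000
    per_study_symbol_dropout: float = 0.1
    planted_blocks: list[PlantedBlock] = field(default_factory=_default_blocks)
    background_noise_sd: float = 0.3
    compression_range: tuple[float, float] = (0.6, 1.0)
    replicates_per_condition: int = 3
    duplicate_probe_fraction: float = 0.1
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self, cutoff_fold: float = 2.0) -> None:
        lo, hi = self.conditions_per_study
        if not (1 <= lo <= hi):
            raise ValueError("conditions_per_study bounds must satisfy 1 <= lo <= hi")
        if self.n_studies * lo > self.total_conditions or self.n_studies * hi < self.total_conditions:
            raise ValueError("total_conditions unreachable with conditions_per_study bounds")
        if not (0 <= self.per_study_symbol_dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        n_block_genes = sum(b.n_genes for b in self.planted_blocks)
        if n_block_genes > self.universe_size:
            raise ValueError("universe too small for the requested planted blocks")
        n_block_conds = sum(b.n_conditions for b in self.planted_blocks)
        if n_block_conds > self.total_conditions:
            raise ValueError("not enough conditions for the requested planted blocks")
        thr = log2(cutoff_fold)
        c_min = self.compression_range[0]
        for i, b in enumerate(self.planted_blocks):
            if b.effect * c_min < thr:
                warnings.warn(
                    f"planted block {i}: worst-case compressed effect "
                    f"{b.effect * c_min:.3f} < log2(cutoff) {thr:.3f}; "
                    "the block may not fully survive binarization",
                    stacklevel=2,
                )
        # expected background density of the +/- cutoff call
        from scipy.stats import norm

        med_var = np.pi / (2 * self.replicates_per_condition)
        fc_sd = self.background_noise_sd * np.sqrt(2 * med_var)
        density = 2 * norm.sf(thr / fc_sd) if fc_sd > 0 else 0.0
        if density > 0.05:
            warnings.warn(
                f"expected background 1-density {density:.3f} > 0.05; "
                "Bimax enumeration may explode on such dense matrices",
                stacklevel=2,
            )


@dataclass
class PlantedBlockTruth:
    """Registry entry: exact membership of one planted block."""

    name: str
    direction: str
    effect: float
    genes: list[str]
    conditions: list[str]  # "study:condition" labels
    compressed_effect: dict[str, float]  # per condition

    def surviving_conditions(self, cutoff_fold: float = 2.0) -> list[str]:
        thr = log2(cutoff_fold)
        return [c for c in self.conditions if self.compressed_effect[c] >= thr]


@dataclass
class CorpusRegistry:
    """Ground truth for a generated corpus."""

    blocks: list[PlantedBlockTruth]
    universe: list[str]
    compression: dict[str, float]  # per study

    def gene_sets(self) -> dict[str, tuple[str, list[str]]]:
        return {
            b.name: (",".join(b.conditions), list(b.genes)) for b in self.blocks
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "blocks": [asdict(b) for b in self.blocks],
                    "universe": self.universe,
                    "compression": self.compression,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CorpusRegistry":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            blocks=[PlantedBlockTruth(**b) for b in raw["blocks"]],
            universe=raw["universe"],
            compression=raw["compression"],
        )


def _allocate_conditions(
    rng: np.random.Generator, spec: CorpusSpec
) -> list[int]:
    """Per-study condition counts within bounds, summing to total_conditions."""
    lo, hi = spec.conditions_per_study
    counts = rng.integers(lo, hi + 1, size=spec.n_studies)
    diff = spec.total_conditions - int(counts.sum())
    while diff != 0:
        i = int(rng.integers(spec.n_studies))
        if diff > 0 and counts[i] < hi:
            counts[i] += 1
            diff -= 1
        elif diff < 0 and counts[i] > lo:
            counts[i] -= 1
            diff += 1
    return [int(c) for c in counts]


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[ExpressionStudy], CorpusRegistry]:
    """Generate replicate-level studies with planted blocks and their registry.

    Each study carries a probe x sample log2 intensity matrix (a
    fraction of genes get a duplicate probe), full sample metadata with
    one shared control group, and a probe -> symbol annotation. After
    the standard preprocessing chain the merged matrix contains each
    planted block at >= effect x study compression (see module
    docstring for the planted signal model).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    universe = [f"GENE{i:05d}" for i in range(spec.universe_size)]
    study_ids = [f"S{i + 1:02d}" for i in range(spec.n_studies)]
    cond_counts = _allocate_conditions(rng, spec)
    conditions = {
        sid: [f"C{j + 1}" for j in range(cond_counts[i])]
        for i, sid in enumerate(study_ids)
    }
    compression = {
        sid: float(rng.uniform(*spec.compression_range)) for sid in study_ids
    }

    # disjoint gene and condition assignments for the planted blocks
    gene_perm = rng.permutation(spec.universe_size)
    all_slots = [(sid, c) for sid in study_ids for c in conditions[sid]]
    slot_perm = rng.permutation(len(all_slots))
    blocks: list[PlantedBlockTruth] = []
    claimed: set[int] = set()

    def take_slot(exclude_study: str | None = None) -> int:
        for idx in slot_perm:
            idx = int(idx)
            if idx in claimed:
                continue
            if exclude_study is not None and all_slots[idx][0] == exclude_study:
                continue
            claimed.add(idx)
            return idx
        raise ValueError("not enough free condition slots for the planted blocks")

    g_cursor = 0
    for k, blk in enumerate(spec.planted_blocks, start=1):
        genes = sorted(
            universe[i] for i in gene_perm[g_cursor : g_cursor + blk.n_genes]
        )
        g_cursor += blk.n_genes
        picked = [take_slot() for _ in range(blk.n_conditions)]
        if len({all_slots[i][0] for i in picked}) < 2:
            # planted blocks must span at least two studies; swap the last
            # slot for one from another study (deterministic)
            claimed.discard(picked[-1])
            picked[-1] = take_slot(exclude_study=all_slots[picked[0]][0])
        slots = [all_slots[i] for i in picked]
        labels = sorted(f"{sid}:{c}" for sid, c in slots)
        blocks.append(
            PlantedBlockTruth(
                name=f"planted_{k}_{blk.direction}",
                direction=blk.direction,
                effect=blk.effect,
                genes=genes,
                conditions=labels,
                compressed_effect={
                    lab: blk.effect * compression[lab.split(":", 1)[0]]
                    for lab in labels
                },
            )
        )

    # per-(study, condition, gene) true fold change
    true_fc: dict[str, dict[str, dict[str, float]]] = {
        sid: {c: {} for c in conditions[sid]} for sid in study_ids
    }
    for blk in blocks:
        sign = 1.0 if blk.direction == "up" else -1.0
        for lab in blk.conditions:
            sid, c = lab.split(":", 1)
            for g in blk.genes:
                true_fc[sid][c][g] = sign * blk.effect

    studies: list[ExpressionStudy] = []
    study_seeds = root.spawn(spec.n_studies)
    n_rep = spec.replicates_per_condition
    for i, sid in enumerate(study_ids):
        srng = np.random.default_rng(study_seeds[i])
        c_s = compression[sid]
        keep = srng.random(spec.universe_size) >= spec.per_study_symbol_dropout
        # planted genes are measured on every platform: dropout would
        # remove them from the cross-study intersection and the merged
        # matrix could no longer contain the planted block
        forced = {g for blk in blocks for g in blk.genes}
        genes_s = [
            g
            for j, g in enumerate(universe)
            if keep[j] or g in forced
        ]
        dup = srng.random(len(genes_s)) < spec.duplicate_probe_fraction
        probes = []
        probe_gene = []
        for j, g in enumerate(genes_s):
            probes.append(f"{sid}_P{j:05d}a")
            probe_gene.append(g)
            if dup[j]:
                probes.append(f"{sid}_P{j:05d}b")
                probe_gene.append(g)
        baseline = {
            g: srng.normal(spec.baseline_mean, spec.baseline_sd) for g in genes_s
        }
        conds = conditions[sid]
        sample_cols = []
        meta_rows = []
        for cond in ["CTRL"] + conds:
            is_ctrl = cond == "CTRL"
            for r in range(1, n_rep + 1):
                s_id = f"{sid}_{cond}_r{r}"
                sample_cols.append((cond, s_id))
                meta_rows.append(
                    {
                        "sample_id": s_id,
                        "study_id": sid,
                        "condition_id": cond,
                        "is_control": is_ctrl,
                        "control_group": "cg1",
                        "replicate_id": f"r{r}",
                        "dose": 0.0,
                    }
                )
        data = np.empty((len(probes), len(sample_cols)))
        for col, (cond, _) in enumerate(sample_cols):
            fc_map = true_fc[sid].get(cond, {})
            for row, (p, g) in enumerate(zip(probes, probe_gene)):
                signal = c_s * fc_map.get(g, 0.0)
                data[row, col] = baseline[g] + signal
        data += srng.normal(0.0, spec.background_noise_sd, size=data.shape)

        # enforce the planted floor: realized gene-level fold change
        # (median over probes then replicates, minus the same for the
        # control) must reach compression x effect in magnitude
        values = pd.DataFrame(
            data, index=probes, columns=[s for _, s in sample_cols]
        )
        gene_index = pd.Index(probe_gene)
        cols_of = {}
        for cond in ["CTRL"] + conds:
            cols_of[cond] = [s for c, s in sample_cols if c == cond]
        ctrl_gene = (
            values[cols_of["CTRL"]]
            .groupby(gene_index)
            .median()
            .median(axis=1)
        )
        for cond in conds:
            fc_map = true_fc[sid].get(cond, {})
            if not fc_map:
                continue
            sub = values[cols_of[cond]]
            gene_level = sub.groupby(gene_index).median().median(axis=1)
            for g, target in fc_map.items():
                floor = c_s * abs(target)
                realized = gene_level[g] - ctrl_gene[g]
                if target > 0 and realized < floor:
                    shift = floor - realized
                elif target < 0 and realized > -floor:
                    shift = -floor - realized
                else:
                    continue
                rows = gene_index == g
                values.loc[rows, cols_of[cond]] += shift

        meta = pd.DataFrame(meta_rows)
        annotation = pd.DataFrame(
            {"probe_id": probes, "gene_symbol": probe_gene}
        )
        studies.append(
            ExpressionStudy(
                study_id=sid,
                values=values,
                meta=meta,
                annotation=annotation,
                platform_id=f"SYNTH_{i % 4}",
            )
        )
    registry = CorpusRegistry(
        blocks=blocks, universe=universe, compression=compression
    )
    return studies, registry


@dataclass
class PlantedSet:
    """A gene set planted with a per-gene linear dose slope (log2/level)."""

    name: str
    genes: list[str] | int = 20
    slope: float = 1.0


@dataclass
class ExposureSpec:
    """Study conditions for a synthetic dose-response exposure study."""

    study_id: str = "EXPO"
    n_genes: int = 2000
    dose_levels: int = 3  # non-control levels; control is added on top
    replicates_per_level: int = 3
    planted_sets: list[PlantedSet] = field(default_factory=list)
    residual_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    gene_universe: Sequence[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.dose_levels < 1:
            raise ValueError("need >= 1 non-control dose level")
        if self.replicates_per_level < 2:
            raise ValueError(
                "need >= 2 replicates per level (the dose-effect F is "
                "undefined otherwise)"
            )
        if self.gene_universe is not None and len(self.gene_universe) < self.n_genes:
            raise ValueError("gene_universe smaller than n_genes")


def generate_exposure_study(
    spec: ExposureSpec,
) -> tuple[DoseResponseStudy, dict[str, list[str]]]:
    """Generate a dose-response study with planted linearly responding sets.

    Group means of a planted set's genes rise by ``slope`` log2 units
    per dose index (control = 0); all other genes are flat. Residuals
    are i.i.d. normal with ``residual_sd``. Returns the study and the
    ground-truth mapping of set name -> planted genes.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.gene_universe is not None:
        genes = [str(g) for g in spec.gene_universe[: spec.n_genes]]
    else:
        genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    truth: dict[str, list[str]] = {}
    slope_vec = np.zeros(spec.n_genes)
    available = list(range(spec.n_genes))
    for ps in spec.planted_sets:
        if isinstance(ps.genes, int):
            if ps.genes > len(available):
                raise ValueError("universe too small for the requested planted sets")
            pick_idx = rng.choice(len(available), size=ps.genes, replace=False)
            members = sorted(genes[available[i]] for i in pick_idx)
            available = [a for i, a in enumerate(available) if i not in set(pick_idx)]
        else:
            members = sorted(str(g) for g in ps.genes)
            missing = [g for g in members if g not in gene_pos]
            if missing:
                raise ValueError(f"planted set {ps.name!r}: genes not in universe: {missing}")
        for g in members:
            slope_vec[gene_pos[g]] = ps.slope
        truth[ps.name] = members

    levels = ["d0"] + [f"d{i}" for i in range(1, spec.dose_levels + 1)]
    n_rep = spec.replicates_per_level
    samples = [f"{spec.study_id}_{lvl}_r{r}" for lvl in levels for r in range(1, n_rep + 1)]
    dose_index = np.repeat(np.arange(len(levels)), n_rep)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    mean = baseline[:, None] + slope_vec[:, None] * dose_index[None, :]
    data = mean + rng.normal(0.0, spec.residual_sd, size=(spec.n_genes, len(samples)))
    values = pd.DataFrame(data, index=genes, columns=samples)
    dose_group = pd.Series(
        [levels[i] for i in dose_index], index=samples, name="dose_group"
    )
    study = DoseResponseStudy(
        study_id=spec.study_id, values=values, dose_group=dose_group
    )
    return study, truth


# ---------------------------------------------------------------------------
# TSV export (the formats the preprocessing and enrichment stages consume)

def write_study_tsv(study: ExpressionStudy, out_dir) -> None:
    """Write ``<sid>_expr.tsv``, ``<sid>_meta.tsv``, ``<sid>_annot.tsv``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = study.study_id
    study.values.rename_axis("probe_id").to_csv(out / f"{sid}_expr.tsv", sep="\t")
    study.meta.to_csv(out / f"{sid}_meta.tsv", sep="\t", index=False)
    study.annotation.to_csv(out / f"{sid}_annot.tsv", sep="\t", index=False)


def write_exposure_tsv(study: DoseResponseStudy, out_dir) -> None:
    """Write ``<sid>_expr.tsv`` and ``<sid>_meta.tsv`` (with dose column)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = study.study_id
    study.values.rename_axis("gene_symbol").to_csv(out / f"{sid}_expr.tsv", sep="\t")
    meta = pd.DataFrame(
        {"sample_id": study.values.columns, "dose_group": study.dose_group.values}
    )
    meta.insert(1, "study_id", sid)
    meta.to_csv(out / f"{sid}_meta.tsv", sep="\t", index=False)


def read_exposure_tsv(expr_path, meta_path, study_id: str | None = None) -> DoseResponseStudy:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    if "dose_group" not in meta.columns:
        raise ValueError(f"{meta_path}: metadata lacks a dose_group column")
    if study_id is None:
        study_id = str(meta["study_id"].iloc[0]) if "study_id" in meta.columns else "study"
    dose = pd.Series(meta["dose_group"].values, index=meta["sample_id"].values)
    return DoseResponseStudy(study_id=study_id, values=values, dose_group=dose)
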