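"""Reading, normalising and merging per-study expression matrices.

The preprocessing chain turns replicate-level log2 intensity (or log2
ratio) matrices from several microarray studies into a single merged
gene-symbol x condition matrix of control-centred log2 fold changes:

1. optional ``log2`` transform for raw-scale input,
2. optional quantile normalisation across sample columns,
3. median collapse of technical replicates (samples sharing a
   condition and replicate id),
4. probe -> gene-symbol annotation, expansion of multi-symbol probes,
   and median collapse of probes per symbol,
5. median collapse of biological replicates to one column per
   experimental condition,
6. centring of every treated condition on its matched control group
   (control columns are removed afterwards),
7. intersection merge across studies on canonical gene symbols.

The median is used throughout as a robust estimate of central
tendency; even-sized groups take the midpoint of the two central
values. All matrices are pandas DataFrames: rows are probes or gene
symbols, columns are samples, replicates or conditions depending on
the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

#: columns every sample-metadata table must provide
META_COLUMNS = (
    "sample_id",
    "study_id",
    "condition_id",
    "is_control",
    "control_group",
    "replicate_id",
)


def canonical_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-stripped and upper-cased."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionStudy:
    """One study's expression matrix plus sample metadata and annotation.

    Parameters
    ----------
    values
        Probe x sample matrix of log2 intensities or log2 ratios.
        Duplicate probe rows (technical replicate spots) are allowed
        and collapsed later.
    meta
        Sample metadata with the columns in :data:`META_COLUMNS` and an
        optional ``dose`` column. One row per sample.
    annotation
        Two-column frame mapping ``probe_id`` to ``gene_symbol``.
        Many-to-one and one-to-many mappings are both allowed.
    """

    study_id: str
    values: pd.DataFrame
    meta: pd.DataFrame
    annotation: pd.DataFrame
    platform_id: str = ""

    def __post_init__(self) -> None:
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise ValueError(
                f"study {self.study_id!r}: metadata lacks columns {missing_cols}"
            )
        if self.meta["sample_id"].duplicated().any():
            dupes = sorted(self.meta.loc[self.meta["sample_id"].duplicated(), "sample_id"])
            raise ValueError(f"study {self.study_id!r}: duplicate sample ids {dupes}")
        known = set(self.meta["sample_id"])
        unknown = [s for s in self.values.columns if s not in known]
        if unknown:
            raise ValueError(
                f"study {self.study_id!r}: samples missing from metadata: {unknown}"
            )
        for col in ("probe_id", "gene_symbol"):
            if col not in self.annotation.columns:
                raise ValueError(
                    f"study {self.study_id!r}: annotation lacks column {col!r}"
                )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_expression_table(
    path,
    meta_path,
    annotation_path,
    study_id: str | None = None,
    platform_id: str = "",
) -> ExpressionStudy:
    """Read a tab-delimited expression matrix with metadata and annotation.

    The expression file has probe ids in the first column and sample ids
    in the header. Every sample column must appear in the metadata; a
    missing sample is a hard error naming the sample. Duplicate probe
    rows are retained (they are median-collapsed later).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "replicate_id": str})
    if "is_control" in meta.columns:
        meta["is_control"] = meta["is_control"].astype(bool)
    annotation = pd.read_csv(
        annotation_path, sep="\t", dtype=str, names=None, header=0
    )
    if annotation.shape[1] < 2:
        raise ValueError(f"annotation {annotation_path} must have two columns")
    annotation = annotation.iloc[:, :2]
    annotation.columns = ["probe_id", "gene_symbol"]
    if study_id is None:
        ids = meta["study_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"metadata lists several study ids {sorted(ids)}; pass study_id")
        study_id = str(ids[0])
    return ExpressionStudy(
        study_id=study_id,
        values=values,
        meta=meta,
        annotation=annotation,
        platform_id=platform_id,
    )


def lowess_normalize_two_color(
    m: np.ndarray,
    a: np.ndarray,
    span: float = 0.4,
    iterations: int = 3,
) -> np.ndarray:
    """Intensity-dependent normalisation of two-color log ratios.

    Subtracts the locally weighted regression (LOWESS) fit of M on A
    from M, removing the intensity-dependent dye bias. ``span`` is the
    fraction of points in each local fit and ``iterations`` the number
    of robustifying reweightings.

    Non-finite entries are passed through as NaN. Fewer than 10 finite
    points is an error: the local fit is unreliable.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("M and A must be equal-length 1-d vectors")
    finite = np.isfinite(m) & np.isfinite(a)
    if finite.sum() < 10:
        raise ValueError(
            f"only {int(finite.sum())} finite (M, A) points; need >= 10 for a LOWESS fit"
        )
    fit = _sm_lowess(
        m[finite], a[finite], frac=span, it=iterations, return_sorted=False
    )
    out = np.full_like(m, np.nan)
    out[finite] = m[finite] - fit
    return out


def quantile_normalize(values: pd.DataFrame | np.ndarray):
    """Force all columns to share one common empirical distribution.

    Each column's sorted values are replaced by the across-column mean
    of the row-wise sorted values; within-column ranks are preserved
    (ties keep their original order). After normalisation all columns
    have identical sorted vectors.
    """
    is_frame = isinstance(values, pd.DataFrame)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-d matrix with >= 2 columns")
    if not np.isfinite(arr).all():
        raise ValueError(
            "matrix contains missing/non-finite values; impute or drop before quantile normalization"
        )
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    mean_sorted = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    np.put_along_axis(
        out, order, np.broadcast_to(mean_sorted[:, None], arr.shape), axis=0
    )
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def collapse_by_median(
    values: pd.DataFrame,
    group_key: Mapping,
    axis: str = "rows",
) -> pd.DataFrame:
    """Median-collapse rows or columns that share a group label.

    ``group_key`` maps row (or column) labels to group labels; labels
    without a mapping are dropped with a logged count. NaNs are ignored
    within a group; a group that is all-NaN in some cell yields a
    missing value there (logged). Groups are emitted in sorted label
    order, so the operation is idempotent once applied.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    df = values if axis == "rows" else values.T
    mapped = df.index.map(lambda lbl: group_key.get(lbl))
    n_unmapped = int(pd.isna(mapped).sum())
    if n_unmapped:
        logger.info("collapse_by_median: dropping %d unmapped %s", n_unmapped, axis)
    keep = ~pd.isna(mapped)
    grouped = df.loc[keep].groupby(np.asarray(mapped[keep]), sort=True).median()
    n_missing = int(grouped.isna().sum().sum())
    if n_missing:
        logger.info("collapse_by_median: %d cells empty after NA removal", n_missing)
    return grouped if axis == "rows" else grouped.T


def condition_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-condition view of a sample metadata table.

    Returns one row per condition_id with is_control, control_group
    and (where present) dose; raises if a condition's control flag or
    control group is inconsistent across its samples.
    """
    cols = ["condition_id", "is_control", "control_group"]
    if "dose" in meta.columns:
        cols.append("dose")
    tab = meta[cols].drop_duplicates()
    if tab["condition_id"].duplicated().any():
        bad = sorted(tab.loc[tab["condition_id"].duplicated(), "condition_id"])
        raise ValueError(f"inconsistent control/group metadata for conditions {bad}")
    return tab.set_index("condition_id")

def center_to_control(
    values: pd.DataFrame,
    cond_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Center treated condition columns on their matched control.

    ``values`` is a gene x condition matrix (replicates already
    collapsed); ``cond_meta`` is a :func:`condition_table` frame. The
    control value of a group is the median across its control
    condition columns (normally one). Every treated column has its
    group's control subtracted — the log2 fold change versus matched
    control, estimated from medians — and control columns are removed.
    A treated condition with no control in its group is a hard error.
    """
    missing = [c for c in values.columns if c not in cond_meta.index]
    if missing:
        raise ValueError(f"conditions absent from metadata: {missing}")
    sub = cond_meta.loc[list(values.columns)]
    out = {}
    for group, members in sub.groupby("control_group", sort=False):
        ctrl_conds = members.index[members["is_control"]]
        treated = members.index[~members["is_control"]]
        if len(treated) and not len(ctrl_conds):
            raise ValueError(
                f"treated conditions {sorted(treated)} have no control in group {group!r}"
            )
        if not len(treated):
            continue
        ctrl = values[list(ctrl_conds)].median(axis=1)
        for cond in treated:
            out[cond] = values[cond] - ctrl
    centered = pd.DataFrame(out, index=values.index)
    # preserve original column order among treated conditions
    treated_order = [c for c in values.columns if c in centered.columns]
    return centered[treated_order]


@dataclass
class PreprocessConfig:
    """Knobs of the per-study preprocessing chain."""

    log2_input: bool = False        # apply log2 to raw-scale values
    log2_epsilon: float = 1e-6      # floor before log2 for raw input
    quantile: bool = False          # quantile-normalize across samples
    drop_incomplete_genes: bool = True


def preprocess_study(
    study: ExpressionStudy,
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Run the full per-study chain down to a gene x condition fold-change matrix.

    Steps: optional log2, optional quantile normalisation, technical
    replicate collapse, symbol annotation + probe collapse, biological
    replicate collapse, control centring, removal of genes with any
    missing value.
    """
    cfg = config or PreprocessConfig()
    values = study.values
    if cfg.log2_input:
        values = np.log2(values.clip(lower=cfg.log2_epsilon))
    if cfg.quantile:
        values = quantile_normalize(values)

    meta = study.meta.set_index("sample_id")
    meta = meta.loc[list(values.columns)]

    # technical replicates: samples sharing (condition, replicate)
    tech_key = {
        s: f"{meta.at[s, 'condition_id']}||{meta.at[s, 'replicate_id']}"
        for s in values.columns
    }
    values = collapse_by_median(values, tech_key, axis="columns")

    # probe -> symbol expansion and collapse
    ann = study.annotation.copy()
    ann["gene_symbol"] = ann["gene_symbol"].map(canonical_symbol)
    ann["probe_id"] = ann["probe_id"].astype(str)
    long = values.reset_index(names="probe_id")
    long["probe_id"] = long["probe_id"].astype(str)
    n_unannotated = int((~long["probe_id"].isin(set(ann["probe_id"]))).sum())
    long = ann.merge(long, on="probe_id", how="inner")
    if n_unannotated > 0:
        logger.info(
            "preprocess_study[%s]: %d probe rows without annotation dropped",
            study.study_id,
            n_unannotated,
        )
    values = long.drop(columns=["probe_id"]).groupby("gene_symbol", sort=True).median()

    # biological replicates -> condition columns
    bio_key = {lbl: lbl.split("||", 1)[0] for lbl in values.columns}
    values = collapse_by_median(values, bio_key, axis="columns")

    cond_meta = condition_table(meta.reset_index())
    centered = center_to_control(values, cond_meta)

    if cfg.drop_incomplete_genes:
        complete = centered.dropna(axis=0)
        n_dropped = centered.shape[0] - complete.shape[0]
        if n_dropped:
            logger.info(
                "preprocess_study[%s]: dropped %d genes with missing values",
                study.study_id,
                n_dropped,
            )
        centered = complete
    return centered


def merge_studies(
    fold_changes: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Merge per-study fold-change matrices on the gene-symbol intersection.

    Row set is the intersection of the studies' canonical gene symbols;
    columns are all condition columns, labelled ``study_id:condition``.
    Duplicate symbols arising from canonicalization within one study
    are median-collapsed first. An empty intersection is a hard error.
    """
    if len(fold_changes) < 2:
        raise ValueError("need at least two studies to merge")
    canon = {}
    for sid, df in fold_changes.items():
        c = df.copy()
        c.index = [canonical_symbol(g) for g in c.index]
        if c.index.duplicated().any():
            c = c.groupby(level=0, sort=True).median()
        canon[sid] = c.sort_index()
    common: set[str] | None = None
    for c in canon.values():
        common = set(c.index) if common is None else common & set(c.index)
    if not common:
        raise ValueError("gene-symbol intersection across studies is empty")
    genes = sorted(common)
    logger.info(
        "merge_studies: %d common gene symbols across %d studies",
        len(genes),
        len(canon),
    )
    pieces = []
    for sid, c in canon.items():
        part = c.loc[genes]
        part.columns = [f"{sid}:{col}" for col in part.columns]
        pieces.append(part)
    merged = pd.concat(pieces, axis=1)
    merged = merged.dropna(axis=0)
    merged.index.name = "gene_symbol"
    return merged


def write_merged_matrix(merged: pd.DataFrame, path) -> None:
    merged.to_csv(path, sep="\t")


def read_merged_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_symbol"
    return df
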