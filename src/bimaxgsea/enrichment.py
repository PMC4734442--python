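"""Gene-set scoring in dose-response studies via F statistics and Welch's t.

For a study with several dose groups, each gene receives a one-way
ANOVA F statistic for the dose factor (dose treated as categorical).
The F statistics are log2-transformed, and a gene set is scored by a
Welch two-sample t-test comparing the mean log2(F) of the set's genes
against the mean log2(F) of all genes in the study (the set included,
by default). Larger set means indicate that the set's genes respond
to dose more strongly than a typical gene. Results are reported as t,
Welch-Satterthwaite degrees of freedom, the p-value and -log10(p).

Genes whose F statistic is undefined (zero within-group variance) or
zero (log2 undefined) are excluded from both groups, with counts kept
on the :class:`GeneFStats` object.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import canonical_symbol

logger = logging.getLogger(__name__)


@dataclass
class DoseResponseStudy:
    """Log2 expression matrix with a categorical dose label per sample.

    ``dose_group`` maps each sample (column of ``values``) to a dose
    level label; the control is simply one of the levels. Validity
    requires >= 2 levels with >= 2 samples each, otherwise the
    within-group variance (and hence F) is undefined.
    """

    study_id: str
    values: pd.DataFrame
    dose_group: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.dose_group.index]
        if missing:
            raise ValueError(
                f"study {self.study_id!r}: samples without dose label: {missing}"
            )
        self.dose_group = self.dose_group.loc[list(self.values.columns)]
        counts = self.dose_group.value_counts()
        if len(counts) < 2:
            raise ValueError(
                f"study {self.study_id!r}: need >= 2 dose levels, got {len(counts)}"
            )
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"study {self.study_id!r}: dose level(s) with < 2 samples: "
                f"{sorted(small.index)}"
            )

    @property
    def levels(self) -> list:
        return sorted(self.dose_group.unique())


@dataclass
class GeneFStats:
    """Per-gene dose-effect F statistics for one study.

    ``table`` has one row per gene with columns ``F`` (NaN where the
    within-group mean square is zero), ``log2_f`` (NaN where F is zero
    or undefined), ``defined`` and ``status`` ("ok",
    "zero_within_variance" or "zero_f").
    """

    study_id: str
    table: pd.DataFrame
    n_groups: int
    n_samples: int

    @property
    def usable(self) -> pd.Series:
        """log2(F) restricted to genes where it is defined."""
        return self.table.loc[self.table["defined"], "log2_f"]


def dose_f_statistics(study: DoseResponseStudy) -> GeneFStats:
    """One-way ANOVA F for the dose factor, per gene, plus log2(F).

    F = MS_between / MS_within with dose as a categorical factor.
    Genes with zero within-group mean square are flagged undefined;
    genes with F = 0 are flagged undefined for the log2 transform.
    Neither is silently dropped.
    """
    x = np.asarray(study.values, dtype=float)
    groups = study.dose_group
    levels = study.levels
    k = len(levels)
    n = x.shape[1]
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for lvl in levels:
        cols = np.asarray(groups == lvl)
        xg = x[:, cols]
        mg = xg.mean(axis=1)
        ssb += cols.sum() * (mg - grand) ** 2
        ssw += ((xg - mg[:, None]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / msw, np.nan)
        log2_f = np.where(np.isnan(f) | (f <= 0), np.nan, np.log2(np.where(f > 0, f, 1.0)))
    status = np.where(msw <= 0, "zero_within_variance", np.where(f <= 0, "zero_f", "ok"))
    table = pd.DataFrame(
        {
            "F": f,
            "log2_f": log2_f,
            "defined": ~np.isnan(log2_f),
            "status": status,
        },
        index=study.values.index,
    )
    n_undef = int((~table["defined"]).sum())
    if n_undef:
        logger.info(
            "dose_f_statistics[%s]: %d of %d genes with undefined log2(F)",
            study.study_id,
            n_undef,
            len(table),
        )
    return GeneFStats(
        study_id=study.study_id, table=table, n_groups=k, n_samples=n
    )


def welch_t(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """Welch's two-sample t statistic and Welch-Satterthwaite df.

    Explicit formulas (sample variances with n-1 denominators):
    t = (m1 - m2) / sqrt(v1/n1 + v2/n2);
    df = (v1/n1 + v2/n2)^2 / ((v1/n1)^2/(n1-1) + (v2/n2)^2/(n2-1)).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need >= 2 observations")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return (0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2), float(n1 + n2 - 2))
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(t), float(df)


@dataclass
class EnrichmentResult:
    """Welch test of a gene set's log2(F) against the study background."""

    set_name: str
    study_id: str
    t_statistic: float = math.nan
    degrees_of_freedom: float = math.nan
    p_value: float = math.nan
    n_set: int = 0
    n_background: int = 0
    mean_set: float = math.nan
    mean_background: float = math.nan
    background: str = "all"
    alternative: str = "two-sided"
    evaluable: bool = True

    @property
    def minus_log10_p(self) -> float:
        if not self.evaluable or not (self.p_value > 0):
            return math.nan
        return -math.log10(self.p_value)


def geneset_welch_test(
    fstats: GeneFStats,
    gene_set: Iterable[str],
    set_name: str = "",
    background: str = "all",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Welch two-sample t-test of a gene set's log2(F) versus the background.

    Group 1 is the set intersected with the study's genes that have a
    defined log2(F); group 2 is, by default, *all* such genes (set
    members included), matching the mean-of-all-genes background; pass
    ``background="complement"`` to exclude set members. ``alternative``
    is ``"two-sided"`` or ``"greater"`` (set mean above background).
    Fewer than 2 usable set genes yields a result flagged not
    evaluable rather than an exception.
    """
    if background not in ("all", "complement"):
        raise ValueError("background must be 'all' or 'complement'")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    usable = fstats.usable
    wanted = {canonical_symbol(g) for g in gene_set}
    in_set = usable.index.map(lambda g: canonical_symbol(g) in wanted)
    x1 = usable[np.asarray(in_set)]
    x2 = usable if background == "all" else usable[~np.asarray(in_set)]
    base = EnrichmentResult(
        set_name=set_name,
        study_id=fstats.study_id,
        n_set=len(x1),
        n_background=len(x2),
        background=background,
        alternative=alternative,
    )
    if len(x1) < 2 or len(x2) < 2:
        base.evaluable = False
        return base
    t, df = welch_t(np.asarray(x1), np.asarray(x2))
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(t, df))
    p = min(p, 1.0)
    base.t_statistic = t
    base.degrees_of_freedom = df
    base.p_value = p
    base.mean_set = float(np.mean(x1))
    base.mean_background = float(np.mean(x2))
    return base


def enrich_all(
    studies: Sequence[DoseResponseStudy],
    gene_sets: Mapping[str, Iterable[str]],
    adjust: str = "none",
    background: str = "all",
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every gene set in every study.

    Returns a long-format table (one row per set x study) and a
    sets x studies matrix of -log10(p) for plotting. ``adjust="BH"``
    applies Benjamini-Hochberg across sets within each study
    (``p_adj`` column); the default is unadjusted.
    """
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    if not len(studies) or not len(gene_sets):
        raise ValueError("need at least one study and one gene set")
    rows = []
    for study in studies:
        try:
            fstats = dose_f_statistics(study)
        except ValueError as exc:
            logger.warning("enrich_all: skipping study %s (%s)", study.study_id, exc)
            continue
        study_rows = []
        for name, genes in gene_sets.items():
            res = geneset_welch_test(
                fstats,
                genes,
                set_name=name,
                background=background,
                alternative=alternative,
            )
            study_rows.append(
                {
                    "set": res.set_name,
                    "study": res.study_id,
                    "n_set": res.n_set,
                    "n_background": res.n_background,
                    "mean_set": res.mean_set,
                    "mean_background": res.mean_background,
                    "t": res.t_statistic,
                    "df": res.degrees_of_freedom,
                    "p": res.p_value,
                    "minus_log10_p": res.minus_log10_p,
                    "evaluable": res.evaluable,
                }
            )
        if adjust == "BH":
            from statsmodels.stats.multitest import multipletests

            ps = np.array([r["p"] for r in study_rows])
            ok = ~np.isnan(ps)
            adj = np.full_like(ps, np.nan)
            if ok.sum():
                adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
            for r, a in zip(study_rows, adj):
                r["p_adj"] = a
        rows.extend(study_rows)
    long = pd.DataFrame(rows)
    matrix = (
        long.pivot(index="set", columns="study", values="minus_log10_p")
        if len(long)
        else pd.DataFrame()
    )
    return long, matrix


def plot_enrichment_bars(matrix: pd.DataFrame, study_id: str, ax=None):
    """Barplot of -log10(p) per gene set for one study (display helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    vals = matrix[study_id]
    ax.bar(range(len(vals)), vals.values)
    ax.set_xticks(range(len(vals)))
    ax.set_xticklabels(vals.index, rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(study_id)
    return ax
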