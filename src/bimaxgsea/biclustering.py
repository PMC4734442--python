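"""Binary fold-change matrices and repeated Bimax biclustering.

A bicluster here is an inclusion-maximal all-ones submatrix of a 0/1
up- or down-regulation matrix: a set of genes that all pass the fold
cutoff (in the same direction) on a common set of experimental
conditions, such that no further gene or condition can be added
without introducing a 0. Bimax enumerates these by divide and
conquer; the repeated wrapper extracts biclusters one at a time,
largest area first, masking each accepted bicluster's cells to zero
so that overlapping structures sharing rows or columns (but not
cells) remain discoverable.

Column-count enforcement: Bimax itself has no native column maximum,
so a maximal bicluster wider than ``max_cols`` is truncated to the
``max_cols`` columns with the most 1s outside the bicluster's rows
(ties broken lexicographically by label) and then re-extended to all
rows supporting the truncated column set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

DEFAULT_MIN_ROWS = 15
DEFAULT_MIN_COLS = 5
DEFAULT_MAX_COLS = 15
DEFAULT_CUTOFF_FOLD = 2.0


@dataclass
class BinaryMatrix:
    """0/1 indicator matrix for one regulation direction.

    A cell is 1 in the ``up`` matrix iff its log2 fold change is
    >= log2(cutoff_fold), and 1 in the ``down`` matrix iff it is
    <= -log2(cutoff_fold); the boundary is inclusive. The two
    matrices derived from one input are therefore disjoint.
    """

    values: pd.DataFrame
    direction: str
    cutoff_fold: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not self.cutoff_fold > 1:
            raise ValueError("cutoff_fold must be > 1")

    @property
    def density(self) -> float:
        return float(np.asarray(self.values).mean())


@dataclass(frozen=True)
class Bicluster:
    """Gene set with the condition set it was found on, plus direction."""

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    direction: str = "up"

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def area(self) -> int:
        return len(self.genes) * len(self.conditions)


@dataclass
class BiclusterRun:
    """Ordered result of a repeated-Bimax run with its parameters."""

    biclusters: list[Bicluster]
    min_rows: int = DEFAULT_MIN_ROWS
    min_cols: int = DEFAULT_MIN_COLS
    max_cols: int = DEFAULT_MAX_COLS
    cutoff_fold: float = DEFAULT_CUTOFF_FOLD
    direction: str = "up"
    source_digest: str = ""

    def __len__(self) -> int:
        return len(self.biclusters)


def binarize(
    merged: pd.DataFrame,
    cutoff_fold: float = DEFAULT_CUTOFF_FOLD,
    direction: str = "up",
) -> BinaryMatrix:
    """Threshold a log2 fold-change matrix into a 0/1 matrix.

    ``cutoff_fold`` is on the linear scale (2 means two-fold);
    thresholding is inclusive at exactly the cutoff.
    """
    if not cutoff_fold > 1:
        raise ValueError("cutoff_fold must be > 1")
    arr = np.asarray(merged, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("fold-change matrix contains non-finite values")
    thr = np.log2(cutoff_fold)
    if direction == "up":
        ind = arr >= thr
    elif direction == "down":
        ind = arr <= -thr
    else:
        raise ValueError("direction must be 'up' or 'down'")
    values = pd.DataFrame(
        ind.astype(np.uint8), index=merged.index, columns=merged.columns
    )
    return BinaryMatrix(values=values, direction=direction, cutoff_fold=cutoff_fold)


def _as_bool_array(matrix) -> tuple[np.ndarray, list, list, str]:
    if isinstance(matrix, BinaryMatrix):
        df = matrix.values
        direction = matrix.direction
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
        direction = "up"
    else:
        arr = np.asarray(matrix).astype(bool)
        return (
            arr,
            list(range(arr.shape[0])),
            list(range(arr.shape[1])),
            "up",
        )
    return (
        np.asarray(df, dtype=bool),
        list(df.index),
        list(df.columns),
        direction,
    )


def _row_bitmasks(arr: np.ndarray) -> list[int]:
    n_rows, n_cols = arr.shape
    weights = [1 << j for j in range(n_cols)]
    masks = []
    for i in range(n_rows):
        m = 0
        row = arr[i]
        for j in range(n_cols):
            if row[j]:
                m |= weights[j]
        masks.append(m)
    return masks


def _bits(mask: int) -> tuple[int, ...]:
    out = []
    j = 0
    while mask:
        if mask & 1:
            out.append(j)
        mask >>= 1
        j += 1
    return tuple(out)


def _enumerate_maximal(
    masks: Sequence[int],
    n_cols: int,
    min_rows: int,
    min_cols: int,
) -> set[tuple[tuple[int, ...], int]]:
    """Inclusion-maximal all-ones submatrices of a row-bitmask matrix.

    Divide and conquer: pick a template row whose support is a proper
    subset of the current columns, split the columns into the template's
    (shared) support and the (exclusive) rest, and recurse on (a) all
    rows restricted to the shared columns and (b) the rows with a 1 in
    an exclusive column on the unchanged column set. Every maximal
    bicluster survives intact down one of the branches and surfaces as
    an all-ones leaf; leaves that are non-maximal with respect to the
    full matrix are discarded by a closure check and duplicates removed.
    Returns a set of (sorted row index tuple, column bitmask) pairs.
    """
    full_cols = (1 << n_cols) - 1
    results: set[tuple[tuple[int, ...], int]] = set()
    seen: set[tuple[int, tuple[int, ...]]] = set()
    all_rows = [i for i in range(len(masks)) if masks[i]]

    stack: list[tuple[list[int], int]] = [(all_rows, full_cols)]
    while stack:
        rows, cols = stack.pop()
        rows = [r for r in rows if masks[r] & cols]
        if len(rows) < min_rows or bin(cols).count("1") < min_cols:
            continue
        key = (cols, tuple(rows))
        if key in seen:
            continue
        seen.add(key)
        template = None
        for r in rows:
            if masks[r] & cols != cols:
                template = r
                break
        if template is None:
            # all-ones leaf; keep only if maximal in the full matrix
            closure_rows = [r for r in all_rows if masks[r] & cols == cols]
            if len(closure_rows) != len(rows):
                continue  # not row-maximal; the maximal version is its own leaf
            inter = full_cols
            for r in closure_rows:
                inter &= masks[r]
            if inter != cols:
                continue  # not column-maximal
            results.add((tuple(closure_rows), cols))
            continue
        c1 = masks[template] & cols
        c2 = cols & ~c1
        stack.append((rows, c1))
        stack.append(([r for r in rows if masks[r] & c2], cols))
    return results


def bimax_enumerate(
    matrix,
    min_rows: int = 1,
    min_cols: int = 1,
) -> list[Bicluster]:
    """Enumerate all inclusion-maximal all-ones biclusters meeting size minima.

    Accepts a :class:`BinaryMatrix`, a 0/1 DataFrame, or a plain array.
    The output is sorted canonically (by column then row label tuples),
    so identical inputs give identical lists. An all-zero matrix yields
    an empty list.
    """
    if min_rows < 1 or min_cols < 1:
        raise ValueError("size minima must be >= 1")
    arr, row_labels, col_labels, direction = _as_bool_array(matrix)
    if arr.size == 0:
        return []
    masks = _row_bitmasks(arr)
    found = _enumerate_maximal(masks, arr.shape[1], min_rows, min_cols)
    out = []
    for rows, cols in found:
        genes = tuple(row_labels[r] for r in rows)
        conds = tuple(col_labels[j] for j in _bits(cols))
        out.append(Bicluster(genes=genes, conditions=conds, direction=direction))
    out.sort(key=lambda b: (b.conditions, b.genes))
    return out


def bruteforce_maximal_biclusters(
    matrix,
    min_rows: int = 1,
    min_cols: int = 1,
) -> list[Bicluster]:
    """Ground-truth enumeration by exhaustion over column subsets.

    For every nonempty column subset, takes all rows that are 1 on it
    and keeps the pair iff it is inclusion-maximal (the subset equals
    the intersection of those rows' supports) and meets the minima.
    Only feasible for <= 15 columns; intended as a test oracle.
    """
    arr, row_labels, col_labels, direction = _as_bool_array(matrix)
    n_rows, n_cols = arr.shape
    if n_cols > 15 or n_rows > 64:
        raise ValueError("brute-force oracle limited to <= 64 rows x 15 columns")
    masks = _row_bitmasks(arr)
    full_cols = (1 << n_cols) - 1
    found = set()
    for cols in range(1, full_cols + 1):
        rows = [r for r in range(n_rows) if masks[r] & cols == cols]
        if len(rows) < min_rows or bin(cols).count("1") < min_cols:
            continue
        inter = full_cols
        for r in rows:
            inter &= masks[r]
        if inter != cols:
            continue  # a column can be added -> not maximal
        found.add((tuple(rows), cols))
    out = [
        Bicluster(
            genes=tuple(row_labels[r] for r in rows),
            conditions=tuple(col_labels[j] for j in _bits(cols)),
            direction=direction,
        )
        for rows, cols in found
    ]
    out.sort(key=lambda b: (b.conditions, b.genes))
    return out


def _truncate_wide(
    rows: tuple[int, ...],
    cols: int,
    masks: Sequence[int],
    col_labels: Sequence,
    max_cols: int,
    n_rows: int,
) -> tuple[tuple[int, ...], int]:
    """Truncate a too-wide bicluster to max_cols columns, then re-extend rows.

    Keeps the columns with the most 1s outside the bicluster's rows
    (ties: lexicographically smallest label), favouring columns that
    stay informative elsewhere in the matrix.
    """
    row_set = set(rows)
    col_idx = _bits(cols)
    outside = {}
    for j in col_idx:
        bit = 1 << j
        outside[j] = sum(
            1 for r in range(n_rows) if r not in row_set and masks[r] & bit
        )
    ranked = sorted(col_idx, key=lambda j: (-outside[j], str(col_labels[j])))
    kept = ranked[:max_cols]
    new_cols = 0
    for j in kept:
        new_cols |= 1 << j
    new_rows = tuple(
        r for r in range(n_rows) if masks[r] & new_cols == new_cols
    )
    return new_rows, new_cols


def repeated_bimax(
    matrix,
    min_rows: int = DEFAULT_MIN_ROWS,
    min_cols: int = DEFAULT_MIN_COLS,
    max_cols: int = DEFAULT_MAX_COLS,
) -> BiclusterRun:
    """Iteratively extract biclusters, masking each one's cells to zero.

    Each round enumerates maximal biclusters of the current (masked)
    matrix, truncates any wider than ``max_cols``, and accepts the
    largest-area candidate (ties: more rows, then lexicographically
    smallest condition label set). Accepted cells are zeroed before
    the next round, so the total number of 1-cells strictly decreases
    and termination is guaranteed.
    """
    if min_cols > max_cols:
        raise ValueError("min_cols must be <= max_cols")
    arr, row_labels, col_labels, direction = _as_bool_array(matrix)
    cutoff = matrix.cutoff_fold if isinstance(matrix, BinaryMatrix) else DEFAULT_CUTOFF_FOLD
    digest = hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]
    work = arr.copy()
    n_rows = work.shape[0]
    accepted: list[Bicluster] = []
    while True:
        masks = _row_bitmasks(work)
        found = _enumerate_maximal(masks, work.shape[1], min_rows, min_cols)
        candidates = set()
        for rows, cols in found:
            if bin(cols).count("1") > max_cols:
                rows, cols = _truncate_wide(
                    rows, cols, masks, col_labels, max_cols, n_rows
                )
            if len(rows) >= min_rows and bin(cols).count("1") >= min_cols:
                candidates.add((rows, cols))
        if not candidates:
            break

        def sort_key(cand):
            rows, cols = cand
            area = len(rows) * bin(cols).count("1")
            labels = tuple(str(col_labels[j]) for j in _bits(cols))
            return (-area, -len(rows), labels, rows)

        rows, cols = min(candidates, key=sort_key)
        col_idx = _bits(cols)
        accepted.append(
            Bicluster(
                genes=tuple(row_labels[r] for r in rows),
                conditions=tuple(col_labels[j] for j in col_idx),
                direction=direction,
            )
        )
        work[np.ix_(list(rows), list(col_idx))] = False
    return BiclusterRun(
        biclusters=accepted,
        min_rows=min_rows,
        min_cols=min_cols,
        max_cols=max_cols,
        cutoff_fold=cutoff,
        direction=direction,
        source_digest=digest,
    )


def bicluster_both_directions(
    merged: pd.DataFrame,
    cutoff_fold: float = DEFAULT_CUTOFF_FOLD,
    min_rows: int = DEFAULT_MIN_ROWS,
    min_cols: int = DEFAULT_MIN_COLS,
    max_cols: int = DEFAULT_MAX_COLS,
) -> dict[str, BiclusterRun]:
    """Binarize a merged fold-change matrix both ways and run repeated Bimax."""
    return {
        direction: repeated_bimax(
            binarize(merged, cutoff_fold=cutoff_fold, direction=direction),
            min_rows=min_rows,
            min_cols=min_cols,
            max_cols=max_cols,
        )
        for direction in ("up", "down")
    }


def order_for_heatmap(
    merged: pd.DataFrame,
    subset: Iterable[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Leaf orderings of genes and conditions for heatmap display.

    Average-linkage (UPGMA) hierarchical clustering with distance
    1 - Spearman rho (midrank ties). Zero-variance rows or columns
    make the correlation undefined and are a hard error listing the
    offending labels.
    """
    sub = merged.loc[list(subset)] if subset is not None else merged
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 rows to order")

    def _order(df: pd.DataFrame, axis_name: str) -> list[str]:
        arr = np.asarray(df, dtype=float)
        flat = np.ptp(arr, axis=1) == 0
        if flat.any():
            bad = [str(lbl) for lbl, f in zip(df.index, flat) if f]
            raise ValueError(
                f"zero-variance {axis_name} make Spearman undefined: {bad}"
            )
        rho = spearmanr(arr, axis=1).statistic
        if np.ndim(rho) == 0:  # exactly two vectors -> scalar rho
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        dist = np.clip(1.0 - rho, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        link = average(squareform(dist, checks=False))
        return [df.index[i] for i in leaves_list(link)]

    row_order = _order(sub, "rows")
    col_order = _order(sub.T, "columns")
    return row_order, col_order


# ---------------------------------------------------------------------------
# serialisation

def run_to_dict(runs: dict[str, BiclusterRun]) -> dict:
    payload = {"parameters": {}, "biclusters": []}
    for direction, run in runs.items():
        payload["parameters"][direction] = {
            "min_rows": run.min_rows,
            "min_cols": run.min_cols,
            "max_cols": run.max_cols,
            "cutoff_fold": run.cutoff_fold,
            "source_digest": run.source_digest,
        }
        for k, bc in enumerate(run.biclusters, start=1):
            payload["biclusters"].append(
                {
                    "name": f"bicluster_{k}_{direction}",
                    "direction": direction,
                    "genes": list(bc.genes),
                    "conditions": list(bc.conditions),
                }
            )
    return payload


def write_run_json(runs: dict[str, BiclusterRun], path) -> None:
    with open(path, "w") as fh:
        json.dump(run_to_dict(runs), fh, indent=2, sort_keys=True)


def read_run_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
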