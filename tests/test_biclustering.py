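import numpy as np
import pandas as pd
import pytest

from bimaxgsea import (
    Bicluster,
    bimax_enumerate,
    binarize,
    bruteforce_maximal_biclusters,
    order_for_heatmap,
    repeated_bimax,
)


def as_sets(biclusters):
    return {(frozenset(b.genes), frozenset(b.conditions)) for b in biclusters}


class TestBinarize:
    @pytest.mark.parametrize(
        "log2fc,up,down",
        [
            (1.0, 1, 0),    # boundary inclusive
            (-1.3, 0, 1),
            (0.5, 0, 0),
            (-1.0, 0, 1),   # boundary inclusive, down
        ],
    )
    def test_thresholding(self, log2fc, up, down):
        df = pd.DataFrame({"c": [log2fc]}, index=["g"])
        assert binarize(df, 2.0, "up").values.iloc[0, 0] == up
        assert binarize(df, 2.0, "down").values.iloc[0, 0] == down

    def test_up_and_down_disjoint(self, rng):
        df = pd.DataFrame(rng.normal(scale=2.0, size=(50, 10)))
        up = binarize(df, 2.0, "up").values.to_numpy()
        down = binarize(df, 2.0, "down").values.to_numpy()
        assert not np.any(up & down)

    def test_nonfinite_rejected(self):
        df = pd.DataFrame({"c": [np.nan]})
        with pytest.raises(ValueError, match="non-finite"):
            binarize(df)

    def test_lower_cutoff_never_loses_ones(self, rng):
        df = pd.DataFrame(rng.normal(scale=1.0, size=(100, 20)))
        counts = [
            binarize(df, cf, "up").values.to_numpy().sum()
            + binarize(df, cf, "down").values.to_numpy().sum()
            for cf in (1.5, 1.75, 2.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestBimaxEnumerate:
    def test_three_row_worked_example(self):
        m = pd.DataFrame(
            [[1, 1, 0], [1, 1, 1], [0, 1, 1]],
            index=["r1", "r2", "r3"],
            columns=["c1", "c2", "c3"],
        )
        out = as_sets(bimax_enumerate(m, 2, 2))
        assert out == {
            (frozenset({"r1", "r2"}), frozenset({"c1", "c2"})),
            (frozenset({"r2", "r3"}), frozenset({"c2", "c3"})),
        }

    def test_all_ones_matrix_is_single_bicluster(self):
        m = np.ones((3, 3), dtype=int)
        out = bimax_enumerate(m, 2, 2)
        assert len(out) == 1
        assert out[0].n_genes == 3 and out[0].n_conditions == 3

    def test_identity_matrix_has_no_blocks(self):
        assert bimax_enumerate(np.eye(4, dtype=int), 2, 2) == []

    def test_all_zero_matrix_is_empty_not_error(self):
        assert bimax_enumerate(np.zeros((5, 5), dtype=int), 1, 1) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        density = rng.uniform(0.2, 0.8)
        m = (rng.random((6, 6)) < density).astype(int)
        assert as_sets(bimax_enumerate(m, 2, 2)) == as_sets(
            bruteforce_maximal_biclusters(m, 2, 2)
        )

    def test_every_result_is_all_ones_and_maximal(self, rng):
        m = (rng.random((10, 8)) < 0.5).astype(int)
        df = pd.DataFrame(m)
        for bc in bimax_enumerate(df, 2, 2):
            block = df.loc[list(bc.genes), list(bc.conditions)]
            assert block.to_numpy().all()
            # no row or column can be added
            others = df.drop(index=list(bc.genes))
            assert not others[list(bc.conditions)].all(axis=1).any()
            other_cols = df[df.columns.difference(bc.conditions)]
            assert not other_cols.loc[list(bc.genes)].all(axis=0).any()


class TestRepeatedBimax:
    def test_recovers_two_disjoint_planted_blocks(self, rng):
        m = (rng.random((40, 12)) < 0.01).astype(int)
        m[:15, :5] = 1
        m[20:35, 6:11] = 1
        run = repeated_bimax(pd.DataFrame(m), 15, 5, 15)
        got = as_sets(run.biclusters)
        assert (frozenset(range(15)), frozenset(range(5))) in got
        assert (frozenset(range(20, 35)), frozenset(range(6, 11))) in got

    def test_wide_block_truncated_to_max_cols(self):
        m = pd.DataFrame(np.ones((20, 20), dtype=int))
        run = repeated_bimax(m, 15, 5, 15)
        first = run.biclusters[0]
        assert first.n_conditions == 15 and first.n_genes == 20
        # truncation keeps the bicluster all-ones and row-maximal
        assert m.loc[list(first.genes), list(first.conditions)].to_numpy().all()
        assert set(first.genes) == set(m.index)

    def test_matrix_below_minima_gives_empty_run(self, rng):
        m = (rng.random((30, 10)) < 0.05).astype(int)
        assert len(repeated_bimax(pd.DataFrame(m), 15, 5, 15)) == 0

    def test_deterministic_including_order(self, rng):
        m = (rng.random((40, 12)) < 0.4).astype(int)
        a = repeated_bimax(pd.DataFrame(m), 3, 2, 6)
        b = repeated_bimax(pd.DataFrame(m), 3, 2, 6)
        assert a.biclusters == b.biclusters

    def test_each_bicluster_all_ones_at_discovery_and_masked_after(self, rng):
        m = (rng.random((40, 12)) < 0.4).astype(int)
        run = repeated_bimax(pd.DataFrame(m), 3, 2, 6)
        assert len(run) > 0
        work = m.copy()
        ones_before = work.sum()
        for bc in run.biclusters:
            rows = [int(g) for g in bc.genes]
            cols = [int(c) for c in bc.conditions]
            assert work[np.ix_(rows, cols)].all(), "cells not all-ones at discovery"
            work[np.ix_(rows, cols)] = 0
            assert work.sum() < ones_before, "masking must strictly reduce 1-cells"
            ones_before = work.sum()

    def test_min_cols_above_max_cols_rejected(self):
        with pytest.raises(ValueError, match="min_cols"):
            repeated_bimax(np.ones((5, 5), dtype=int), 2, 4, 3)


def _naive_upgma_heights(dist):
    """Average-linkage merge heights by direct agglomeration (test oracle)."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    d = dist.astype(float).copy()
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = keys[i], keys[j]
                dd = np.mean(
                    [d[x, y] for x in clusters[a] for y in clusters[b]]
                )
                if best is None or dd < best[0]:
                    best = (dd, a, b)
        dd, a, b = best
        heights.append(dd)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return sorted(heights)


class TestOrderForHeatmap:
    def test_identical_rows_are_adjacent(self, rng):
        base = rng.normal(size=6)
        m = pd.DataFrame(
            [base, rng.normal(size=6), base + 0.0, rng.normal(size=6)],
            index=["a", "x", "b", "y"],
        )
        row_order, _ = order_for_heatmap(m)
        ia, ib = row_order.index("a"), row_order.index("b")
        assert abs(ia - ib) == 1

    def test_antimonotone_pair_at_maximal_distance(self):
        # a and b are perfectly anti-monotone (rho = -1, distance 2);
        # c is monotone with a (distance 0), so a and c merge first and
        # b joins last
        m = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0],
                "b": [4.0, 3.0, 2.0, 1.0],
                "c": [1.1, 2.2, 2.9, 4.2],
            }
        ).T
        row_order, _ = order_for_heatmap(m)
        assert abs(row_order.index("a") - row_order.index("c")) == 1
        assert row_order.index("b") in (0, len(row_order) - 1)

    def test_merge_heights_match_naive_upgma(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform
        from scipy.stats import spearmanr

        m = rng.normal(size=(4, 10))
        rho = spearmanr(m, axis=1).statistic
        dist = 1.0 - rho
        np.fill_diagonal(dist, 0.0)
        link = average(squareform(dist, checks=False))
        assert np.allclose(sorted(link[:, 2]), _naive_upgma_heights(dist), atol=1e-12)

    def test_zero_variance_row_is_named_in_error(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 5)), index=["a", "flat", "c", "d"])
        m.loc["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            order_for_heatmap(m)

    def test_requires_three_rows(self, rng):
        m = pd.DataFrame(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match="3 rows"):
            order_for_heatmap(m)
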