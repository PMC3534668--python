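"""Country profiles, Spearman distances, and UPGMA agglomeration."""

import numpy as np
import pandas as pd
import pytest

from stemnet import clustering
from stemnet.clustering import ClusteringConfig
from ._oracles import naive_upgma, rank_pearson_distance


def _table(rows):
    return pd.DataFrame(
        [
            {
                "study_id": s, "line_id": l, "pub_year": 2005,
                "country": c, "funders": "NIH", "cell_class": "hESC",
            }
            for s, l, c in rows
        ]
    )


class TestCountryMatrix:
    def test_below_threshold_country_excluded(self):
        rows = [(f"s{i}", "A", "US") for i in range(30)]
        rows += [(f"t{i}", "A", "DE") for i in range(29)]
        mat = clustering.country_usage_matrix(_table(rows))
        assert list(mat.index) == ["US"]

    def test_single_country_single_line(self):
        rows = [(f"s{i}", "A", "US") for i in range(30)]
        mat = clustering.country_usage_matrix(_table(rows))
        assert mat.shape == (1, 1)
        assert mat.iloc[0, 0] == 30

    def test_no_qualifying_country_raises(self):
        with pytest.raises(ValueError, match="30"):
            clustering.country_usage_matrix(_table([("s1", "A", "US")]))

    def test_matches_crosstab_oracle(self, synth_tables):
        usage, _ = synth_tables
        cfg = ClusteringConfig(min_publications=30)
        mat = clustering.country_usage_matrix(usage, cfg)
        for country in mat.index:
            sub = usage[usage["country"] == country]
            counts = sub.groupby("line_id").size()
            for line in mat.columns:
                assert mat.loc[country, line] == counts.get(line, 0)

    def test_frequency_mode_preserves_ranks(self, synth_tables):
        usage, _ = synth_tables
        counts = clustering.country_usage_matrix(usage)
        freqs = clustering.country_usage_matrix(
            usage, ClusteringConfig(frequencies=True)
        )
        da = clustering.spearman_distance_matrix(counts)
        db = clustering.spearman_distance_matrix(freqs)
        pd.testing.assert_frame_equal(da, db, atol=1e-12, rtol=0)


class TestSpearmanDistance:
    def test_identical_rows_zero_distance(self):
        mat = pd.DataFrame([[1, 5, 3], [1, 5, 3]], index=["US", "DE"])
        d = clustering.spearman_distance_matrix(mat)
        assert d.loc["US", "DE"] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_distance_two(self):
        mat = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["US", "DE"])
        d = clustering.spearman_distance_matrix(mat)
        assert d.loc["US", "DE"] == pytest.approx(2.0, abs=1e-12)

    def test_matches_rank_pearson_oracle(self, rng):
        mat = pd.DataFrame(
            rng.integers(0, 50, size=(6, 15)).astype(float),
            index=[f"C{i}" for i in range(6)],
        )
        d = clustering.spearman_distance_matrix(mat)
        for i in range(6):
            for j in range(i + 1, 6):
                oracle = rank_pearson_distance(mat.iloc[i], mat.iloc[j])
                assert d.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_zero_diagonal_in_range(self, synth_tables):
        usage, _ = synth_tables
        mat = clustering.country_usage_matrix(usage)
        d = clustering.spearman_distance_matrix(mat)
        v = d.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert (v >= -1e-12).all() and (v <= 2 + 1e-12).all()

    def test_constant_row_error_names_country(self):
        mat = pd.DataFrame([[2, 2, 2], [1, 5, 3]], index=["XX", "DE"])
        with pytest.raises(ValueError, match="XX"):
            clustering.spearman_distance_matrix(mat)


class TestUPGMA:
    def test_two_leaves_merge_at_their_distance(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["A", "B"], columns=["A", "B"])
        tree = clustering.average_linkage_tree(d)
        assert tree.merges == [(("A",), ("B",), 0.7, 2)]
        assert tree.to_newick() == "(A:0.35,B:0.35);"

    def test_forced_merge_order(self):
        labels = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]], index=labels, columns=labels, dtype=float
        )
        tree = clustering.average_linkage_tree(d)
        (l1, r1, h1, _), (l2, r2, h2, _) = tree.merges
        assert {l1, r1} == {("A",), ("B",)} and h1 == 1.0
        assert h2 == 4.0

    def test_matches_naive_agglomeration_oracle(self, rng):
        labels = [f"C{i}" for i in range(8)]
        x = rng.random((8, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = pd.DataFrame(d, index=labels, columns=labels)
        tree = clustering.average_linkage_tree(dm)
        oracle = naive_upgma(labels, d)
        for (al, ar, ah, asz), (bl, br, bh, bsz) in zip(tree.merges, oracle):
            assert {al, ar} == {bl, br}
            assert ah == pytest.approx(bh, abs=1e-12)
            assert asz == bsz

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        labels = [f"C{i}" for i in range(9)]
        x = rng.random((9, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        tree = clustering.average_linkage_tree(pd.DataFrame(d, index=labels, columns=labels))
        ours = sorted(m[2] for m in tree.merges)
        scipys = sorted(linkage(squareform(d, checks=False), "average")[:, 2])
        assert np.allclose(ours, scipys, atol=1e-12)

    def test_heights_nondecreasing_and_permutation_invariant(self, synth_tables):
        usage, _ = synth_tables
        mat = clustering.country_usage_matrix(usage)
        d = clustering.spearman_distance_matrix(mat)
        tree = clustering.average_linkage_tree(d)
        heights = tree.heights()
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        perm = list(reversed(d.index))
        tree_p = clustering.average_linkage_tree(d.loc[perm, perm])
        assert [set(l + r) for l, r, _, _ in tree.merges] == [
            set(l + r) for l, r, _, _ in tree_p.merges
        ]

    def test_linkage_matrix_is_scipy_compatible(self):
        labels = ["A", "B", "C", "D"]
        d = pd.DataFrame(
            [[0, 1, 5, 6], [1, 0, 5.5, 6.5], [5, 5.5, 0, 2], [6, 6.5, 2, 0]],
            index=labels, columns=labels, dtype=float,
        )
        z = clustering.average_linkage_tree(d).to_linkage()
        from scipy.cluster.hierarchy import cophenet

        assert z.shape == (3, 4)
        assert (np.diff(z[:, 2]) >= 0).all()
        assert cophenet(z).shape == (6,)
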