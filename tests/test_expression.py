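import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denet.expression import (
    Contrast,
    CountMatrix,
    call_de,
    default_contrasts,
    log2_fold_changes,
    marker_panel_matrix,
    normalize_log,
    pca,
    read_counts,
    sample_distance_matrix,
    size_factors,
)


class TestReadCounts:
    def test_well_formed_table_parses_identically(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene_id\ts1\ts2\na\t1\t2\nb\t3\t4\nc\t5\t6\n")
        cm = read_counts(p)
        assert cm.shape == (3, 2)
        assert cm.gene_ids == ("a", "b", "c")
        assert cm.sample_ids == ("s1", "s2")
        np.testing.assert_array_equal(cm.counts, [[1, 2], [3, 4], [5, 6]])

    def test_duplicate_gene_id_names_the_duplicate(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene_id\ts1\na\t1\nb\t2\na\t3\n")
        with pytest.raises(ValueError, match="duplicate gene id.*a"):
            read_counts(p)

    def test_negative_cell_reports_coordinates(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene_id\ts1\ts2\na\t1\t2\nb\t3\t-4\n")
        with pytest.raises(ValueError, match="gene 'b'.*sample 's2'"):
            read_counts(p)

    def test_non_integer_cell_reports_coordinates(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene_id\ts1\na\t1.5\n")
        with pytest.raises(ValueError, match="non-integer.*'a'.*'s1'"):
            read_counts(p)


class TestSizeFactors:
    def test_doubled_column_gives_sqrt2_pair(self):
        cm = CountMatrix(("a", "b", "c"), ("s1", "s2"),
                         np.array([[4, 8], [10, 20], [7, 14]]))
        np.testing.assert_allclose(size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_identical_columns_give_unit_factors(self, small_counts):
        cm = CountMatrix(("a", "b"), ("s1", "s2", "s3"),
                         np.array([[5, 5, 5], [9, 9, 9]]))
        np.testing.assert_allclose(size_factors(cm), [1, 1, 1])

    def test_no_all_positive_row_is_an_error(self):
        cm = CountMatrix(("a", "b"), ("s1", "s2"), np.array([[0, 5], [3, 0]]))
        with pytest.raises(ValueError, match="no all-positive gene row"):
            size_factors(cm)

    @given(c=st.integers(min_value=2, max_value=16))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        """Scaling one column by c scales its factor by c and all by c^(-1/m)."""
        counts = np.array([[10, 20, 30], [100, 110, 90], [5, 8, 6]])
        base = size_factors(CountMatrix(("a", "b", "c"), ("s1", "s2", "s3"), counts))
        scaled = counts.copy()
        scaled[:, 0] *= c
        s = size_factors(CountMatrix(("a", "b", "c"), ("s1", "s2", "s3"), scaled))
        adj = float(c) ** (-1 / 3)
        np.testing.assert_allclose(s, base * adj * np.array([c, 1, 1]), rtol=1e-10)


class TestNormalizeLog:
    def test_all_zero_counts_map_to_zero(self):
        cm = CountMatrix(("a", "b"), ("s1",), np.zeros((2, 1), dtype=int))
        out = normalize_log(cm, np.ones(1), pseudocount=1.0)
        assert (out.to_numpy() == 0).all()

    def test_count_seven_unit_factor_gives_three(self):
        cm = CountMatrix(("a",), ("s1",), np.array([[7]]))
        assert normalize_log(cm, np.ones(1), 1.0).iat[0, 0] == pytest.approx(3.0)

    def test_matches_elementwise_oracle(self, rng):
        counts = rng.integers(0, 500, size=(5, 3))
        cm = CountMatrix(tuple("abcde"), ("x", "y", "z"), counts)
        s = np.array([0.8, 1.0, 1.3])
        out = normalize_log(cm, s, 0.5).to_numpy()
        expected = np.log2(counts / s + 0.5)
        np.testing.assert_allclose(out, expected)

    def test_nonpositive_pseudocount_rejected(self, small_counts):
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_log(small_counts, np.ones(4), 0.0)


class TestSampleDistance:
    def test_duplicated_sample_is_at_distance_zero(self, rng):
        x = rng.normal(size=(20, 1))
        m = pd.DataFrame(np.hstack([x, x, rng.normal(size=(20, 1))]),
                         columns=["a", "a2", "b"])
        d = sample_distance_matrix(m)
        assert d.loc["a", "a2"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_at_distance_two(self, rng):
        x = rng.normal(size=20)
        m = pd.DataFrame({"a": x, "b": -x})
        assert sample_distance_matrix(m).loc["a", "b"] == pytest.approx(2.0)

    def test_symmetric_with_zero_diagonal(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        d = sample_distance_matrix(m).to_numpy()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_array_equal(np.diag(d), np.zeros(5))

    def test_zero_variance_column_names_the_sample(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            sample_distance_matrix(m)


class TestPca:
    def test_variance_fractions_conserve_and_decrease(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 6)))
        _, frac = pca(m, 3)
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(frac) <= 1e-12).all()

    def test_identical_samples_have_identical_scores(self, rng):
        x = rng.normal(size=(30, 1))
        m = pd.DataFrame(np.hstack([x, x, rng.normal(size=(30, 2))]),
                         columns=["a", "a2", "b", "c"])
        scores, _ = pca(m, 2)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["a2"], atol=1e-8)

    def test_matches_sklearn_up_to_sign(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        m = pd.DataFrame(rng.normal(size=(10, 4)))
        scores, frac = pca(m, 3)
        ref = SkPCA(n_components=3).fit_transform(m.to_numpy().T)
        for k in range(3):
            col, refcol = scores.to_numpy()[:, k], ref[:, k]
            assert np.allclose(col, refcol, atol=1e-8) or np.allclose(col, -refcol, atol=1e-8)

    def test_rank_bound_enforced(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="n_components"):
            pca(m, 5)


class TestLog2FoldChanges:
    def test_identical_treated_and_control_counts_give_zero(self):
        counts = np.array([[10, 10], [200, 200], [7, 7]])
        cm = CountMatrix(("a", "b", "c"), ("t", "c0"), counts)
        lfc = log2_fold_changes(cm, [Contrast("x", ("t",), ("c0",))])
        np.testing.assert_allclose(lfc["x"], 0.0, atol=1e-12)

    def test_fourfold_counts_give_lfc_two(self):
        ctrl = np.array([1000, 5000, 2000])
        counts = np.column_stack([ctrl * 4, ctrl])
        cm = CountMatrix(("a", "b", "c"), ("t", "c0"), counts)
        # size factors would absorb a global 4x shift; pin them to 1 for the limit check
        lfc = log2_fold_changes(cm, [Contrast("x", ("t",), ("c0",))], pseudocount=1.0,
                                factors=np.ones(2))
        np.testing.assert_allclose(lfc["x"], 2.0, atol=0.01)

    def test_matches_definition_oracle(self, rng):
        counts = rng.integers(1, 1000, size=(8, 4))
        cm = CountMatrix(tuple(f"g{i}" for i in range(8)), ("a", "b", "c", "d"), counts)
        s = size_factors(cm)
        lfc = log2_fold_changes(cm, [Contrast("x", ("a", "b"), ("c", "d"))], 1.0)
        norm = np.log2(counts / s + 1.0)
        expected = norm[:, :2].mean(axis=1) - norm[:, 2:].mean(axis=1)
        np.testing.assert_allclose(lfc["x"], expected)

    def test_row_permutation_equivariance(self, rng):
        counts = rng.integers(1, 1000, size=(6, 2))
        ids = tuple(f"g{i}" for i in range(6))
        cm = CountMatrix(ids, ("t", "c0"), counts)
        lfc = log2_fold_changes(cm, [Contrast("x", ("t",), ("c0",))])
        perm = rng.permutation(6)
        cm2 = CountMatrix(tuple(ids[i] for i in perm), ("t", "c0"), counts[perm])
        lfc2 = log2_fold_changes(cm2, [Contrast("x", ("t",), ("c0",))])
        pd.testing.assert_series_equal(lfc["x"].sort_index(), lfc2["x"].sort_index())

    def test_unknown_sample_rejected(self, small_counts):
        with pytest.raises(ValueError, match="unknown sample"):
            log2_fold_changes(small_counts, [Contrast("x", ("nope",), ("s1",))])


class TestCallDe:
    @pytest.mark.parametrize(
        "lfc, de, sign",
        [(1.0, True, 1), (-1.2, True, -1), (0.99, False, 0), (-1.0, True, -1)],
    )
    def test_inclusive_threshold_and_sign(self, lfc, de, sign):
        profile = call_de(pd.DataFrame({"c": [lfc]}, index=["g"]))
        assert bool(profile.is_de.iat[0, 0]) is de
        assert profile.sign.iat[0, 0] == sign

    def test_global_sign_flip_preserves_de_set(self, rng):
        lfc = pd.DataFrame(rng.normal(scale=1.5, size=(50, 3)), columns=list("abc"))
        p1, p2 = call_de(lfc), call_de(-lfc)
        pd.testing.assert_frame_equal(p1.is_de, p2.is_de)
        pd.testing.assert_frame_equal(p1.sign, -p2.sign)


class TestMarkerPanel:
    def test_panel_order_preserved(self, rng):
        lfc = pd.DataFrame(rng.normal(size=(4, 2)), index=list("abcd"), columns=["x", "y"])
        mat, missing = marker_panel_matrix(lfc, ["d", "a", "c"])
        assert list(mat.index) == ["d", "a", "c"]
        assert missing == []

    def test_unknown_gene_reported_not_dropped_silently(self, rng):
        lfc = pd.DataFrame(rng.normal(size=(2, 1)), index=["a", "b"], columns=["x"])
        mat, missing = marker_panel_matrix(lfc, [("a", "grp1"), ("zz", "grp2")])
        assert missing == ["zz"]
        assert len(mat) == 1

    def test_empty_condition_list_is_an_error(self):
        lfc = pd.DataFrame(index=["a"], columns=[])
        with pytest.raises(ValueError, match="no condition columns"):
            marker_panel_matrix(lfc, ["a"])

    def test_empty_panel_is_an_error(self, rng):
        lfc = pd.DataFrame(rng.normal(size=(2, 1)), index=["a", "b"], columns=["x"])
        with pytest.raises(ValueError, match="empty"):
            marker_panel_matrix(lfc, [])


class TestDefaultContrasts:
    def test_dose_vs_control_shape(self, tiny_design):
        contrasts = default_contrasts(tiny_design)
        assert {c.name for c in contrasts} == {"D4_10nM", "D4_100nM", "D9_10nM", "D9_100nM"}

    def test_spontaneous_mode_uses_baseline(self, tiny_design):
        contrasts = default_contrasts(tiny_design, mode="spontaneous")
        assert {c.name for c in contrasts} == {"D4_0nM", "D9_0nM"}
        assert all(c.control == ("D0_0nM",) for c in contrasts)
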