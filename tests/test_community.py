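"""Community ecology: distances, ordination, pair groups, cohort comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from twinmeta.community_analysis import (
    DistanceMatrix,
    bray_curtis,
    compare_cohorts,
    compare_groups,
    distance_matrix,
    enumerate_pairs,
    ordinate,
    summarize_cohort,
)
from twinmeta.profile_io import AbundanceTable, MetadataTable
from twinmeta.simstudy import bray_curtis_reference


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_computed_value(self):
        assert bray_curtis([2, 1, 0], [1, 1, 1]) == pytest.approx(1 / 3)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    def test_semimetric_properties(self, rng):
        for _ in range(50):
            a, b = rng.random(12), rng.random(12)
            d = bray_curtis(a, b)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(b, a))
        assert bray_curtis(a, a) == 0.0


class TestDistanceMatrix:
    def test_matches_double_loop_oracle(self, rng):
        x = rng.random((8, 5))
        dm = distance_matrix(pd.DataFrame(x))
        for i in range(8):
            for j in range(8):
                expected = 0.0 if i == j else bray_curtis_reference(x[i], x[j])
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permutation_consistency(self, rng):
        x = pd.DataFrame(rng.random((6, 4)), index=list("abcdef"))
        dm = distance_matrix(x)
        perm = list("fabcde")
        dm2 = distance_matrix(x.loc[perm])
        for s1 in perm:
            for s2 in perm:
                assert dm2.between(s1, s2) == pytest.approx(dm.between(s1, s2))

    def test_all_zero_row_rejected(self):
        x = pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            distance_matrix(x)


class TestOrdinate:
    def test_equilateral_triangle_distances_reproduced(self):
        d = 0.7
        dm = DistanceMatrix(ids=["a", "b", "c"], values=d * (1 - np.eye(3)))
        coords = ordinate(dm, k=2).coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(d, abs=1e-8)

    def test_euclidean_configuration_recovered_in_full_rank(self, rng):
        pts = rng.random((7, 3))
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix(ids=[str(i) for i in range(7)],
                            values=squareform(pdist(pts)), metric="euclidean")
        coords = ordinate(dm, k=6).coordinates.to_numpy()
        emb = squareform(pdist(coords))
        np.testing.assert_allclose(emb, dm.values, atol=1e-8)

    def test_zero_distances_embed_at_origin(self):
        dm = DistanceMatrix(ids=list("abc"), values=np.zeros((3, 3)))
        assert np.all(ordinate(dm, k=2).coordinates.to_numpy() == 0.0)

    def test_too_many_dimensions_rejected(self):
        dm = DistanceMatrix(ids=list("abc"), values=0.5 * (1 - np.eye(3)))
        with pytest.raises(ValueError, match="k must"):
            ordinate(dm, k=4)

    def test_eigenvalues_decreasing_and_nonnegative(self, rng):
        x = rng.random((10, 6))
        res = ordinate(distance_matrix(pd.DataFrame(x)), k=3)
        eig = res.eigenvalues
        assert np.all(eig > 0)
        assert np.all(np.diff(eig) <= 1e-12)


def _tiny_metadata(n_pairs=2, n_timepoints=2):
    rows = []
    for p in range(n_pairs):
        for letter in "ab":
            for tp in range(1, n_timepoints + 1):
                subj = f"pair{p}{letter}"
                rows.append((f"{subj}_t{tp}", subj, f"pair{p}", tp))
    return MetadataTable(
        data=pd.DataFrame(rows, columns=["sample_id", "subject_id", "pair_id", "timepoint"])
    )


class TestEnumeratePairs:
    def test_counts_for_two_pairs_two_timepoints(self):
        pairs = enumerate_pairs(_tiny_metadata())
        assert len(pairs.by_type("self")) == 4
        assert len(pairs.by_type("twin")) == 2
        assert len(pairs.by_type("unrelated")) == 4  # C(4,2) - 2 at time point 1

    def test_single_timepoint_has_no_self_pairs(self):
        with pytest.warns(UserWarning, match="self group"):
            pairs = enumerate_pairs(_tiny_metadata(n_timepoints=1))
        assert pairs.by_type("self") == []

    def test_sample_never_paired_with_itself(self):
        for a, b, _ in enumerate_pairs(_tiny_metadata()).pairs:
            assert a != b


class TestCompareGroups:
    def test_degenerate_equal_groups(self):
        gc = compare_groups({"x": [2.0, 2.0, 2.0], "y": [2.0, 2.0]}, contrasts=[("x", "y")])
        assert gc.tests[("x", "y")] == (0.0, 1.0)

    def test_strong_shift_detected(self, rng):
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(5.0, 1.0, 20)
        _, p = compare_groups({"a": a, "b": b}, contrasts=[("a", "b")]).tests[("a", "b")]
        assert p < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="'y'"):
            compare_groups({"x": [1.0, 2.0], "y": [1.0]}, contrasts=[("x", "y")])

    def test_null_pvalues_uniform(self):
        ps = []
        for s in range(100):
            r = np.random.default_rng(s)
            gc = compare_groups(
                {"a": r.normal(size=50), "b": r.normal(size=50)}, contrasts=[("a", "b")]
            )
            ps.append(gc.tests[("a", "b")][1])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestCohortSummary:
    def _table(self, values):
        lineage = "k__B|p__P|c__C|o__O|f__F|g__G|s__Sp"
        return AbundanceTable(
            data=pd.DataFrame({lineage: values}, index=[f"S{i}" for i in range(len(values))])
        )

    def test_prevalence_and_conditional_mean(self):
        summary = summarize_cohort(self._table([0.0005, 0.002, 0.01, 0.0]))
        row = summary.table.iloc[0]
        assert row["prevalence"] == pytest.approx(50.0)
        assert row["conditional_mean"] == pytest.approx(0.006)

    def test_threshold_comparison_is_strict(self):
        summary = summarize_cohort(self._table([0.001, 0.001]))
        assert summary.table["prevalence"].iloc[0] == 0.0

    def test_never_present_clade_flagged_undefined(self):
        summary = summarize_cohort(self._table([0.0, 0.0]))
        assert summary.table["prevalence"].iloc[0] == 0.0
        assert np.isnan(summary.table["conditional_mean"].iloc[0])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(self._table([0.1]), threshold=-0.01)


class TestCompareCohorts:
    def _summary(self, prev, mean):
        df = pd.DataFrame({"prevalence": prev, "conditional_mean": mean},
                          index=[f"sp{i}" for i in range(len(prev))])
        from twinmeta.community_analysis import CohortSummary
        return CohortSummary(table=df, threshold=0.001)

    def test_cohort_vs_itself(self, rng):
        s = self._summary(rng.random(10) * 100, rng.random(10))
        out = compare_cohorts(s, s)
        assert out["prevalence"][0] == pytest.approx(1.0)

    def test_exact_negative_linear_transform(self, rng):
        prev = rng.random(10) * 100
        mean = rng.random(10)
        a = self._summary(prev, mean)
        b = self._summary(100 - prev, 1 - mean)
        out = compare_cohorts(a, b)
        assert out["prevalence"][0] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self, rng):
        pa, pb = rng.random(10), rng.random(10)
        a = self._summary(pa, rng.random(10))
        b = self._summary(pb, rng.random(10))
        r = compare_cohorts(a, b)["prevalence"][0]
        xa, xb = pa - pa.mean(), pb - pb.mean()
        expected = float((xa @ xb) / np.sqrt((xa @ xa) * (xb @ xb)))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        a = self._summary([50.0] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])
        b = self._summary([10, 20, 30, 40, 50], [0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(ValueError, match="constant"):
            compare_cohorts(a, b)
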