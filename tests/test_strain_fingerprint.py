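"""Strain barcodes: RPK math, eligibility, distances, bins, group tests."""

import numpy as np
import pandas as pd
import pytest

from twinmeta.community_analysis import PairSet
from twinmeta.profile_io import MarkerProfileSet
from twinmeta.strain_fingerprint import (
    Barcode,
    MarkerVector,
    StrainComparison,
    barcode_diff,
    compare_strain_groups,
    eligible_comparisons,
    make_barcode,
    marker_rpk,
    rpk_to_coverage,
    species_mean_divergence,
    strain_distance,
)


class TestRpkMath:
    def test_marker_rpk_formula(self):
        assert marker_rpk(50, 2000) == pytest.approx(25.0)
        assert marker_rpk(0, 500) == 0.0
        with pytest.raises(ValueError):
            marker_rpk(10, 0)

    def test_coverage_anchor_ten_rpk_is_one_fold(self):
        assert rpk_to_coverage(10.0, 100.0) == 1.0
        assert rpk_to_coverage(0.0, 100.0) == 0.0
        assert rpk_to_coverage(20.0, 100.0) == 2.0
        with pytest.raises(ValueError):
            rpk_to_coverage(5.0, 0.0)

    def test_composition_simplifies_exactly(self, rng):
        for _ in range(100):
            reads = int(rng.integers(0, 1000))
            length = int(rng.integers(100, 5000))
            read_len = int(rng.integers(50, 300))
            composed = rpk_to_coverage(marker_rpk(reads, length), read_len)
            assert composed == pytest.approx(reads * read_len / length, rel=1e-15)


def _marker_set(values_by_species, samples):
    return MarkerProfileSet(
        species_tables={
            sp: pd.DataFrame(v, index=samples, columns=[f"m{i}" for i in range(len(v[0]))])
            for sp, v in values_by_species.items()
        }
    )


class TestEligibility:
    def _pairs(self):
        return PairSet(pairs=[("S1", "S2", "twin")])

    def test_both_medians_above_threshold(self):
        mset = _marker_set({"Sp": [[6.0, 6.0, 6.0], [6.0, 6.0, 6.0]]}, ["S1", "S2"])
        assert len(eligible_comparisons(mset, self._pairs())) == 1

    def test_strictly_greater_than_rule(self):
        mset = _marker_set({"Sp": [[6.0, 6.0, 6.0], [5.0, 5.0, 5.0]]}, ["S1", "S2"])
        assert eligible_comparisons(mset, self._pairs()) == []

    def test_absent_species_excluded(self):
        mset = _marker_set({"Sp": [[20.0, 20.0, 20.0], [0.0, 0.0, 0.0]]}, ["S1", "S2"])
        assert eligible_comparisons(mset, self._pairs()) == []

    def test_zero_markers_count_toward_median(self):
        # median over ALL markers including zeros: (0, 0, 30) -> median 0
        mset = _marker_set({"Sp": [[0.0, 0.0, 30.0], [0.0, 0.0, 30.0]]}, ["S1", "S2"])
        assert eligible_comparisons(mset, self._pairs()) == []

    def test_raising_threshold_is_monotone(self, rng):
        mset = _marker_set({"Sp": list(rng.random((4, 5)) * 20)}, ["S1", "S2", "S3", "S4"])
        pairs = PairSet(pairs=[("S1", "S2", "twin"), ("S3", "S4", "unrelated"),
                               ("S1", "S3", "unrelated")])
        previous = None
        for thr in (0.0, 2.0, 5.0, 10.0, 50.0):
            current = set(eligible_comparisons(mset, pairs, thr))
            if previous is not None:
                assert current <= previous
            previous = current


class TestStrainDistance:
    def _vec(self, rpk, species="Sp", sample="S1"):
        return MarkerVector(species=species, sample_id=sample,
                            rpk=pd.Series(rpk, index=[f"m{i}" for i in range(len(rpk))]))

    def test_identical_profiles(self):
        assert strain_distance(self._vec([1, 2, 3]), self._vec([1, 2, 3], sample="S2")) == 0.0

    def test_disjoint_presence(self):
        assert strain_distance(self._vec([5, 0]), self._vec([0, 7], sample="S2")) == 1.0

    def test_hand_computed(self):
        d = strain_distance(self._vec([10, 0, 5]), self._vec([0, 10, 5], sample="S2"))
        assert d == pytest.approx(2 / 3)

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            strain_distance(self._vec([1]), self._vec([1], species="Other"))


class TestBarcode:
    def _vec(self, rpk):
        return MarkerVector(species="Sp", sample_id="S1",
                            rpk=pd.Series(rpk, index=[f"m{i}" for i in range(len(rpk))]))

    def test_default_binning(self):
        bc = make_barcode(self._vec([0.0, 0.5, 5.0, 50.0]))
        assert bc.levels.tolist() == ["absent", "low", "mid", "high"]
        assert bc.presence.tolist() == [False, True, True, True]

    def test_unsorted_bounds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_barcode(self._vec([1.0]), level_bounds=(10.0, 1.0))

    def test_diff_marks_presence_discordance(self):
        a = make_barcode(self._vec([5.0, 0.0, 2.0]))
        b = make_barcode(self._vec([5.0, 3.0, 2.0]))
        d = barcode_diff(a, b)
        assert d["discordant"].tolist() == [False, True, False]
        none = barcode_diff(a, a)
        assert not none["discordant"].any()

    def test_complementary_barcodes_all_marked(self):
        a = make_barcode(self._vec([1.0, 0.0, 1.0, 0.0]))
        b = make_barcode(self._vec([0.0, 1.0, 0.0, 1.0]))
        assert barcode_diff(a, b)["discordant"].sum() == 4


def test_barcode_discordance_table_counts_presence_flips():
    from twinmeta.strain_fingerprint import barcode_discordance_table
    mset = _marker_set({"Sp": [[10.0, 0.0, 5.0], [10.0, 3.0, 0.0]]}, ["S1", "S2"])
    comps = [StrainComparison("Sp", "S1", "S2", "twin", 0.4),
             StrainComparison("Sp", "S1", "S2", "unrelated", 0.4)]
    out = barcode_discordance_table(mset, comps)
    assert len(out) == 1  # unrelated comparisons are not reported
    assert out["n_discordant_markers"].iloc[0] == 2
    assert out["n_markers"].iloc[0] == 3


class TestGroupTests:
    def test_identical_groups_give_null_statistic(self):
        comps = [StrainComparison("Sp", "a", "b", t, d)
                 for t in ("twin", "self") for d in (0.2, 0.2, 0.2)]
        gc = compare_strain_groups(comps, contrasts=[("twin", "self")])
        assert gc.tests[("twin", "self")] == (0.0, 1.0)

    def test_small_group_rejected(self):
        comps = [StrainComparison("Sp", "a", "b", "twin", 0.1),
                 StrainComparison("Sp", "a", "c", "twin", 0.2),
                 StrainComparison("Sp", "a", "d", "self", 0.1)]
        with pytest.raises(ValueError, match="self"):
            compare_strain_groups(comps, contrasts=[("twin", "self")])


class TestSpeciesMeanDivergence:
    def test_single_and_pair_means(self):
        comps = [StrainComparison("Sp", "a", "b", "twin", 0.2),
                 StrainComparison("Sp", "c", "d", "twin", 0.4),
                 StrainComparison("Other", "a", "b", "self", 0.5)]
        out = species_mean_divergence(comps).set_index(["species", "pair_type"])
        assert out.loc[("Sp", "twin"), "mean_distance"] == pytest.approx(0.3)
        assert out.loc[("Sp", "twin"), "n"] == 2
        assert out.loc[("Other", "self"), "mean_distance"] == pytest.approx(0.5)

    def test_matches_pandas_groupby_oracle(self, rng):
        comps = [
            StrainComparison(f"sp{int(rng.integers(3))}", "a", "b",
                             ["twin", "self", "unrelated"][int(rng.integers(3))],
                             float(rng.random()))
            for _ in range(60)
        ]
        out = species_mean_divergence(comps).set_index(["species", "pair_type"])
        df = pd.DataFrame([(c.species, c.pair_type, c.distance) for c in comps],
                          columns=["species", "pair_type", "distance"])
        for (sp, pt), grp in df.groupby(["species", "pair_type"]):
            assert out.loc[(sp, pt), "mean_distance"] == pytest.approx(grp["distance"].mean())
            assert out.loc[(sp, pt), "n"] == len(grp)
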