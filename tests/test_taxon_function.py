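"""Taxon-function correlations, co-occurrence network and classification."""

import numpy as np
import pandas as pd
import pytest

from twinmeta.profile_io import AbundanceTable, CarriageMatrix, FunctionTable
from twinmeta.simstudy import spearman_rho_reference
from twinmeta.taxon_function import (
    CooccurrenceNetwork,
    classify_correlations,
    cooccurrence_network,
    correlation_matrix,
    cross_cohort_overlap,
    spearman,
)


def _lineage(name):
    return f"k__B|p__P|c__C|o__O|f__F|g__G|s__{name}"


def _abundance(values, names, samples=None):
    samples = samples or [f"S{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=samples, columns=[_lineage(n) for n in names])
    return AbundanceTable(data=df / max(1.0, df.to_numpy().max() * len(names)))


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(10, dtype=float)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_tie_handling_matches_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_rho_reference(x, y), abs=1e-15)

    def test_random_tied_vectors_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y)[0] == pytest.approx(spearman_rho_reference(x, y), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_cell_count_is_product(self, rng):
        taxa = _abundance(rng.random((10, 5)) + 0.01, [f"t{i}" for i in range(5)])
        modules = FunctionTable(data=pd.DataFrame(
            rng.random((10, 7)), index=taxa.sample_ids, columns=[f"M{i:05d}" for i in range(7)]))
        records = correlation_matrix(taxa, modules)
        assert len(records) == 35

    def test_each_cell_matches_scalar_op(self, rng):
        taxa = _abundance(rng.random((12, 3)) + 0.01, ["a", "b", "c"])
        modules = FunctionTable(data=pd.DataFrame(
            rng.random((12, 2)), index=taxa.sample_ids, columns=["M00001", "M00002"]))
        records = correlation_matrix(taxa, modules).set_index(["taxon", "module"])
        for t in ["a", "b", "c"]:
            x = taxa.data[_lineage(t)].to_numpy()
            for m in ["M00001", "M00002"]:
                rho, p = spearman(x, modules.data[m].to_numpy())
                assert records.loc[(t, m), "rho"] == pytest.approx(rho, abs=1e-12)
                assert records.loc[(t, m), "p"] == pytest.approx(p, abs=1e-12)

    def test_self_correlation_layout_has_unit_diagonal(self, rng):
        x = rng.random((10, 4)) + 0.01
        taxa = _abundance(x, [f"t{i}" for i in range(4)])
        modules = FunctionTable(data=pd.DataFrame(
            taxa.data.to_numpy(), index=taxa.sample_ids, columns=[f"t{i}" for i in range(4)]))
        records = correlation_matrix(taxa, modules).set_index(["taxon", "module"])
        for i in range(4):
            assert records.loc[(f"t{i}", f"t{i}"), "rho"] == pytest.approx(1.0)

    def test_invariant_to_sample_order(self, rng):
        taxa = _abundance(rng.random((10, 4)) + 0.01, [f"t{i}" for i in range(4)])
        modules = FunctionTable(data=pd.DataFrame(
            rng.random((10, 3)), index=taxa.sample_ids, columns=["M1", "M2", "M3"]))
        base = correlation_matrix(taxa, modules)
        perm = list(rng.permutation(taxa.sample_ids))
        taxa2 = AbundanceTable(data=taxa.data.loc[perm])
        modules2 = FunctionTable(data=modules.data.loc[perm])
        again = correlation_matrix(taxa2, modules2)
        pd.testing.assert_frame_equal(base, again, rtol=1e-12)

    def test_too_few_shared_samples_rejected(self, rng):
        taxa = _abundance(rng.random((3, 4)) + 0.01, [f"t{i}" for i in range(4)])
        modules = FunctionTable(data=pd.DataFrame(
            rng.random((3, 2)), index=taxa.sample_ids, columns=["M1", "M2"]))
        with pytest.raises(ValueError, match="4 shared samples"):
            correlation_matrix(taxa, modules)


class TestCooccurrenceNetwork:
    def test_fewer_than_three_taxa_rejected(self, rng):
        taxa = _abundance(rng.random((10, 2)) + 0.01, ["a", "b"])
        with pytest.raises(ValueError, match="3 taxa"):
            cooccurrence_network(taxa)

    def test_perfectly_covarying_pair_found(self, rng):
        base = rng.random(40)
        data = np.column_stack([base, base * 2, rng.random(40), rng.random(40)])
        taxa = _abundance(data + 0.01, ["a", "a2", "n1", "n2"])
        net = cooccurrence_network(taxa)
        assert frozenset(("a", "a2")) in net.edges
        assert net.neighbors("a") >= {"a2"}

    def test_diagonal_never_an_edge(self, rng):
        taxa = _abundance(rng.random((20, 5)) + 0.01, [f"t{i}" for i in range(5)])
        net = cooccurrence_network(taxa)
        assert all(len(e) == 2 for e in net.edges)

    def test_null_false_edge_rate_bounded(self):
        rates = []
        for s in range(50):
            rng = np.random.default_rng(s)
            taxa = _abundance(rng.random((100, 10)) + 0.01, [f"t{i}" for i in range(10)])
            net = cooccurrence_network(taxa, q_threshold=0.2)
            rates.append(len(net.edges) / 45)
        assert np.mean(rates) <= 0.2 + 0.1


def _records(rows):
    return pd.DataFrame(rows, columns=["taxon", "module", "rho", "p", "q", "tier"])


def _network(taxa, edges):
    n = len(taxa)
    return CooccurrenceNetwork(
        taxa=list(taxa),
        rho=pd.DataFrame(np.eye(n), index=taxa, columns=taxa),
        q=pd.DataFrame(np.ones((n, n)), index=taxa, columns=taxa),
        edges={frozenset(e) for e in edges},
    )


class TestClassification:
    def _fixture(self):
        records = _records([
            ("carrier", "M1", 0.8, 0.001, 0.01, "fdr"),
            ("friend", "M1", 0.7, 0.002, 0.02, "fdr"),
            ("loner", "M1", 0.6, 0.003, 0.03, "fdr"),
            ("negative", "M1", -0.7, 0.001, 0.01, "fdr"),
            ("carrier", "M2", 0.1, 0.5, 0.8, "none"),
        ])
        carriage = CarriageMatrix(data=pd.DataFrame(
            {"M1": [1.0, 0.0, 0.0, 0.0], "M2": [1.0, 0.0, 0.0, 0.0]},
            index=["carrier", "friend", "loner", "negative"]))
        network = _network(["carrier", "friend", "loner", "negative"],
                           [("carrier", "friend")])
        return records, carriage, network

    def test_rules(self):
        records, carriage, network = self._fixture()
        out = classify_correlations(records, carriage, network).set_index(["taxon", "module"])
        assert out.loc[("carrier", "M1"), "class"] == "encoded"
        assert out.loc[("friend", "M1"), "class"] == "associated"
        assert out.loc[("loner", "M1"), "class"] == "unexplained"
        assert out.loc[("negative", "M1"), "class"] == "not-classified"
        assert out.loc[("carrier", "M2"), "class"] == "not-classified"

    def test_exhaustive_and_mutually_exclusive(self):
        records, carriage, network = self._fixture()
        out = classify_correlations(records, carriage, network)
        sig_pos = out[(out["tier"] != "none") & (out["rho"] > 0)]
        assert set(sig_pos["class"]) <= {"encoded", "associated", "unexplained"}
        rest = out[(out["tier"] == "none") | (out["rho"] <= 0)]
        assert set(rest["class"]) <= {"not-classified"}

    def test_raising_threshold_never_increases_encoded(self):
        records, carriage, network = self._fixture()
        counts = []
        for thr in (0.1, 0.5, 0.9, 1.0):
            out = classify_correlations(records, carriage, network, encoded_threshold=thr)
            counts.append(int((out["class"] == "encoded").sum()))
        assert counts == sorted(counts, reverse=True)

    def test_missing_carriage_treated_as_zero_with_warning(self):
        records, _, network = self._fixture()
        carriage = CarriageMatrix(data=pd.DataFrame({"M1": [1.0]}, index=["carrier"]))
        with pytest.warns(UserWarning, match="missing"):
            out = classify_correlations(records, carriage, network)
        assert (out.set_index("taxon").loc["friend", "carriage"] == 0.0).all()


class TestCrossCohortOverlap:
    def test_identical_sets_fully_overlap(self):
        r = _records([("a", "M1", 0.8, 0.001, 0.01, "fdr"),
                      ("b", "M2", 0.5, 0.02, 0.3, "nominal")])
        out = cross_cohort_overlap(r, r, tier="fdr")
        assert len(out) == 1 and out["taxon"].iloc[0] == "a"
        assert len(cross_cohort_overlap(r, r, tier="nominal")) == 2

    def test_disjoint_sets_empty(self):
        a = _records([("a", "M1", 0.8, 0.001, 0.01, "fdr")])
        b = _records([("b", "M2", 0.8, 0.001, 0.01, "fdr")])
        assert len(cross_cohort_overlap(a, b)) == 0

    def test_sign_flip_excluded(self):
        a = _records([("a", "M1", 0.8, 0.001, 0.01, "fdr")])
        b = _records([("a", "M1", -0.8, 0.001, 0.01, "fdr")])
        assert len(cross_cohort_overlap(a, b)) == 0
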