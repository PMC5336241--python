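import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceshift.enrichment_stats import (ContingencyTable2x2, QpcrMeasurement,
                                          chi_square_2x2,
                                          event_type_distribution_test,
                                          pfaffl_ratio, propagate_annotations,
                                          splicing_gene_enrichment,
                                          term_enrichment)

from ._oracles import bh_stepup, exact_hypergeom_upper_p, permutation_chi2_p


class TestChiSquare:
    def test_independent_table(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(20, 10, 10, 20))
        assert stat == pytest.approx(20 / 3)
        assert p == pytest.approx(0.00982, abs=2e-4)

    def test_zero_marginal_degenerates_to_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p = chi_square_2x2(ContingencyTable2x2(5, 7, 0, 0))
        assert (stat, p) == (0.0, 1.0)

    @pytest.mark.parametrize("cells", [
        (120, 80, 90, 110), (60, 45, 45, 60), (200, 150, 170, 190),
    ])
    def test_agrees_with_permutation_null(self, cells):
        stat, p = chi_square_2x2(ContingencyTable2x2(*cells))
        p_perm, se = permutation_chi2_p(*cells, n_perm=10_000, seed=7)
        assert abs(p - p_perm) < 3 * se + 1e-12


class TestEventTypeDistribution:
    @staticmethod
    def table(type_counts):
        rows = [{"event_id": f"{t}{i}", "etype": t}
                for t, n in type_counts.items() for i in range(n)]
        return pd.DataFrame(rows, columns=["event_id", "etype"])

    def test_identical_distribution_is_flat(self):
        counts = {"RI": 40, "SE": 30, "A5": 10, "A3": 10, "MXE": 10}
        total = self.table(counts)
        out = event_type_distribution_test(total, total)
        assert (out["statistic"] < 1e-9).all()
        assert (out["p"] > 0.99).all()

    def test_planted_ri_excess_flagged_enriched(self):
        total = self.table({"RI": 100, "SE": 100, "A5": 100, "A3": 100,
                            "MXE": 100})
        diff = total[(total["etype"] == "RI") |
                     (total["event_id"].isin(
                         [f"{t}{i}" for t in ("SE", "A5", "A3", "MXE")
                          for i in range(10)]))]
        out = event_type_distribution_test(diff, total).set_index("etype")
        assert out.loc["RI", "direction"] == "enriched"
        assert out.loc["RI", "p"] < 0.01

    def test_single_type_catalog_degenerates(self):
        total = self.table({"RI": 20})
        out = event_type_distribution_test(total.head(5), total)
        assert out.set_index("etype").loc["RI", "p"] == pytest.approx(1.0)

    def test_differential_must_be_subset(self):
        total = self.table({"RI": 5})
        rogue = self.table({"SE": 1})
        with pytest.raises(ValueError, match="subset"):
            event_type_distribution_test(rogue, total)


class TestSplicingGeneEnrichment:
    def test_flat_fractions_not_significant(self):
        universe = {f"g{i}" for i in range(200)}
        splicing = {f"g{i}" for i in range(0, 200, 10)}      # 10% everywhere
        diff = {f"g{i}" for i in range(0, 100)}
        frac, stat, p = splicing_gene_enrichment(diff, splicing, universe)
        assert frac == pytest.approx(0.1)
        assert p > 0.5

    def test_planted_threefold_enrichment_detected(self):
        universe = {f"g{i}" for i in range(1000)}
        splicing = {f"g{i}" for i in range(100)}
        diff = {f"g{i}" for i in range(30)} | {f"g{i}" for i in range(100, 170)}
        frac, stat, p = splicing_gene_enrichment(diff, splicing, universe)
        assert frac == pytest.approx(0.3)
        assert p < 0.01

    def test_empty_differential_set(self):
        frac, stat, p = splicing_gene_enrichment(set(), {"g1"}, {"g1", "g2"})
        assert np.isnan(frac) and p == 1.0

    def test_diff_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            splicing_gene_enrichment({"gX"}, set(), {"g1"})


class TestTermEnrichment:
    def test_study_equal_to_reference_is_null(self):
        universe = [f"g{i}" for i in range(10)]
        ann = {g: {"T1"} for g in universe[:4]}
        out = term_enrichment(ann, universe, universe, propagate=False)
        assert np.allclose(out["p"], 1.0)

    def test_fully_annotated_study_exact_p(self):
        # study of 5, term annotates 5 of 20: p = 1 / C(20, 5)
        universe = [f"g{i}" for i in range(20)]
        ann = {g: {"T1"} for g in universe[:5]}
        out = term_enrichment(ann, universe[:5], universe, propagate=False)
        from math import comb
        assert out.loc[0, "p"] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    @pytest.mark.parametrize("universe,annotated,study,hits", [
        (20, 6, 5, 3), (25, 8, 4, 2), (15, 5, 5, 4),
    ])
    def test_hypergeometric_matches_exact_enumeration(self, universe,
                                                      annotated, study, hits):
        genes = [f"g{i}" for i in range(universe)]
        ann = {g: {"T"} for g in genes[:annotated]}
        study_set = genes[:hits] + genes[annotated:annotated + study - hits]
        out = term_enrichment(ann, study_set, genes, propagate=False)
        expected = exact_hypergeom_upper_p(universe, annotated, study, hits)
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_bh_stepup_matches_hand_computation(self):
        # three terms engineered to give ordered raw p-values; the adjusted
        # values must match the literal step-up recursion
        universe = [f"g{i}" for i in range(30)]
        ann = {}
        for g in universe[:6]:
            ann.setdefault(g, set()).add("T1")
        for g in universe[:12]:
            ann.setdefault(g, set()).add("T2")
        for g in universe[:20]:
            ann.setdefault(g, set()).add("T3")
        out = term_enrichment(ann, universe[:6], universe, propagate=False)
        assert list(out["q"]) == pytest.approx(bh_stepup(out["p"]))
        assert (out["q"] >= out["p"]).all()
        assert out["q"].max() <= 1.0

    def test_bh_on_canonical_vector(self):
        assert bh_stepup([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_propagation_adds_ancestor_hits(self):
        ann = {"g1": {"child"}, "g2": {"child"}, "g3": {"parent"}}
        edges = [("child", "parent"), ("parent", "root")]
        propagated = propagate_annotations(ann, edges)
        assert propagated["g1"] == {"child", "parent", "root"}
        universe = ["g1", "g2", "g3", "g4"]
        out = term_enrichment(ann, ["g1", "g2"], universe,
                              propagate=True, parent_edges=edges)
        hits = out.set_index("term_id")["study_hits"]
        assert hits["parent"] >= hits["child"]
        assert hits["root"] >= hits["parent"]

    def test_cyclic_parent_graph_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            propagate_annotations({"g": {"a"}}, [("a", "b"), ("b", "a")])

    def test_study_gene_outside_reference_named(self):
        with pytest.raises(ValueError, match="gX"):
            term_enrichment({}, ["gX"], ["g1"], propagate=False)


class TestPfaffl:
    def test_no_change(self):
        m = QpcrMeasurement(2.0, 2.0, 0.0, 0.0)
        assert pfaffl_ratio(m) == pytest.approx(1.0)

    def test_three_cycle_shift_is_eightfold(self):
        m = QpcrMeasurement(2.0, 2.0, 3.0, 0.0)
        assert pfaffl_ratio(m) == pytest.approx(8.0)

    def test_unequal_efficiencies(self):
        m = QpcrMeasurement(1.9, 1.8, 2.0, 1.0)
        assert pfaffl_ratio(m) == pytest.approx(1.9 ** 2 / 1.8)

    @pytest.mark.parametrize("bad", [1.0, 0.5, 2.5])
    def test_efficiency_outside_range_rejected(self, bad):
        with pytest.raises(ValueError):
            QpcrMeasurement(bad, 2.0, 1.0, 1.0)

    @given(e_t=st.floats(1.1, 2.0), dct=st.floats(-5, 5),
           delta=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_multiplicative_in_target_ct_shift(self, e_t, dct, delta):
        base = pfaffl_ratio(QpcrMeasurement(e_t, 2.0, dct, 0.5))
        shifted = pfaffl_ratio(QpcrMeasurement(e_t, 2.0, dct + delta, 0.5))
        assert shifted == pytest.approx(base * e_t ** delta, rel=1e-9)
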