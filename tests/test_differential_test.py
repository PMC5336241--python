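import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spliceshift.differential_test import (ALIGNMENT_COLUMNS, call_differential,
                                           calls_to_table, consistency_filter,
                                           filter_orthologs, find_reciprocal,
                                           genotype_overlap, reads_filter)
from spliceshift.psi_quant import EventCounts


def counts(cond_reps):
    return {
        cond: [EventCounts("ev", f"{cond}_r{i + 1}", inc, exc)
               for i, (inc, exc) in enumerate(reps)]
        for cond, reps in cond_reps.items()
    }


class TestReadsFilter:
    def test_any_replicate_below_threshold_fails(self):
        c = counts({"c1": [(15, 10), (11, 10)], "c2": [(20, 10), (9, 10)]})
        passed, totals = reads_filter(c)
        assert not passed
        assert totals == {"c1": [25, 21], "c2": [30, 19]}

    def test_boundary_is_inclusive(self):
        c = counts({"c1": [(10, 10), (10, 10)], "c2": [(10, 10), (10, 10)]})
        passed, _ = reads_filter(c)
        assert passed

    def test_missing_replicate_counts_as_zero(self, caplog):
        c = counts({"c1": [(50, 50)], "c2": [(50, 50)]})
        c["c2"].append(None)
        passed, totals = reads_filter(c)
        assert not passed
        assert totals["c2"] == [100, 0]

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(200):
            table = rng.integers(0, 40, size=(2, 2, 2))
            c = counts({
                "c1": [tuple(table[0, 0]), tuple(table[0, 1])],
                "c2": [tuple(table[1, 0]), tuple(table[1, 1])],
            })
            passed, _ = reads_filter(c)
            assert passed == bool(table.sum(axis=2).min() >= 20)


class TestConsistencyFilter:
    def test_tight_replicates_wide_conditions_pass(self):
        ok, within, between = consistency_filter(
            {"c1": [0.70, 0.72], "c2": [0.30, 0.33]})
        assert ok
        assert within == pytest.approx(0.03)
        assert between == pytest.approx(0.37)

    def test_noisy_replicates_fail(self):
        ok, within, between = consistency_filter(
            {"c1": [0.50, 0.70], "c2": [0.55, 0.60]})
        assert not ok
        assert within == pytest.approx(0.20)
        assert between == pytest.approx(0.05)

    def test_single_replicates_have_zero_within_spread(self):
        ok, within, between = consistency_filter({"c1": [0.4], "c2": [0.6]})
        assert ok and within == 0.0 and between == pytest.approx(0.2)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(200):
            psi = {c: list(rng.random(int(rng.integers(1, 4))))
                   for c in ("c1", "c2")}
            ok, within, between = consistency_filter(psi)
            wm = max((abs(a - b) for reps in psi.values()
                      for a, b in itertools.combinations(reps, 2)),
                     default=0.0)
            bm = min(abs(a - b) for a in psi["c1"] for b in psi["c2"])
            assert (within, between) == (wm, bm)
            assert ok == (wm < bm)


class TestCallDifferential:
    def test_identical_conditions_not_significant(self):
        c = counts({"c1": [(100, 100), (100, 100)],
                    "c2": [(100, 100), (100, 100)]})
        call = call_differential(c, gene_id="g")
        assert call.delta_psi == pytest.approx(0.0)
        assert not call.significant

    def test_strong_shift_is_significant_with_negative_delta(self):
        c = counts({"c1": [(90, 10), (88, 12)], "c2": [(40, 60), (45, 55)]})
        call = call_differential(c)
        assert call.significant
        assert call.bf >= 5.0
        assert call.delta_psi < 0

    def test_bf_threshold_is_inclusive(self):
        c = counts({"c1": [(90, 10), (88, 12)], "c2": [(40, 60), (45, 55)]})
        bf = call_differential(c).bf
        at_threshold = call_differential(c, bf_threshold=bf)
        assert at_threshold.significant  # BF == threshold still passes
        above = call_differential(c, bf_threshold=bf * (1 + 1e-9))
        assert not above.significant

    def test_significance_monotone_in_threshold(self):
        c = counts({"c1": [(80, 20), (78, 22)], "c2": [(30, 70), (35, 65)]})
        flags = [call_differential(c, bf_threshold=t).significant
                 for t in (1.0, 5.0, 1e6, 1e12)]
        assert flags == sorted(flags, reverse=True)


class TestFindReciprocal:
    @staticmethod
    def calls(rows):
        return pd.DataFrame(
            rows, columns=["event_id", "gene_id", "bf", "delta_psi",
                           "passed_reads_filter", "passed_consistency_filter",
                           "significant"])

    def make(self, event_id, delta, sig=True):
        return {"event_id": event_id, "gene_id": "g_" + event_id, "bf": 10.0,
                "delta_psi": delta, "passed_reads_filter": sig,
                "passed_consistency_filter": sig, "significant": sig}

    def test_disjoint_significant_sets_give_nothing(self):
        a = self.calls([self.make("e1", 0.2)])
        b = self.calls([self.make("e2", -0.2)])
        assert len(find_reciprocal(a, b)) == 0

    def test_opposite_signs_included_same_sign_excluded(self):
        a = self.calls([self.make("e1", 0.2), self.make("e2", 0.3)])
        b = self.calls([self.make("e1", -0.3), self.make("e2", 0.1)])
        out = find_reciprocal(a, b)
        assert list(out["event_id"]) == ["e1"]

    def test_non_significant_events_never_qualify(self):
        a = self.calls([self.make("e1", 0.2, sig=False)])
        b = self.calls([self.make("e1", -0.3)])
        assert len(find_reciprocal(a, b)) == 0

    def test_symmetric_in_arguments(self):
        a = self.calls([self.make("e1", 0.2), self.make("e2", -0.4)])
        b = self.calls([self.make("e1", -0.3), self.make("e2", 0.2)])
        assert set(find_reciprocal(a, b)["event_id"]) == \
            set(find_reciprocal(b, a)["event_id"])


def alignment_row(query, subject, identity, sstart, send, bitscore=100.0,
                  evalue=1e-30):
    return dict(zip(ALIGNMENT_COLUMNS,
                    [query, subject, identity, send - sstart + 1, 0, 0,
                     1, send - sstart + 1, sstart, send, evalue, bitscore]))


class TestFilterOrthologs:
    def test_identity_boundary(self):
        aln = pd.DataFrame([alignment_row("q1", "s1", 39.9, 1, 90)])
        assert filter_orthologs(aln, {"s1": 100}) == {}
        aln = pd.DataFrame([alignment_row("q1", "s1", 40.0, 1, 90)])
        assert "q1" in filter_orthologs(aln, {"s1": 100})

    def test_coverage_boundary(self):
        aln = pd.DataFrame([alignment_row("q1", "s1", 80.0, 1, 74)])
        assert filter_orthologs(aln, {"s1": 100}) == {}
        aln = pd.DataFrame([alignment_row("q1", "s1", 80.0, 1, 75)])
        assert "q1" in filter_orthologs(aln, {"s1": 100})

    def test_zero_subject_length_skipped_with_warning(self):
        aln = pd.DataFrame([alignment_row("q1", "s1", 80.0, 1, 90)])
        with pytest.warns(UserWarning, match="s1"):
            assert filter_orthologs(aln, {"s1": 0}) == {}

    def test_best_hit_by_bitscore_then_evalue_then_id(self):
        aln = pd.DataFrame([
            alignment_row("q1", "sB", 80.0, 1, 90, bitscore=200),
            alignment_row("q1", "sA", 80.0, 1, 90, bitscore=300),
            alignment_row("q1", "sC", 80.0, 1, 90, bitscore=300, evalue=1e-50),
        ])
        lengths = {"sA": 100, "sB": 100, "sC": 100}
        assert filter_orthologs(aln, lengths)["q1"].subject_gene == "sC"

    def test_hundred_record_table_matches_brute_force(self, rng):
        rows, lengths = [], {}
        for k in range(100):
            subject = f"s{k}"
            lengths[subject] = 100
            rows.append(alignment_row(
                f"q{k % 25}", subject,
                identity=float(rng.uniform(20, 90)),
                sstart=1, send=int(rng.integers(50, 101)),
                bitscore=float(rng.uniform(50, 400))))
        aln = pd.DataFrame(rows)
        result = filter_orthologs(aln, lengths)
        surviving = [r for r in rows
                     if r["pct_identity"] >= 40.0
                     and (r["send"] - r["sstart"] + 1) / 100 >= 0.75]
        expected = {}
        for r in surviving:
            cur = expected.get(r["query"])
            if cur is None or r["bitscore"] > cur["bitscore"]:
                expected[r["query"]] = r
        assert set(result) == set(expected)
        for q, pair in result.items():
            assert pair.subject_gene == expected[q]["subject"]


class TestGenotypeOverlap:
    def test_identical_sets(self):
        frac, shared = genotype_overlap({"g1", "g2"}, {"g1", "g2"})
        assert frac == 1.0 and shared == ["g1", "g2"]

    def test_partial_overlap_fraction(self):
        a = {f"g{i}" for i in range(1, 11)}
        b = {"g1"} | {f"g{i}" for i in range(11, 30)}
        frac, shared = genotype_overlap(a, b)
        assert frac == pytest.approx(0.1) and shared == ["g1"]

    def test_empty_first_set_is_undefined(self):
        frac, shared = genotype_overlap(set(), {"g1"})
        assert math.isnan(frac) and shared == []

    def test_with_ortholog_translation_matches_set_arithmetic(self, rng):
        from spliceshift.differential_test import OrthologPair

        genes_a = [f"a{i}" for i in range(30)]
        genes_b = {f"b{i}" for i in rng.choice(50, size=25, replace=False)}
        mapping = {
            g: OrthologPair(g, f"b{int(rng.integers(0, 50))}", 80.0, 0.9)
            for g in genes_a if rng.random() < 0.8
        }
        frac, shared = genotype_overlap(genes_a, genes_b, mapping)
        translated = {mapping[g].subject_gene for g in genes_a if g in mapping}
        assert shared == sorted(translated & genes_b)
        assert frac == len(shared) / len(genes_a)
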