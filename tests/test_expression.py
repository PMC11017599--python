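"""Hotspot-expression association: grouping rules and rank-sum tests."""

import numpy as np
import pandas as pd
import pytest

from breakome.expression import (gene_hotspot_status, hierarchical_bins,
                                 rank_sum_test, representative_transcript,
                                 tissue_expression, with_without_comparison)
from breakome.hotspots import HotspotDefinition, HotspotSet
from breakome.io_core import ExpressionMatrix, TssTable


def tss(rows):
    return TssTable(pd.DataFrame(rows, columns=["gene_id", "transcript_id",
                                                "chrom", "tss_pos", "strand"]))


def expr(genes, cols, tissues):
    tpm = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(tpm=tpm, sample_tissue=tissues)


def hs(positions, tissue="t1"):
    return HotspotSet(HotspotDefinition("sample_shared", 1, 2), tissue,
                      frozenset(positions))


class TestRepresentativeTranscript:
    def _table(self, n_tx=3, n_genes=30):
        rows = []
        for g in range(n_genes):
            for t in range(n_tx):
                rows.append((f"g{g:03d}", f"g{g:03d}.t{t}", "chr1",
                             1000 * g + 10 * t, "+"))
        return tss(rows)

    def test_single_transcript_gene(self):
        t = tss([("gA", "gA.t0", "chr1", 5, "+")])
        out = representative_transcript(t, rng_seed=1)
        assert out.iloc[0].transcript_id == "gA.t0"

    def test_deterministic_under_seed(self):
        t = self._table()
        a = representative_transcript(t, rng_seed=5)
        b = representative_transcript(t, rng_seed=5)
        assert a["transcript_id"].tolist() == b["transcript_id"].tolist()

    def test_choice_frequencies_uniform(self):
        t = self._table(n_tx=3, n_genes=2)
        counts = {0: 0, 1: 0, 2: 0}
        for seed in range(300):
            out = representative_transcript(t, rng_seed=seed)
            counts[int(out.iloc[0].transcript_id[-1])] += 1
        se = np.sqrt(300 * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - 100) <= 3 * se


class TestTissueExpression:
    def test_mean_and_identity(self):
        e = expr(["g1"], {"a": [2.0], "b": [4.0], "c": [7.0]},
                 {"a": "t1", "b": "t1", "c": "t2"})
        assert tissue_expression(e, "t1").loc["g1"] == 3.0
        assert tissue_expression(e, "t2").loc["g1"] == 7.0
        with pytest.raises(ValueError):
            tissue_expression(e, "nope")

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(20)]
        cols = {f"s{j}": rng.random(20) * 10 for j in range(6)}
        e = expr(genes, cols, {f"s{j}": "t1" for j in range(6)})
        got = tissue_expression(e, "t1")
        want = np.mean([cols[f"s{j}"] for j in range(6)], axis=0)
        assert np.allclose(got.values, want)


def test_exact_rank_sum_enumeration():
    assert rank_sum_test([5, 6, 7], [1, 2, 3]) == pytest.approx(0.1)


class TestGeneStatus:
    def test_most_proximal_bin_per_strand(self):
        t = tss([("gA", "a0", "chr1", 1000, "+")])
        # template hotspots (gene +, break -) at |d| = 3 and 80
        status = gene_hotspot_status(hs({("chr1", 1003, "-"), ("chr1", 1080, "-")}), t)
        row = status.iloc[0]
        assert row.bin_template == "5" and row.has_template
        assert row.bin_nontemplate == "none"

    def test_both_strands_same_bin(self):
        t = tss([("gA", "a0", "chr1", 1000, "+")])
        status = gene_hotspot_status(hs({("chr1", 1010, "-"), ("chr1", 1010, "+")}), t)
        row = status.iloc[0]
        assert row.bin_template == "6-20" and row.bin_nontemplate == "6-20"

    def test_any_tss_of_gene_counts(self):
        t = tss([("gA", "a0", "chr1", 1000, "+"), ("gA", "a1", "chr1", 9000, "+")])
        status = gene_hotspot_status(hs({("chr1", 9010, "-")}), t)
        assert status.iloc[0].has_template

    def test_no_hotspots_all_none(self):
        t = tss([("gA", "a0", "chr1", 1000, "+")])
        status = gene_hotspot_status(hs(set()), t)
        assert status.iloc[0].bin_template == "none"
        assert not status.iloc[0].has_template


class TestWithWithout:
    def _setup(self, rng, effect=1.0, n=60):
        genes = [f"g{i:03d}" for i in range(2 * n)]
        t = tss([(g, g + ".t0", "chr1", 2000 * i, "+")
                 for i, g in enumerate(genes)])
        flagged = {("chr1", 2000 * i + 3, "-") for i in range(n)}
        base = rng.lognormal(1.0, 1.0, 2 * n)
        base[:n] *= effect
        e = expr(genes, {"s1": base, "s2": base * rng.lognormal(0, 0.1, 2 * n)},
                 {"s1": "t1", "s2": "t1"})
        status = gene_hotspot_status(hs(flagged), t)
        return status, e

    def test_planted_effect_detected(self):
        status, e = self._setup(np.random.default_rng(42), effect=4.0)
        cmp_ = with_without_comparison(status, e, "t1", "either")
        assert cmp_.p_value < 0.01 and cmp_.median_a > cmp_.median_b

    def test_empty_group_untestable(self):
        status, e = self._setup(np.random.default_rng(43))
        status["has_template"] = False
        status["has_nontemplate"] = False
        cmp_ = with_without_comparison(status, e, "t1", "either")
        assert not cmp_.testable


class TestHierarchicalBins:
    def _status(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "has_template", "bin_template",
                                         "has_nontemplate", "bin_nontemplate"])
        return df

    def test_union_over_tissues_keeps_both_bins(self):
        genes = ["gA"]
        e = expr(genes, {"s1": [10.0], "s2": [20.0]}, {"s1": "t1", "s2": "t2"})
        statuses = {
            "t1": self._status([("gA", True, "5", False, "none")]),
            "t2": self._status([("gA", True, "51-100", False, "none")]),
        }
        members, _ = hierarchical_bins(statuses, e, pooling="union")
        assert set(members["bin"]) == {"5", "51-100"}

    def test_most_proximal_pooling_keeps_one(self):
        genes = ["gA"]
        e = expr(genes, {"s1": [10.0], "s2": [20.0]}, {"s1": "t1", "s2": "t2"})
        statuses = {
            "t1": self._status([("gA", True, "5", False, "none")]),
            "t2": self._status([("gA", True, "51-100", False, "none")]),
        }
        members, _ = hierarchical_bins(statuses, e, pooling="most_proximal")
        assert set(members["bin"]) == {"5"}

    def test_gene_on_both_strands_in_both_groups(self):
        genes = ["gA"]
        e = expr(genes, {"s1": [10.0]}, {"s1": "t1"})
        statuses = {"t1": self._status([("gA", True, "6-20", True, "6-20")])}
        members, _ = hierarchical_bins(statuses, e)
        assert set(members["strand"]) == {"template", "nontemplate"}

    def test_pairwise_tests_emitted(self):
        rng = np.random.default_rng(44)
        genes = [f"g{i:03d}" for i in range(40)]
        e = expr(genes, {"s1": rng.lognormal(1, 1, 40)}, {"s1": "t1"})
        rows = [(g, True, "5" if i < 20 else "151-200", False, "none")
                for i, g in enumerate(genes)]
        statuses = {"t1": self._status(rows)}
        members, tests = hierarchical_bins(statuses, e)
        sub = tests[(tests.bin_a == "5") & (tests.bin_b == "151-200") &
                    (tests.strand == "template")]
        assert len(sub) == 1 and sub.iloc[0].n_a == 20
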