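"""Nearest-TSS assignment, density profiles, R, per-bin odds ratios."""

import numpy as np
import pandas as pd
import pytest

from breakome import intervals as iv
from breakome.io_core import GenomeMask, MappableSpace, TssTable
from breakome.tss_enrichment import (BIN_LABELS, DISTANCE_BINS, TssIndex,
                                     assign_to_tss, bin_odds_ratios, bin_of,
                                     density_profile, enrichment_ratio,
                                     odds_ratio, paired_tissue_test,
                                     region_lengths, template_nontemplate_ratio)
from conftest import empty_mask, full_mask


def tss(rows):
    return TssTable(pd.DataFrame(rows, columns=["gene_id", "transcript_id",
                                                "chrom", "tss_pos", "strand"]))


class TestAssignToTss:
    def test_nearest_and_strand_class(self):
        t = tss([("gA", "a0", "chr1", 1000, "+"), ("gB", "b0", "chr1", 5000, "-")])
        out = assign_to_tss({("chr1", 1050, "+")}, t)
        row = out.iloc[0]
        assert row.tss_pos == 1000 and row.signed_distance == 50
        assert row.strand_class == "nontemplate"

    def test_distance_zero_is_template_for_opposite_strand(self):
        t = tss([("gA", "a0", "chr1", 1000, "+")])
        out = assign_to_tss({("chr1", 1000, "-")}, t)
        assert out.iloc[0].abs_distance == 0
        assert out.iloc[0].strand_class == "template"

    def test_equidistant_tie_goes_to_smaller_coordinate(self):
        t = tss([("gA", "a0", "chr1", 900, "+"), ("gB", "b0", "chr1", 1100, "-")])
        out = assign_to_tss({("chr1", 1000, "+")}, t)
        assert out.iloc[0].tss_pos == 900

    def test_max_distance_cutoff(self):
        t = tss([("gA", "a0", "chr1", 0, "+")])
        out = assign_to_tss({("chr1", 4000, "+"), ("chr1", 6000, "+")}, t,
                            max_distance=5000)
        assert out["pos"].tolist() == [4000]


class TestDensityProfile:
    def test_normalization_identity_when_fully_mappable(self):
        t = tss([("g", "t0", "chr1", 10_000, "+")])
        ms = MappableSpace({"chr1": 20_000}, full_mask({"chr1": 20_000}),
                           empty_mask())
        positions = {("chr1", 10_000 + d, "+") for d in (-4990, -10, 3, 777)}
        prof = density_profile(positions, t, ms)
        assert np.allclose(prof["f"], 1.0)
        for _, row in prof.iterrows():
            N = prof[prof.strand_class == row.strand_class]["n"].sum()
            if row.n:
                assert row.D == pytest.approx(row.n / N)

    def test_normalized_score_arithmetic(self):
        # mappable = first 10 bp of every 20 bp block: f_j = 0.5 exactly
        blocks = [(s, s + 10) for s in range(0, 20_000, 20)]
        ms = MappableSpace({"chr1": 20_000},
                           GenomeMask("non_repeat", {"chr1": iv.as_intervals(blocks)}),
                           empty_mask())
        t = tss([("g", "t0", "chr1", 10_000, "+")])
        positions = {("chr1", 10_000 + 20 * k + 2, "-") for k in range(10)}
        prof = density_profile(positions, t, ms)
        hit = prof[prof.n > 0]
        assert np.allclose(prof["f"], 0.5)
        assert np.allclose(hit["D"], (hit["n"] / 10) / 0.5)


class TestEnrichmentRatio:
    def _scene(self):
        t = tss([("g", "t0", "chr1", 5000, "+")])
        ms = MappableSpace({"chr1": 10_001}, full_mask({"chr1": 10_001}),
                           empty_mask())
        return t, ms

    def test_hand_computed_ratio(self):
        t, ms = self._scene()
        inner = {("chr1", 5000 + d, "+") for d in range(-5, 5)}          # 10 in +/-200
        outer = {("chr1", 5000 + 300 + k, "+") for k in range(90)}       # 90 outside
        er = enrichment_ratio(inner | outer, t, ms)
        assert er["M200"] == 10 and er["M5000"] == 100
        assert er["L200"] == 401 and er["L5000"] == 10_001
        assert er["R"] == pytest.approx((10 / 100) / (401 / 10_001))

    def test_all_positions_inside_200_gives_boundary_ratio(self):
        t, ms = self._scene()
        inner = {("chr1", 5000 + d, "+") for d in range(-100, 100)}
        er = enrichment_ratio(inner, t, ms)
        assert er["R"] == pytest.approx(er["L5000"] / er["L200"])

    def test_uniform_positions_give_ratio_near_one(self):
        t, ms = self._scene()
        rng = np.random.default_rng(12)
        pos = {("chr1", int(p), "+") for p in rng.choice(10_001, 4000, replace=False)}
        er = enrichment_ratio(pos, t, ms)
        se = er["R"] * np.sqrt(1 / er["M200"])
        assert abs(er["R"] - 1) <= 3 * se


class TestOddsRatios:
    def test_formula(self):
        assert odds_ratio(20, 1000, 2000, 10**6) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            odds_ratio(1, 0, 10, 100)
        with pytest.raises(ValueError):
            odds_ratio(1, 10, 0, 100)

    def test_bins_partition_the_200bp_window(self):
        d = np.arange(0, 201)
        b = bin_of(d)
        assert (b >= 0).all()
        for i, (lo, hi) in enumerate(DISTANCE_BINS):
            assert ((b == i) == ((d >= lo) & (d <= hi))).all()
        assert bin_of([201])[0] == -1

    def test_bin_counts_match_brute_force(self):
        rng = np.random.default_rng(13)
        t = tss([(f"g{i}", f"g{i}.t", "chr1", int(p), "+-"[i % 2])
                 for i, p in enumerate(sorted(rng.choice(50_000, 8, replace=False)))])
        ms = MappableSpace({"chr1": 50_000}, full_mask({"chr1": 50_000}),
                           empty_mask())
        positions = {("chr1", int(p), "+-"[rng.integers(2)])
                     for p in rng.choice(50_000, 2000, replace=False)}
        table = bin_odds_ratios(positions, t, ms)
        # brute force: nearest TSS by full scan, smaller coordinate on ties
        tss_rows = list(t.df.itertuples(index=False))
        want = {(cls, lbl): 0 for cls in ("all", "template", "nontemplate")
                for lbl in BIN_LABELS}
        for chrom, pos, strand in positions:
            best = min(tss_rows, key=lambda r: (abs(pos - r.tss_pos), r.tss_pos))
            d = abs(pos - best.tss_pos)
            for i, (lo, hi) in enumerate(DISTANCE_BINS):
                if lo <= d <= hi:
                    cls = "template" if strand != best.strand else "nontemplate"
                    want[("all", BIN_LABELS[i])] += 1
                    want[(cls, BIN_LABELS[i])] += 1
        for _, row in table.iterrows():
            assert row["M"] == want[(row["strand_class"], row["bin"])]
            # OR equals the formula applied to the recounted quantities
            assert row["OR"] == pytest.approx(
                (row["M"] / row["T"]) / (row["L_positions"] / row["LG_positions"]))

    def test_uniform_positions_or_near_one_per_bin(self):
        rng = np.random.default_rng(14)
        t = tss([(f"g{i}", f"g{i}.t", "chr1", 3000 + 7000 * i, "+")
                 for i in range(14)])
        ms = MappableSpace({"chr1": 100_000}, full_mask({"chr1": 100_000}),
                           empty_mask())
        positions = {("chr1", int(p), "+-"[rng.integers(2)])
                     for p in rng.choice(100_000, 60_000, replace=False)}
        table = bin_odds_ratios(positions, t, ms)
        for _, row in table.iterrows():
            se = np.sqrt(1 / max(row.M, 1))
            assert abs(row.OR - 1) <= 3 * se


class TestRatioAndPairedTest:
    def test_template_ratio_values(self):
        assert template_nontemplate_ratio(33, 20) == pytest.approx(1.65)
        assert template_nontemplate_ratio(7, 7) == 1.0
        assert np.isnan(template_nontemplate_ratio(5, 0))

    def test_exact_signed_rank_enumeration(self):
        assert paired_tissue_test((2, 3, 4), (1, 1, 1), "greater") == \
            pytest.approx(0.125)

    def test_identical_vectors_give_p_one(self):
        assert paired_tissue_test((1, 2, 3), (1, 2, 3)) == 1.0

    def test_zero_differences_excluded(self):
        # first pair ties out; effectively n = 2, all positive: p = 1/4
        assert paired_tissue_test((2, 3, 4), (2, 1, 1), "greater") == \
            pytest.approx(0.25)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_tissue_test((1,), (2,))


def test_region_lengths_partition(tiny_ds):
    index = TssIndex(tiny_ds.tss_table)
    lens = region_lengths(index, tiny_ds.mappable)
    assert lens["L_bins"].sum() == lens["L200"]
    assert lens["L200"] <= lens["L5000"] <= lens["LG"]
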