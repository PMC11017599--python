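"""SSB-AP overlap odds ratios, the AP-1 shift, and CG-dinucleotide context."""

import numpy as np
import pytest

from breakome import intervals as iv
from breakome.io_core import GenomeMask
from breakome.overlap_ber import (cg_background, cg_context,
                                  merged_cohort_hotspots, overlap_odds_ratio,
                                  shift_ap_upstream)
from conftest import make_sample

RC = str.maketrans("ACGT", "TGCA")


class TestShift:
    def test_strand_oriented_upstream(self):
        assert shift_ap_upstream({("chr1", 100, "+")}) == {("chr1", 99, "+")}
        assert shift_ap_upstream({("chr1", 100, "-")}) == {("chr1", 101, "-")}

    def test_boundary_dropped(self):
        assert shift_ap_upstream({("chr1", 0, "+")}) == set()
        assert shift_ap_upstream({("chr1", 9, "-")}, {"chr1": 10}) == set()

    def test_bijection_on_interior(self):
        pts = {("c", p, s) for p in range(5, 50) for s in "+-"}
        shifted = shift_ap_upstream(pts)
        # shifting back downstream restores the original set
        back = {(c, p + 1 if s == "+" else p - 1, s) for c, p, s in shifted}
        assert back == pts
        assert len(shifted) == len(pts)


class TestOverlapOddsRatio:
    def test_hand_computed_oor(self):
        ssb = {("c", i, "+") for i in range(100)}
        ap = {("c", i, "+") for i in range(95, 295)}
        res = overlap_odds_ratio(ssb, ap, mode="direct", LG=10**6)
        assert res.O == 5 and res.T == 100 and res.M == 200
        assert res.OOR == pytest.approx(250.0)
        assert res.fisher_p < 1e-6

    def test_disjoint_sets(self):
        ssb = {("c", 1, "+")}
        ap = {("c", 2, "+")}
        res = overlap_odds_ratio(ssb, ap, mode="direct", LG=1000)
        assert res.OOR == 0.0

    def test_strand_matching_flag(self):
        ssb = {("c", 1, "+")}
        ap = {("c", 1, "-")}
        assert overlap_odds_ratio(ssb, ap, "direct", 1000).O == 0
        assert overlap_odds_ratio(ssb, ap, "direct", 1000,
                                  strand_matched=False).O == 1

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_odds_ratio(set(), {("c", 1, "+")}, "direct", 10)

    def test_double_count_needs_flanking_aps(self):
        # one SSB flanked by AP at the same base and AP one base downstream
        ssb = {("c", 10, "+")}
        ap = {("c", 10, "+"), ("c", 11, "+")}
        direct = overlap_odds_ratio(ssb, ap, "direct", 1000)
        shifted = overlap_odds_ratio(ssb, shift_ap_upstream(ap), "ap_minus_1", 1000)
        assert direct.O == 1 and shifted.O == 1


class TestCgContext:
    def test_hand_scanned_contexts(self):
        genome = {"c": "TACGA"}
        assert cg_context({("c", 2, "+")}, genome).n_in_cg == 1    # C|G
        res = cg_context({("c", 1, "+")}, genome)
        assert res.n_in_cg == 1 and res.n_bar_cg == 1              # |CG
        assert cg_context({("c", 3, "+")}, genome).n_in_cg == 0

    def test_minus_strand_uses_reverse_complement(self):
        # revcomp(TACGA) = TCGTA; - strand break at reference pos 3 reads
        # base C (comp of G) with 3' neighbour G (comp of C at pos 2): C|G
        res = cg_context({("c", 3, "-")}, {"c": "TACGA"})
        assert res.n_in_cg == 1 and res.n_c_bar_g == 1

    def test_contig_edge_excluded_from_denominator(self):
        res = cg_context({("c", 4, "+"), ("c", 2, "+")}, {"c": "TACGA"})
        assert res.n_total == 1 and res.n_excluded == 1

    def test_strand_symmetry_under_genome_revcomp(self):
        rng = np.random.default_rng(21)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        L = len(seq)
        positions = {("c", int(p), "+-"[rng.integers(2)])
                     for p in rng.integers(5, L - 5, 150)}
        mirrored = {("c", L - 1 - p, "-" if s == "+" else "+")
                    for _, p, s in positions}
        a = cg_context(positions, {"c": seq})
        b = cg_context(mirrored, {"c": seq.translate(RC)[::-1]})
        assert a.n_in_cg == b.n_in_cg and a.n_total == b.n_total


class TestCgBackground:
    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(22)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        mask = GenomeMask("non_repeat", {"c": iv.as_intervals([(0, 300)])})
        got = cg_background({"c": seq}, mask)
        hits = total = 0
        for p in range(len(seq)):
            for strand in "+-":
                if strand == "+" and p + 2 < len(seq):
                    total += 1
                    hits += (seq[p] == "C" and seq[p + 1] == "G") or \
                        (seq[p + 1] == "C" and seq[p + 2] == "G")
                if strand == "-" and p - 2 >= 0:
                    total += 1
                    hits += (seq[p] == "G" and seq[p - 1] == "C") or \
                        (seq[p - 1] == "G" and seq[p - 2] == "C")
        assert got == pytest.approx(hits / total)

    def test_cgcg_genome_saturates(self):
        mask = GenomeMask("non_repeat", {"c": iv.as_intervals([(0, 4)])})
        assert cg_background({"c": "CGCG"}, mask) == 1.0

    def test_no_cytosine_genome_is_zero(self):
        mask = GenomeMask("non_repeat", {"c": iv.as_intervals([(0, 8)])})
        assert cg_background({"c": "ATGATGAT"}, mask) == 0.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            cg_background({"c": "ACGT"}, GenomeMask("non_repeat", {}))

    def test_planted_cpg_islands_raise_tss_background(self, tiny_ds):
        mask = tiny_ds.mappable.as_mask()
        windows = {c: iv.merge(iv.as_intervals(
            [(max(0, t - 200), t + 201) for t in grp["tss_pos"]]))
            for c, grp in tiny_ds.tss_table.df.groupby("chrom")}
        assert cg_background(tiny_ds.genome, mask, region=windows) > \
            cg_background(tiny_ds.genome, mask)


class TestMergedCohort:
    def test_cross_tissue_sharing_allowed(self):
        s1 = make_sample([("c", 7, "+", 1)], "s1", tissue="liver")
        s2 = make_sample([("c", 7, "+", 1)], "s2", tissue="heart")
        assert merged_cohort_hotspots([s1, s2]).positions == {("c", 7, "+")}

    def test_single_tissue_matches_per_tissue_calling(self):
        from breakome.hotspots import call_sample_shared
        rng = np.random.default_rng(23)
        ss = [make_sample([("c", int(p), "+", 1)
                           for p in rng.choice(100, 40, replace=False)], f"s{i}")
              for i in range(3)]
        assert merged_cohort_hotspots(ss).positions == \
            call_sample_shared(ss).positions

    def test_matches_brute_force(self):
        rng = np.random.default_rng(24)
        ss = [make_sample([("c", int(p), "+-"[rng.integers(2)],
                            int(rng.geometric(0.5)))
                           for p in rng.choice(200, 80, replace=False)],
                          f"s{i}", tissue=f"t{i % 2}") for i in range(4)]
        depth = [{(r.chrom, r.pos, r.strand): r.depth for r in s.records()}
                 for s in ss]
        allpos = set().union(*depth)
        want = {p for p in allpos if sum(1 for d in depth if d.get(p, 0) >= 1) >= 2}
        assert merged_cohort_hotspots(ss).positions == want
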