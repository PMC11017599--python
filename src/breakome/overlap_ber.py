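"""SSB-AP site overlap statistics probing base-excision-repair provenance.

During BER an AP site yields nicks at fixed offsets: the AP
endonuclease (APE1) cut immediately 5' of the site, recovered by
shifting AP coordinates upstream one base ("AP-1"), and the
pre-ligation nick immediately 3' of the site, recovered by direct
coordinate overlap. Overlap strength is the odds ratio
OOR = (O/T) / (M/LG) with O shared positions, T and M the SSB and AP
set sizes and LG the number of mappable strand-specific candidate
positions, plus a companion one-sided Fisher exact test.

CG-dinucleotide context: a break at p (strand-oriented sequence s) is
"C|G" when s[p] = C and s[p+1] = G, and "|CG" when s[p+1] = C and
s[p+2] = G, the bar marking the nick 3' of the base at p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .hotspots import HotspotSet, call_sample_shared
from .io_core import BreakSample, GenomeMask

logger = logging.getLogger(__name__)

__all__ = ["OverlapResult", "CgContextResult", "shift_ap_upstream",
           "overlap_odds_ratio", "cg_context", "cg_background",
           "merged_cohort_hotspots"]

Position = tuple[str, int, str]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class OverlapResult:
    mode: str            # "direct" or "ap_minus_1"
    O: int               # shared positions
    T: int               # SSB set size
    M: int               # AP set size
    LG: int              # candidate strand-specific positions
    OOR: float
    fisher_p: float
    frac_of_ssb: float
    frac_of_ap: float

    def summary(self) -> dict:
        return {"mode": self.mode, "O": self.O, "T": self.T, "M": self.M,
                "LG": self.LG, "OOR": self.OOR, "fisher_p": self.fisher_p,
                "frac_of_ssb": self.frac_of_ssb, "frac_of_ap": self.frac_of_ap}


@dataclass
class CgContextResult:
    n_in_cg: int
    n_total: int         # positions actually tested
    fraction: float
    n_c_bar_g: int       # "C|G": break 3' of the C
    n_bar_cg: int        # "|CG": break immediately 5' of the CG
    n_excluded: int      # too close to a contig end to test
    background_fraction: float | None = None


def shift_ap_upstream(ap_positions: Iterable[Position],
                      chrom_lengths: Mapping[str, int] | None = None) -> set[Position]:
    """Shift AP coordinates one base upstream in strand orientation.

    + strand: pos - 1; - strand: pos + 1. Positions leaving the
    chromosome are dropped with a warning.
    """
    out: set[Position] = set()
    dropped = 0
    for chrom, pos, strand in ap_positions:
        new = pos - 1 if strand == "+" else pos + 1
        if new < 0 or (chrom_lengths is not None and new >= chrom_lengths.get(chrom, np.inf)):
            dropped += 1
            continue
        out.add((chrom, new, strand))
    if dropped:
        logger.warning("shift_ap_upstream dropped %d out-of-bounds positions", dropped)
    return out


def overlap_odds_ratio(ssb_set: Iterable[Position], ap_set: Iterable[Position],
                       mode: str, LG: int,
                       strand_matched: bool = True) -> OverlapResult:
    """OOR = (O/T) / (M/LG) between an SSB and an AP position set.

    ``ap_set`` must already be shifted when ``mode="ap_minus_1"``.
    ``LG`` is the number of candidate positions in the universe the
    sets are drawn from (2 x mappable bases for strand-matched sets,
    1 x for strand-agnostic). Fisher test is one-sided for
    over-representation of AP positions among SSB positions.
    """
    if mode not in ("direct", "ap_minus_1"):
        raise ValueError(f"unknown mode {mode!r}")
    ssb = set(ssb_set)
    ap = set(ap_set)
    if not strand_matched:
        ssb = {(c, p) for c, p, _ in ssb}
        ap = {(c, p) for c, p, _ in ap}
    T, M = len(ssb), len(ap)
    if T == 0 or M == 0:
        raise ValueError("empty SSB or AP set")
    O = len(ssb & ap)
    OOR = (O / T) / (M / LG)
    table = [[O, T - O], [M - O, LG - T - (M - O)]]
    fisher_p = float(stats.fisher_exact(table, alternative="greater")[1])
    return OverlapResult(mode=mode, O=O, T=T, M=M, LG=LG, OOR=OOR,
                         fisher_p=fisher_p, frac_of_ssb=O / T, frac_of_ap=O / M)


def _context_flags(seq: str, pos: int, strand: str):
    """(testable, in_cg, is_c_bar_g) for one strand-oriented position."""
    L = len(seq)
    if strand == "+":
        if pos + 2 >= L:
            return False, False, False
        c_bar_g = seq[pos] == "C" and seq[pos + 1] == "G"
        bar_cg = seq[pos + 1] == "C" and seq[pos + 2] == "G"
    else:
        if pos - 2 < 0:
            return False, False, False
        # strand-oriented base at p is comp(seq[p]); 3' neighbours walk left
        c_bar_g = seq[pos] == "G" and seq[pos - 1] == "C"
        bar_cg = seq[pos - 1] == "G" and seq[pos - 2] == "C"
    return True, c_bar_g or bar_cg, c_bar_g


def cg_context(positions: Iterable[Position],
               genome: Mapping[str, str]) -> CgContextResult:
    """Fraction of strand-specific positions in C|G or |CG context."""
    n_total = n_in = n_cbarg = n_barcg = n_excl = 0
    for chrom, pos, strand in positions:
        seq = genome.get(chrom)
        if seq is None:
            n_excl += 1
            continue
        ok, in_cg, cbarg = _context_flags(seq, pos, strand)
        if not ok:
            n_excl += 1
            continue
        n_total += 1
        if in_cg:
            n_in += 1
            if cbarg:
                n_cbarg += 1
            else:
                n_barcg += 1
    if n_excl:
        logger.info("cg_context excluded %d positions near contig ends", n_excl)
    frac = n_in / n_total if n_total else float("nan")
    return CgContextResult(n_in_cg=n_in, n_total=n_total, fraction=frac,
                           n_c_bar_g=n_cbarg, n_bar_cg=n_barcg, n_excluded=n_excl)


def cg_background(genome: Mapping[str, str], mask: GenomeMask,
                  region: Mapping[str, np.ndarray] | None = None) -> float:
    """Exhaustive fraction of masked strand-positions firing the CG test.

    ``region`` optionally restricts to additional intervals per
    chromosome (e.g. windows around TSSs) intersected with the mask.
    """
    from . import intervals as iv

    n_total = n_in = 0
    for chrom, seq in genome.items():
        ivs = mask.intervals(chrom)
        if region is not None:
            ivs = iv.intersect(ivs, iv.as_intervals(region.get(chrom, [])))
        if len(ivs) == 0:
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        isC = arr == b"C"
        isG = arr == b"G"
        L = len(seq)
        sel = np.zeros(L, dtype=bool)
        for s, e in ivs:
            sel[max(0, s):min(L, e)] = True
        # + strand at p needs p+2 < L
        plus_ok = sel.copy()
        plus_ok[max(0, L - 2):] = False
        p = np.flatnonzero(plus_ok)
        plus_hit = (isC[p] & isG[p + 1]) | (isC[p + 1] & isG[p + 2])
        # - strand at p needs p-2 >= 0
        minus_ok = sel.copy()
        minus_ok[:2] = False
        q = np.flatnonzero(minus_ok)
        minus_hit = (isG[q] & isC[q - 1]) | (isG[q - 1] & isC[q - 2])
        n_total += len(p) + len(q)
        n_in += int(plus_hit.sum()) + int(minus_hit.sum())
    if n_total == 0:
        raise ValueError("empty masked space")
    return n_in / n_total


def merged_cohort_hotspots(all_samples: list[BreakSample], min_depth: int = 1,
                           min_samples: int = 2) -> HotspotSet:
    """Sample-shared calling pooled across all tissues ("merged cohort")."""
    return call_sample_shared(all_samples, min_depth=min_depth,
                              min_samples=min_samples, tissue="merged",
                              require_same_tissue=False)
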