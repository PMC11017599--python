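"""TSS-proximity statistics for breaks and hotspots.

Each position is assigned to its nearest TSS (ties to the smaller
genomic coordinate) and classified template/nontemplate: a break on the
strand opposite the annotated gene strand lies on the template strand.

Statistics:

* aggregate density profile D_j over 500 x 20 bp bins spanning +/-5 kb,
  D_j = (n_j / N) / f_j with f_j the mean mappable fraction of bin j
  over all TSSs;
* enrichment ratio R = (M200/M5000) / (L200/L5000);
* per-distance-bin odds ratios OR = (M_i/T_i) / (L_i/LG) over the six
  bins |d|<=5, 6-20, 21-50, 51-100, 101-150, 151-200 (closed bounds);
* template/nontemplate count ratios and paired per-tissue Wilcoxon
  signed-rank tests.

Lengths for the odds ratios are measured in strand-specific candidate
positions (one per base per strand class; both strands for unstranded
sets), so a uniformly scattered set scores OR = 1 in every bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MappableSpace, TssTable

logger = logging.getLogger(__name__)

__all__ = ["DISTANCE_BINS", "BIN_LABELS", "TssIndex", "assign_to_tss",
           "density_profile", "enrichment_ratio", "odds_ratio",
           "bin_odds_ratios", "template_nontemplate_ratio",
           "paired_tissue_test", "EnrichmentResult", "compute_enrichment",
           "bin_of", "region_lengths"]

# closed-bound |distance| bins partitioning 0..200
DISTANCE_BINS = ((0, 5), (6, 20), (21, 50), (51, 100), (101, 150), (151, 200))
BIN_LABELS = ("5", "6-20", "21-50", "51-100", "101-150", "151-200")

PROFILE_HALFSPAN = 5000
PROFILE_BINWIDTH = 20
PROFILE_NBINS = 2 * PROFILE_HALFSPAN // PROFILE_BINWIDTH  # 500


def bin_of(abs_distance) -> np.ndarray:
    """Distance-bin index (0..5) for |d| <= 200, else -1."""
    d = np.atleast_1d(np.asarray(abs_distance, dtype=np.int64))
    out = np.full(d.shape, -1, dtype=np.int64)
    for i, (lo, hi) in enumerate(DISTANCE_BINS):
        out[(d >= lo) & (d <= hi)] = i
    return out


def positions_frame(positions) -> pd.DataFrame:
    """Normalise a position collection to a (chrom, pos, strand) frame."""
    if isinstance(positions, pd.DataFrame):
        return positions[["chrom", "pos", "strand"]].reset_index(drop=True)
    rows = sorted(positions)
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"]) if rows else \
        pd.DataFrame({"chrom": [], "pos": [], "strand": []})


class TssIndex:
    """Per-chromosome sorted TSS arrays supporting nearest queries.

    Multiple transcripts may share a TSS coordinate; the representative
    row at a coordinate is the first under (tss_pos, gene_id,
    transcript_id) ordering, making tie-breaks deterministic.
    """

    def __init__(self, tss_table: TssTable):
        self.table = tss_table
        self._by_chrom: dict[str, tuple[np.ndarray, pd.DataFrame]] = {}
        df = tss_table.df.sort_values(["chrom", "tss_pos", "gene_id", "transcript_id"])
        for chrom, grp in df.groupby("chrom", sort=False):
            uniq = grp.drop_duplicates("tss_pos")
            self._by_chrom[chrom] = (uniq["tss_pos"].values.astype(np.int64),
                                     uniq.reset_index(drop=True))

    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def nearest(self, chrom: str, pos: np.ndarray):
        """Nearest TSS per position: (row frame, signed genome distance).

        Signed distance = pos - tss_pos. Equidistant ties go to the
        smaller TSS coordinate. Returns (None, None) for a chromosome
        with no TSS.
        """
        if chrom not in self._by_chrom:
            return None, None
        tpos, rows = self._by_chrom[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        right = np.searchsorted(tpos, pos, side="left")
        left = np.clip(right - 1, 0, len(tpos) - 1)
        right = np.clip(right, 0, len(tpos) - 1)
        dl = np.abs(pos - tpos[left])
        dr = np.abs(tpos[right] - pos)
        take_left = dl <= dr  # tie -> smaller coordinate
        idx = np.where(take_left, left, right)
        return rows.iloc[idx].reset_index(drop=True), pos - tpos[idx]

    def nearest_arrays(self, chrom: str, pos: np.ndarray):
        """Vectorised nearest query: (signed distance, gene strand) arrays."""
        if chrom not in self._by_chrom:
            n = len(pos)
            return (np.full(n, np.iinfo(np.int64).max, dtype=np.int64),
                    np.full(n, "+", dtype="<U1"))
        tpos, rows = self._by_chrom[chrom]
        strands = rows["strand"].values.astype("<U1")
        pos = np.asarray(pos, dtype=np.int64)
        right = np.searchsorted(tpos, pos, side="left")
        left = np.clip(right - 1, 0, len(tpos) - 1)
        right = np.clip(right, 0, len(tpos) - 1)
        idx = np.where(np.abs(pos - tpos[left]) <= np.abs(tpos[right] - pos),
                       left, right)
        return pos - tpos[idx], strands[idx]

    def nearest_distance_per_base(self, chrom: str, length: int) -> np.ndarray:
        """|distance to nearest TSS| for every base of a chromosome."""
        d, _ = self.nearest_arrays(chrom, np.arange(length, dtype=np.int64))
        return np.abs(d)


def assign_to_tss(positions, tss_table: TssTable | TssIndex,
                  max_distance: int = 5000) -> pd.DataFrame:
    """Assign positions to their nearest TSS within ``max_distance``.

    Returns a frame with chrom, pos, strand, gene_id, transcript_id,
    tss_pos, gene_strand, signed_distance, abs_distance, strand_class.
    Positions farther than ``max_distance`` from every TSS are dropped.
    """
    index = tss_table if isinstance(tss_table, TssIndex) else TssIndex(tss_table)
    frame = positions_frame(positions)
    parts = []
    for chrom, grp in frame.groupby("chrom", sort=False):
        rows, signed = index.nearest(chrom, grp["pos"].values)
        if rows is None:
            continue
        out = grp.reset_index(drop=True).copy()
        out["gene_id"] = rows["gene_id"].values
        out["transcript_id"] = rows["transcript_id"].values
        out["tss_pos"] = rows["tss_pos"].values
        out["gene_strand"] = rows["strand"].values
        out["signed_distance"] = signed
        out["abs_distance"] = np.abs(signed)
        out["strand_class"] = np.where(out["strand"] != out["gene_strand"],
                                       "template", "nontemplate")
        parts.append(out[out["abs_distance"] <= max_distance])
    if not parts:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "gene_id",
                                     "transcript_id", "tss_pos", "gene_strand",
                                     "signed_distance", "abs_distance", "strand_class"])
    return pd.concat(parts, ignore_index=True)


def mean_bin_mappable_fraction(tss_table: TssTable, mappable: MappableSpace) -> np.ndarray:
    """f_j: mean over TSSs of each 20 bp bin's mappable fraction."""
    offsets = np.arange(-PROFILE_HALFSPAN, PROFILE_HALFSPAN, PROFILE_BINWIDTH)
    sums = np.zeros(PROFILE_NBINS)
    n_tss = 0
    for chrom, grp in tss_table.df.groupby("chrom", sort=False):
        if chrom not in mappable.chrom_lengths:
            continue
        t = grp["tss_pos"].values.astype(np.int64)
        n_tss += len(t)
        for j, off in enumerate(offsets):
            starts = t + off
            counts = mappable.count_in_many(chrom, starts, starts + PROFILE_BINWIDTH)
            sums[j] += counts.sum() / PROFILE_BINWIDTH
    if n_tss == 0:
        raise ValueError("no TSSs on mappable chromosomes")
    return sums / n_tss


def density_profile(positions, tss_table: TssTable, mappable: MappableSpace,
                    assignments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate density profile per strand class over the +/-5 kb span.

    One row per (strand_class, bin): bin_start/bin_end are signed
    distances, n the raw nearest-assigned count, f the mean mappable
    fraction, D = (n/N)/f (NaN where f = 0).
    """
    if assignments is None:
        assignments = assign_to_tss(positions, tss_table, max_distance=PROFILE_HALFSPAN)
    f = mean_bin_mappable_fraction(tss_table, mappable)
    out = []
    for cls, grp in assignments.groupby("strand_class"):
        d = grp["signed_distance"].values
        in_span = (d >= -PROFILE_HALFSPAN) & (d < PROFILE_HALFSPAN)
        j = (d[in_span] + PROFILE_HALFSPAN) // PROFILE_BINWIDTH
        n_j = np.bincount(j.astype(np.int64), minlength=PROFILE_NBINS)
        N = int(n_j.sum())
        if N == 0:
            raise ValueError(f"no assigned positions for strand class {cls}")
        with np.errstate(divide="ignore", invalid="ignore"):
            D = np.where(f > 0, (n_j / N) / f, np.nan)
        for jj in range(PROFILE_NBINS):
            out.append({"strand_class": cls,
                        "bin_start": -PROFILE_HALFSPAN + jj * PROFILE_BINWIDTH,
                        "bin_end": -PROFILE_HALFSPAN + (jj + 1) * PROFILE_BINWIDTH,
                        "n": int(n_j[jj]), "f": f[jj], "D": D[jj]})
    return pd.DataFrame(out)


def region_lengths(tss_index: TssIndex, mappable: MappableSpace) -> dict:
    """Mappable base counts partitioned by distance to the nearest TSS.

    Returns L200, L5000, per-bin L (six closed bins), and LG (all
    mappable bases). Every base is counted once, under its nearest TSS.
    """
    L200 = L5000 = 0
    L_bins = np.zeros(len(DISTANCE_BINS), dtype=np.int64)
    LG = mappable.total_bases
    for chrom, length in mappable.chrom_lengths.items():
        dist = tss_index.nearest_distance_per_base(chrom, length)
        m = mappable.mask(chrom)
        dist = dist[m]
        L200 += int(np.sum(dist <= 200))
        L5000 += int(np.sum(dist <= 5000))
        b = bin_of(dist)
        for i in range(len(DISTANCE_BINS)):
            L_bins[i] += int(np.sum(b == i))
    return {"L200": L200, "L5000": L5000, "L_bins": L_bins, "LG": LG}


def enrichment_ratio(positions, tss_table: TssTable, mappable: MappableSpace,
                     assignments: pd.DataFrame | None = None,
                     lengths: dict | None = None) -> dict:
    """R = (M200/M5000) / (L200/L5000) with unique-position counts.

    M counts unique positions whose nearest TSS lies within the window;
    L counts mappable bases within the window union (each base once).
    """
    index = tss_table if isinstance(tss_table, TssIndex) else TssIndex(tss_table)
    if assignments is None:
        assignments = assign_to_tss(positions, index, max_distance=5000)
    if lengths is None:
        lengths = region_lengths(index, mappable)
    M200 = int((assignments["abs_distance"] <= 200).sum())
    M5000 = int((assignments["abs_distance"] <= 5000).sum())
    L200, L5000 = lengths["L200"], lengths["L5000"]
    if M5000 == 0:
        raise ValueError("no positions within +/-5000 of any TSS")
    if L200 == 0:
        raise ValueError("no mappable bases within +/-200 of any TSS")
    R = (M200 / M5000) / (L200 / L5000)
    return {"M200": M200, "M5000": M5000, "L200": L200, "L5000": L5000, "R": R}


def odds_ratio(M: float, T: float, L: float, LG: float) -> float:
    """OR = (M/T) / (L/LG); raises on T = 0 or L = 0."""
    if T == 0:
        raise ValueError("T is zero")
    if L == 0:
        raise ValueError("L is zero")
    return (M / T) / (L / LG)


def bin_odds_ratios(positions, tss_table: TssTable, mappable: MappableSpace,
                    assignments: pd.DataFrame | None = None,
                    lengths: dict | None = None) -> pd.DataFrame:
    """Per-(strand_class, distance bin) odds ratios for a position set.

    T is the total set size genome-wide. L and LG are in candidate
    strand-positions: per strand class one candidate per base (each base
    has exactly one template and one nontemplate strand w.r.t. its
    nearest gene), LG = 2 x mappable bases; for the unstranded "all"
    class both strands are candidates, so the formula reduces to base
    pair lengths as printed.
    """
    index = tss_table if isinstance(tss_table, TssIndex) else TssIndex(tss_table)
    frame = positions_frame(positions)
    T = len(frame)
    if assignments is None:
        assignments = assign_to_tss(frame, index, max_distance=5000)
    if lengths is None:
        lengths = region_lengths(index, mappable)
    L_bins, LG = lengths["L_bins"], lengths["LG"]
    near = assignments[assignments["abs_distance"] <= 200].copy()
    near["bin"] = bin_of(near["abs_distance"].values)
    out = []
    for cls in ("all", "template", "nontemplate"):
        sub = near if cls == "all" else near[near["strand_class"] == cls]
        n_cand_total = 2 * LG  # strand-specific candidate positions genome-wide
        for i, label in enumerate(BIN_LABELS):
            M = int((sub["bin"] == i).sum())
            L_cand = 2 * L_bins[i] if cls == "all" else int(L_bins[i])
            OR = odds_ratio(M, T, L_cand, n_cand_total)
            out.append({"strand_class": cls, "bin": label, "M": M, "T": T,
                        "L_positions": L_cand, "LG_positions": n_cand_total,
                        "OR": OR})
    return pd.DataFrame(out)


def template_nontemplate_ratio(n_template: int, n_nontemplate: int) -> float:
    if n_nontemplate == 0:
        logger.warning("nontemplate count is zero; template ratio undefined")
        return float("nan")
    return n_template / n_nontemplate


def paired_tissue_test(values_a, values_b, direction: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value for paired per-tissue values.

    ``direction="greater"`` tests a > b. Zero differences are excluded
    (the standard signed-rank convention); the exact distribution is
    used whenever scipy can (no ties, small n).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(a == b):
        return 1.0
    res = stats.wilcoxon(a, b, alternative=direction, zero_method="wilcox")
    return float(res.pvalue)


@dataclass
class EnrichmentResult:
    """All TSS-proximity statistics for one position set."""

    M200: int
    M5000: int
    L200: int
    L5000: int
    R: float
    bin_table: pd.DataFrame          # per (strand_class, bin) OR records
    tn_ratios: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        return {"M200": self.M200, "M5000": self.M5000, "L200": self.L200,
                "L5000": self.L5000, "R": self.R}


def compute_enrichment(positions, tss_table: TssTable, mappable: MappableSpace,
                       lengths: dict | None = None) -> EnrichmentResult:
    """One-stop R, per-bin ORs and template/nontemplate ratios."""
    index = TssIndex(tss_table)
    if lengths is None:
        lengths = region_lengths(index, mappable)
    assignments = assign_to_tss(positions, index, max_distance=5000)
    er = enrichment_ratio(positions, index, mappable, assignments=assignments,
                          lengths=lengths)
    bins = bin_odds_ratios(positions, index.table, mappable,
                           assignments=assignments, lengths=lengths)
    tn = []
    near = assignments[assignments["abs_distance"] <= 200].copy()
    near["bin"] = bin_of(near["abs_distance"].values)
    for i, label in enumerate(BIN_LABELS):
        nt = int(((near["bin"] == i) & (near["strand_class"] == "template")).sum())
        nn = int(((near["bin"] == i) & (near["strand_class"] == "nontemplate")).sum())
        tn.append({"bin": label, "n_template": nt, "n_nontemplate": nn,
                   "ratio": template_nontemplate_ratio(nt, nn) if nn else float("nan")})
    return EnrichmentResult(M200=er["M200"], M5000=er["M5000"], L200=er["L200"],
                            L5000=er["L5000"], R=er["R"], bin_table=bins,
                            tn_ratios=pd.DataFrame(tn))
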