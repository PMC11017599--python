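"""Positional base composition around break positions and TSSs.

Windows are strand-oriented ``2*flank + 1``-mers centred on the break
base (the 3'-OH base), so column ``flank`` is the base immediately
upstream of the nick and column ``flank + 1`` the first base
downstream. Minus-strand windows are reverse-complemented so index 0 is
always the 5'-most base in strand orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["BaseFractionMatrix", "extract_windows", "base_fractions",
           "difference_profile", "upstream_c_enrichment"]

BASES = ("A", "C", "G", "T")
_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass
class BaseFractionMatrix:
    """Per-column base fractions over equal-length strand-oriented windows."""

    fractions: pd.DataFrame   # index: BASES, columns: -flank..+flank offsets
    n_sequences: int

    @property
    def flank(self) -> int:
        return (len(self.fractions.columns) - 1) // 2

    def column(self, offset: int) -> pd.Series:
        return self.fractions[offset]


def extract_windows(positions, genome: Mapping[str, str],
                    flank: int = 5) -> list[str]:
    """Strand-oriented windows of ``2*flank + 1`` bases centred on each position.

    Windows truncated by contig ends are excluded with a logged count.
    """
    out = []
    n_excl = 0
    for chrom, pos, strand in positions:
        seq = genome.get(chrom)
        if seq is None or pos - flank < 0 or pos + flank + 1 > len(seq):
            n_excl += 1
            continue
        w = seq[pos - flank:pos + flank + 1]
        out.append(_revcomp(w) if strand == "-" else w)
    if n_excl:
        logger.info("extract_windows excluded %d truncated windows", n_excl)
    return out


def base_fractions(windows: Iterable[str]) -> BaseFractionMatrix:
    """Per-column base fractions; Ns are excluded from that column's denominator."""
    windows = list(windows)
    if not windows:
        raise ValueError("empty window list")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must have equal length")
    flank = (width - 1) // 2
    arr = np.frombuffer("".join(windows).encode(), dtype="S1").reshape(len(windows), width)
    offsets = list(range(-flank, width - flank))
    mat = np.zeros((4, width))
    for bi, base in enumerate(BASES):
        mat[bi] = (arr == base.encode()).sum(axis=0)
    denom = mat.sum(axis=0)  # counted (non-N) bases per column
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, mat / denom, 0.0)
    df = pd.DataFrame(frac, index=list(BASES), columns=offsets)
    return BaseFractionMatrix(fractions=df, n_sequences=len(windows))


def difference_profile(matrix_a: BaseFractionMatrix, matrix_b: BaseFractionMatrix,
                       threshold: float = 0.05) -> pd.DataFrame:
    """Signed base-fraction differences a - b exceeding the display threshold.

    Only cells with ``|a - b| > threshold`` (strict) are returned, one
    row per (offset, base) with the signed difference.
    """
    if matrix_a.fractions.shape != matrix_b.fractions.shape or \
            list(matrix_a.fractions.columns) != list(matrix_b.fractions.columns):
        raise ValueError("matrices must share shape and offsets")
    diff = matrix_a.fractions - matrix_b.fractions
    rows = []
    # strict inequality, robust to float round-off so a difference of
    # exactly the threshold is suppressed
    eps = 1e-9
    for off in diff.columns:
        for base in BASES:
            d = float(diff.loc[base, off])
            if abs(d) > threshold + eps:
                rows.append({"offset": off, "base": base, "difference": d})
    return pd.DataFrame(rows, columns=["offset", "base", "difference"])


def upstream_c_enrichment(hotspot_windows: Iterable[str],
                          background_windows: Iterable[str]) -> dict:
    """Cytosine excess at the base immediately upstream of the nick.

    Compares the C fraction at the centre column (offset 0, the 3'-OH
    base) between hotspot and background windows with a Fisher exact
    two-proportion test.
    """
    a = base_fractions(hotspot_windows)
    b = base_fractions(background_windows)
    ca = float(a.column(0)["C"])
    cb = float(b.column(0)["C"])
    na, nb = a.n_sequences, b.n_sequences
    ka, kb = round(ca * na), round(cb * nb)
    p = float(stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])[1])
    return {"c_fraction_hotspots": ca, "c_fraction_background": cb,
            "difference": ca - cb, "n_hotspots": na, "n_background": nb,
            "p_value": p}
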