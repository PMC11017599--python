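"""Uniform-placement null model for hotspot occurrence.

For each iteration the observed number of break positions per sample is
re-drawn uniformly (without replacement within a sample) over mappable
positions x strands, hotspots are re-called with the identical
definition, and the hotspot fraction recorded. The real fraction is
compared to the simulated vector with a two-sided one-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hotspots import HotspotDefinition, hotspot_fraction, call_hotspots, pooled_positions
from .io_core import BreakSample, MappableSpace

logger = logging.getLogger(__name__)

__all__ = ["NullResult", "simulate_breaks", "run_null"]


@dataclass
class NullResult:
    n_iterations: int
    simulated_fractions: np.ndarray
    real_fraction: float
    ratio: float            # real / mean(simulated)
    p_value: float          # two-sided one-sample t-test
    degenerate: bool = False

    def summary(self) -> dict:
        return {"real_fraction": self.real_fraction,
                "mean_simulated_fraction": float(np.mean(self.simulated_fractions)),
                "ratio": self.ratio, "p_value": self.p_value,
                "n_iterations": self.n_iterations, "degenerate": self.degenerate}


class _FlatSpace:
    """Flat enumeration of (mappable position, strand) pairs for sampling."""

    def __init__(self, mappable: MappableSpace):
        self.chroms = mappable.chroms
        self.pos_arrays = [mappable.mappable_positions(c) for c in self.chroms]
        sizes = np.array([len(a) for a in self.pos_arrays], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(sizes)))
        self.n_positions = int(self.offsets[-1])
        self.capacity = 2 * self.n_positions

    def decode(self, flat: np.ndarray):
        """flat index -> (chrom_idx array, pos array, strand_idx array)."""
        strand_idx = flat & 1
        pidx = flat >> 1
        cidx = np.searchsorted(self.offsets, pidx, side="right") - 1
        pos = np.empty(len(flat), dtype=np.int64)
        for i in range(len(self.chroms)):
            sel = cidx == i
            if sel.any():
                pos[sel] = self.pos_arrays[i][pidx[sel] - self.offsets[i]]
        return cidx, pos, strand_idx


def _draw_distinct(n: int, capacity: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct uniform integers in [0, capacity) (unordered)."""
    if n > capacity:
        raise ValueError(f"cannot draw {n} distinct from capacity {capacity}")
    if n * 3 > capacity:
        return rng.choice(capacity, size=n, replace=False)
    # collision-resolved oversampling: cheap when n << capacity
    got = np.empty(0, dtype=np.int64)
    while len(got) < n:
        need = n - len(got)
        cand = rng.integers(0, capacity, size=int(need * 1.2) + 16)
        got = np.unique(np.concatenate([got, cand]))
    # subsample back to exactly n uniformly
    return got[rng.choice(len(got), size=n, replace=False)] if len(got) > n else got


def simulate_breaks(n: int, mappable: MappableSpace,
                    rng: np.random.Generator) -> set[tuple[str, int, str]]:
    """n distinct (chrom, pos, strand) triples uniform over mappable space."""
    space = _FlatSpace(mappable)
    if n > space.capacity:
        raise ValueError(f"n={n} exceeds capacity {space.capacity}")
    flat = _draw_distinct(n, space.capacity, rng)
    cidx, pos, sidx = space.decode(flat)
    strands = np.array(["+", "-"])
    return set(zip((space.chroms[i] for i in cidx), pos.tolist(), strands[sidx]))


def run_null(samples: list[BreakSample], definition: HotspotDefinition,
             mappable: MappableSpace, n_iter: int = 100, rng_seed: int = 0,
             depth_mode: str = "empirical") -> NullResult:
    """Randomized-placement null for the hotspot fraction of one tissue.

    ``depth_mode``: "empirical" resamples each simulated position's depth
    from that sample's observed depth distribution; "min_depth" assigns
    the definition's threshold depth to every simulated position.
    """
    if depth_mode not in ("empirical", "min_depth"):
        raise ValueError(f"unknown depth_mode {depth_mode!r}")
    real_hs = call_hotspots(samples, definition)
    real_fraction = hotspot_fraction(real_hs, pooled_positions(samples))

    space = _FlatSpace(mappable)
    rng = np.random.default_rng(rng_seed)
    sizes = [len(s) for s in samples]
    depth_pools = [s.df["depth"].values for s in samples]

    fracs = np.empty(n_iter)
    for it in range(n_iter):
        per_sample_kept = []
        universe_parts = []
        for m, dp in zip(sizes, depth_pools):
            flat = _draw_distinct(m, space.capacity, rng)
            if depth_mode == "empirical":
                depth = rng.choice(dp, size=m, replace=True)
            else:
                depth = np.full(m, definition.min_depth, dtype=np.int64)
            universe_parts.append(flat)
            per_sample_kept.append(flat[depth >= definition.min_depth])
        universe_n = len(np.unique(np.concatenate(universe_parts)))
        if definition.mode == "sample_level":
            n_hot = len(np.unique(np.concatenate(per_sample_kept))) \
                if per_sample_kept else 0
        else:
            pooled = np.concatenate(per_sample_kept)
            _, counts = np.unique(pooled, return_counts=True)
            n_hot = int(np.sum(counts >= definition.min_samples))
        fracs[it] = n_hot / universe_n

    mean_sim = float(np.mean(fracs))
    ratio = real_fraction / mean_sim if mean_sim > 0 else float("inf")
    degenerate = bool(np.std(fracs) == 0)
    if degenerate:
        logger.warning("simulated fractions have zero variance; t-test degenerate")
        p = float("nan") if not np.allclose(fracs, real_fraction) else 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.ttest_1samp(fracs, popmean=real_fraction).pvalue)
    return NullResult(n_iterations=n_iter, simulated_fractions=fracs,
                      real_fraction=real_fraction, ratio=ratio, p_value=p,
                      degenerate=degenerate)
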