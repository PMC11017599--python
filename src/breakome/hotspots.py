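"""Single-nucleotide break hotspot calling at three stringencies.

Hotspots are strand-specific ``(chrom, pos, strand)`` triples called per
tissue from deduplicated, mappability-filtered break samples:

* sample-level: within-sample read depth >= 2 (union over samples);
* sample-shared, depth >= 1: position seen in >= 2 samples of a tissue;
* sample-shared, depth >= 2: depth >= 2 in each of >= 2 samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_core import BreakSample

__all__ = ["HotspotDefinition", "HotspotSet", "call_sample_level",
           "call_sample_shared", "call_hotspots", "hotspot_fraction",
           "pooled_positions"]

Position = tuple[str, int, str]


@dataclass(frozen=True)
class HotspotDefinition:
    mode: str  # "sample_level" or "sample_shared"
    min_depth: int = 1
    min_samples: int = 1

    def __post_init__(self):
        if self.mode not in ("sample_level", "sample_shared"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "sample_level" and self.min_depth < 2:
            raise ValueError("sample_level requires min_depth >= 2")
        if self.mode == "sample_shared" and self.min_samples < 2:
            raise ValueError("sample_shared requires min_samples >= 2")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    @property
    def label(self) -> str:
        if self.mode == "sample_level":
            return f"sample_level_d{self.min_depth}"
        return f"sample_shared_d{self.min_depth}_s{self.min_samples}"


@dataclass
class HotspotSet:
    definition: HotspotDefinition
    tissue: str
    positions: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.positions)


def _check_samples(samples: list[BreakSample]) -> None:
    if not samples:
        raise ValueError("empty sample list")
    tissues = {s.tissue for s in samples}
    if len(tissues) > 1:
        raise ValueError(f"samples span multiple tissues: {sorted(tissues)}")


def call_sample_level(samples: list[BreakSample], min_depth: int = 2) -> HotspotSet:
    """Union over samples of positions with within-sample depth >= min_depth."""
    _check_samples(samples)
    definition = HotspotDefinition("sample_level", min_depth=min_depth)
    hits: set[Position] = set()
    for s in samples:
        sub = s.df[s.df["depth"] >= min_depth]
        hits.update(zip(sub["chrom"], sub["pos"].astype(int), sub["strand"]))
    return HotspotSet(definition, samples[0].tissue, frozenset(hits))


def call_sample_shared(samples: list[BreakSample], min_depth: int = 1,
                       min_samples: int = 2, tissue: str | None = None,
                       require_same_tissue: bool = True) -> HotspotSet:
    """Positions meeting the depth threshold in >= min_samples distinct samples."""
    if not samples:
        raise ValueError("empty sample list")
    if require_same_tissue:
        _check_samples(samples)
    if min_samples > len(samples):
        raise ValueError(f"min_samples={min_samples} exceeds {len(samples)} samples")
    definition = HotspotDefinition("sample_shared", min_depth=min_depth,
                                   min_samples=min_samples)
    counts: Counter = Counter()
    for s in samples:
        sub = s.df[s.df["depth"] >= min_depth]
        counts.update(zip(sub["chrom"], sub["pos"].astype(int), sub["strand"]))
    hits = frozenset(p for p, c in counts.items() if c >= min_samples)
    return HotspotSet(definition, tissue or samples[0].tissue, hits)


def call_hotspots(samples: list[BreakSample], definition: HotspotDefinition) -> HotspotSet:
    if definition.mode == "sample_level":
        return call_sample_level(samples, min_depth=definition.min_depth)
    return call_sample_shared(samples, min_depth=definition.min_depth,
                              min_samples=definition.min_samples)


def pooled_positions(samples: list[BreakSample]) -> set[Position]:
    """Distinct (chrom, pos, strand) break positions pooled over samples."""
    universe: set[Position] = set()
    for s in samples:
        universe.update(zip(s.df["chrom"], s.df["pos"].astype(int), s.df["strand"]))
    return universe


def hotspot_fraction(hotspots: HotspotSet, breaks_universe: set[Position]) -> float:
    """|hotspots| / |distinct pooled break positions of the tissue|."""
    if not breaks_universe:
        raise ValueError("empty break universe")
    return len(hotspots.positions) / len(breaks_universe)
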