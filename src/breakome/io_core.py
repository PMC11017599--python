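"""Core domain types and file formats for strand-specific breakome data.

Coordinates are 0-based half-open internally and BED on disk. A break
record marks the base whose 3'-side carries the nick, in strand
orientation: for a ``+`` strand break at ``pos`` the nick lies between
``pos`` and ``pos + 1`` of the reference; for a ``-`` strand break it
lies between ``pos - 1`` and ``pos`` (the strand-oriented 3' neighbour
of ``pos`` is reference ``pos - 1``).

File dialects
-------------
* Break files: BED6, one line per position, score column = read depth.
* Masks: BED3.
* TSS table: TSV with header ``gene_id transcript_id chrom tss_pos strand``.
* Expression: TSV, genes x samples, first column ``gene_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from . import intervals as iv

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class BreakRecord(NamedTuple):
    chrom: str
    pos: int
    strand: str
    depth: int


@dataclass
class BreakSample:
    """One biological sample's deduplicated break positions.

    Positions are held columnar for vectorised work; ``records()``
    yields :class:`BreakRecord` views.
    """

    sample_id: str
    tissue: str
    df: pd.DataFrame  # columns: chrom, pos, strand, depth

    def __post_init__(self):
        if not self.tissue:
            raise ValueError("tissue label must be non-empty")
        required = ["chrom", "pos", "strand", "depth"]
        if list(self.df.columns) != required:
            self.df = self.df[required]
        if len(self.df) and self.df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError(f"duplicate position in sample {self.sample_id}")
        if len(self.df) and (self.df["depth"] < 1).any():
            raise ValueError("depth must be >= 1")

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterable[BreakRecord]:
        for row in self.df.itertuples(index=False):
            yield BreakRecord(row.chrom, int(row.pos), row.strand, int(row.depth))

    def positions(self) -> set[tuple[str, int, str]]:
        return set(zip(self.df["chrom"], self.df["pos"].astype(int), self.df["strand"]))


@dataclass
class GenomeMask:
    """Sorted, disjoint half-open intervals per chromosome with a role tag."""

    role: str  # e.g. "non_repeat" or "polyA_excluded"
    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.by_chrom = {c: iv.merge(a) for c, a in self.by_chrom.items()}

    def total_length(self) -> int:
        return sum(iv.total_length(a) for a in self.by_chrom.values())

    def intervals(self, chrom: str) -> np.ndarray:
        return self.by_chrom.get(chrom, np.zeros((0, 2), dtype=np.int64))

    def contains(self, chrom: str, pos) -> np.ndarray:
        return iv.contains(self.intervals(chrom), np.atleast_1d(pos))

    @classmethod
    def from_bed(cls, path, role: str) -> "GenomeMask":
        by_chrom: dict[str, list] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: expected >=3 BED fields")
                by_chrom.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls(role=role, by_chrom={c: iv.as_intervals(v) for c, v in by_chrom.items()})

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.by_chrom):
                for s, e in self.by_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass
class TssTable:
    """Transcript start sites with gene strand; one row per transcript."""

    df: pd.DataFrame  # columns: gene_id, transcript_id, chrom, tss_pos, strand

    COLS = ["gene_id", "transcript_id", "chrom", "tss_pos", "strand"]

    def __post_init__(self):
        self.df = self.df[self.COLS].copy()
        self.df["tss_pos"] = self.df["tss_pos"].astype(np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path) -> "TssTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def genes(self) -> list[str]:
        return sorted(self.df["gene_id"].unique())


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with a sample -> tissue map."""

    tpm: pd.DataFrame  # index: gene_id, columns: sample ids
    sample_tissue: dict[str, str]

    def __post_init__(self):
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be >= 0")
        missing = set(self.tpm.columns) - set(self.sample_tissue)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path, sample_tissue: Mapping[str, str]) -> "ExpressionMatrix":
        tpm = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(tpm=tpm, sample_tissue=dict(sample_tissue))

    def to_tsv(self, path) -> None:
        self.tpm.to_csv(path, sep="\t", index_label="gene_id")

    def tissue_samples(self, tissue: str) -> list[str]:
        return [s for s, t in self.sample_tissue.items() if t == tissue]


# ---------------------------------------------------------------------------
# Break file IO
# ---------------------------------------------------------------------------

def read_breaks(path, genome_bounds: Mapping[str, int] | None = None,
                sample_id: str | None = None, tissue: str = "unknown") -> BreakSample:
    """Read a BED6 break file into a :class:`BreakSample`.

    ``genome_bounds`` maps chrom -> length; out-of-bounds records are
    rejected with a logged count. Duplicate (chrom, pos, strand) lines
    are an error, as is any line whose end != start + 1.
    """
    chroms, poss, strands, depths = [], [], [], []
    n_oob = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED fields, got {len(parts)}")
            chrom, start, end, _name, score, strand = parts[:6]
            try:
                start, end, depth = int(start), int(end), int(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed numeric field") from exc
            if end != start + 1:
                raise ValueError(f"{path}:{ln}: single-nucleotide record requires end == start+1")
            if strand not in STRANDS:
                raise ValueError(f"{path}:{ln}: strand must be + or -")
            if genome_bounds is not None:
                L = genome_bounds.get(chrom)
                if L is None or not (0 <= start < L):
                    n_oob += 1
                    continue
            chroms.append(chrom)
            poss.append(start)
            strands.append(strand)
            depths.append(depth)
    if n_oob:
        logger.info("%s: rejected %d out-of-bounds records", path, n_oob)
    df = pd.DataFrame({"chrom": chroms,
                       "pos": np.array(poss, dtype=np.int64),
                       "strand": strands,
                       "depth": np.array(depths, dtype=np.int64)})
    if df.duplicated(["chrom", "pos", "strand"]).any():
        dup = df[df.duplicated(["chrom", "pos", "strand"])].iloc[0]
        raise ValueError(f"{path}: duplicate position {dup.chrom}:{dup.pos}:{dup.strand}")
    return BreakSample(sample_id=sample_id or Path(path).stem, tissue=tissue, df=df)


def write_breaks(sample: BreakSample, path) -> None:
    with open(path, "w") as fh:
        for r in sample.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t.\t{r.depth}\t{r.strand}\n")


def mask_filter(sample: BreakSample, mask: GenomeMask) -> BreakSample:
    """Keep only records whose position lies inside the mask; order preserved."""
    if len(sample.df) == 0:
        return sample
    keep = np.zeros(len(sample.df), dtype=bool)
    for chrom, grp in sample.df.groupby("chrom", sort=False):
        keep[grp.index.values] = iv.contains(mask.intervals(chrom), grp["pos"].values)
    return BreakSample(sample_id=sample.sample_id, tissue=sample.tissue,
                       df=sample.df[keep].reset_index(drop=True))


def effective_length(non_repeat: GenomeMask, polya_excluded: GenomeMask,
                     windows: Mapping[str, np.ndarray]) -> int:
    """Exact bp of ``windows`` inside the non-repeat mask minus polyA exclusions.

    ``windows`` maps chrom -> (N, 2) half-open intervals (need not be
    disjoint; overlap is never double-counted).
    """
    total = 0
    for chrom, w in windows.items():
        w = iv.merge(iv.as_intervals(w))
        kept = iv.subtract(iv.intersect(w, non_repeat.intervals(chrom)),
                           polya_excluded.intervals(chrom))
        total += iv.total_length(kept)
    return total


# ---------------------------------------------------------------------------
# Mappable space: non-repeat minus polyA-excluded, with O(1) range counts
# ---------------------------------------------------------------------------

class MappableSpace:
    """Boolean mappability per chromosome with prefix sums for fast queries.

    Combines the non-repeat mask and the polyA exclusion mask into the
    space over which breaks can be observed; supplies position counts
    in arbitrary windows and a flat enumeration of mappable positions
    used by the uniform null and the synthetic generator.
    """

    def __init__(self, chrom_lengths: Mapping[str, int],
                 non_repeat: GenomeMask, polya_excluded: GenomeMask | None = None):
        self.chrom_lengths = dict(chrom_lengths)
        self.chroms = sorted(self.chrom_lengths)
        self._mask: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, L in self.chrom_lengths.items():
            m = np.zeros(L, dtype=bool)
            for s, e in non_repeat.intervals(chrom):
                m[max(0, s):min(L, e)] = True
            if polya_excluded is not None:
                for s, e in polya_excluded.intervals(chrom):
                    m[max(0, s):min(L, e)] = False
            self._mask[chrom] = m
            self._cum[chrom] = np.concatenate(([0], np.cumsum(m, dtype=np.int64)))

    @property
    def total_bases(self) -> int:
        return int(sum(c[-1] for c in self._cum.values()))

    def mask(self, chrom: str) -> np.ndarray:
        return self._mask[chrom]

    def is_mappable(self, chrom: str, pos) -> np.ndarray:
        return self._mask[chrom][np.atleast_1d(pos)]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Mappable bases in [start, end), clipped to the chromosome."""
        L = self.chrom_lengths[chrom]
        s, e = max(0, start), min(L, end)
        if s >= e:
            return 0
        return int(self._cum[chrom][e] - self._cum[chrom][s])

    def count_in_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        L = self.chrom_lengths[chrom]
        s = np.clip(starts, 0, L)
        e = np.clip(ends, 0, L)
        e = np.maximum(s, e)
        return self._cum[chrom][e] - self._cum[chrom][s]

    def mappable_positions(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self._mask[chrom])

    def as_mask(self, role: str = "mappable") -> GenomeMask:
        by_chrom = {}
        for chrom, m in self._mask.items():
            padded = np.concatenate(([False], m, [False]))
            d = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            by_chrom[chrom] = np.column_stack([starts, ends])
        return GenomeMask(role=role, by_chrom=by_chrom)


# ---------------------------------------------------------------------------
# Genome FASTA and the polyA-adjacency exclusion rule
# ---------------------------------------------------------------------------

def load_genome(path) -> dict[str, str]:
    """Load a FASTA into upper-case in-memory strings (small genomes)."""
    from pyfaidx import Fasta

    if not Path(path).exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def polya_exclusion_mask(seqs: Mapping[str, str], min_run: int = 8,
                         footprint: int = 1) -> GenomeMask:
    """Positions adjacent (3', strand-oriented) to endogenous polyA stretches.

    Break capture anchors on the 3'-OH side, so a run of >= ``min_run``
    adenines blinds the ``footprint`` bases immediately downstream of
    the run on the + strand; a thymine run (a polyA tract on the -
    strand) blinds the bases immediately upstream in reference
    coordinates. Emitted as an unstranded mask.
    """
    by_chrom: dict[str, list] = {}
    for chrom, seq in seqs.items():
        out = []
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for base, downstream in ((b"A", True), (b"T", False)):
            hits = arr == base
            padded = np.concatenate(([False], hits, [False]))
            d = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            runs = ends - starts >= min_run
            for s, e in zip(starts[runs], ends[runs]):
                if downstream:
                    out.append((e, min(len(seq), e + footprint)))
                else:
                    out.append((max(0, s - footprint), s))
        by_chrom[chrom] = iv.as_intervals(out) if out else np.zeros((0, 2), dtype=np.int64)
    return GenomeMask(role="polyA_excluded", by_chrom=by_chrom)
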