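"""Synthetic breakome generator with known planted structure.

Emits everything the pipeline consumes — genome FASTA, non-repeat and
polyA-exclusion masks, a TSS table, per-sample strand-specific SSB and
AP-site break files, and a TPM expression matrix — from a single seeded
configuration, together with the planted truth (hot-position pool,
per-gene hotspot flags and bins, AP-SSB couplings) against which
recovery is measured.

Break model
-----------
``breaks_per_sample`` counts read events. Each event is, with
probability ``hot_fraction``, a uniform draw (with replacement) from a
shared hot-position pool, and otherwise a draw from a per-position
weight field over mappable (position, strand) pairs: uniform background
times, within +/-200 bp of the nearest TSS, the enrichment factor ``e``
and a per-bin profile peaking at +/-5 bp, a template-strand odds factor
``beta``, and an upstream-cytosine preference. A position's read depth
is its event multiplicity plus a Geometric(p) - 1 overdispersion term,
so singleton positions have depth 1 with probability p.

AP sites reuse the machinery with a purine preference at the site and
no TSS enrichment; a fraction ``ap_coupling`` of the AP hot pool is
placed on SSB hot-pool positions, either at the same coordinate
("direct", the short-patch fill-in nick) or one base downstream in
strand orientation ("offset", so the AP-1 shift recovers the APE1
nick).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from .io_core import (BreakSample, ExpressionMatrix, GenomeMask, MappableSpace,
                      TssTable, polya_exclusion_mask, write_breaks, write_genome)
from .tss_enrichment import DISTANCE_BINS, BIN_LABELS, TssIndex, bin_of

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset",
           "generate_genome", "generate_breaks", "generate_ap_sites",
           "generate_expression", "generate_all",
           "expected_enrichment_ratio", "expected_template_ratio"]

Position = tuple[str, int, str]


@dataclass
class SyntheticConfig:
    # genome
    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    gc_content: float = 0.42
    repeat_fraction: float = 0.30
    polya_rate: float = 2e-5          # expected A/T runs per bp
    polya_run_min: int = 8
    polya_run_max: int = 14
    polya_footprint: int = 1
    # annotation
    n_genes: int = 200
    tss_spacing_min: int = 2000
    cpg_island_at_tss: bool = True
    cpg_island_halfwidth: int = 200
    # cohort
    n_tissues: int = 3
    samples_per_tissue: int = 4
    breaks_per_sample: int = 20_000
    ap_per_sample: int | None = None  # defaults to breaks_per_sample
    # planted SSB structure
    tss_enrichment_factor: float = 5.0
    enrichment_profile: tuple = (2.0, 1.6, 1.3, 1.15, 1.05, 1.0)  # per distance bin
    template_bias: float = 2.0        # template:nontemplate odds within +/-200
    hot_fraction: float = 0.3
    hot_pool_size: int = 1000
    upstream_c_bias: float | None = 0.5   # target C fraction at the break base
    depth_geometric_p: float = 0.8
    # planted AP structure
    ap_coupling: float = 0.5
    ap_coupling_mode: str = "direct"  # or "offset"
    ap_purine_bias: float | None = 0.7
    # planted expression structure
    expression_effect: float = 2.0
    expression_distance_graded: bool = False
    expression_noise: float = 0.25
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("hot_fraction", "ap_coupling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tss_enrichment_factor < 1:
            raise ValueError("tss_enrichment_factor must be >= 1")
        if self.template_bias < 0:
            raise ValueError("template_bias must be >= 0")
        if self.ap_coupling_mode not in ("direct", "offset"):
            raise ValueError("ap_coupling_mode must be 'direct' or 'offset'")
        if self.genome_length < self.n_genes * self.tss_spacing_min:
            raise ValueError("genome too short for requested TSS spacing")


@dataclass
class SyntheticTruth:
    hot_pool: list
    ap_pool: list
    couplings: list                     # (ssb triple, ap triple) pairs
    gene_flags: pd.DataFrame            # gene_id, has_/bin_ per strand class

    def to_json(self, path) -> None:
        payload = {
            "hot_pool": [list(p) for p in self.hot_pool],
            "ap_pool": [list(p) for p in self.ap_pool],
            "couplings": [[list(a), list(b)] for a, b in self.couplings],
            "gene_flags": self.gene_flags.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict
    non_repeat: GenomeMask
    polya_excluded: GenomeMask
    mappable: MappableSpace
    tss_table: TssTable
    ssb_samples: list
    ap_samples: list
    expression: ExpressionMatrix
    truth: SyntheticTruth
    ssb_weights: "WeightField" = None
    ap_weights: "WeightField" = None

    @property
    def tissues(self) -> list[str]:
        return sorted({s.tissue for s in self.ssb_samples})

    def samples_of(self, tissue: str, kind: str = "ssb") -> list[BreakSample]:
        pool = self.ssb_samples if kind == "ssb" else self.ap_samples
        return [s for s in pool if s.tissue == tissue]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_sequence(L: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=L, p=p)]


def _cpg_rich_block(L: int, rng: np.random.Generator) -> np.ndarray:
    """GC-rich sequence with explicit CpG dinucleotides interspersed."""
    out = np.empty(L, dtype="<U1")
    i = 0
    p = np.array([0.12, 0.38, 0.38, 0.12])
    while i < L:
        if i + 1 < L and rng.random() < 0.12:
            out[i], out[i + 1] = "C", "G"
            i += 2
        else:
            out[i] = _BASES[rng.choice(4, p=p)]
            i += 1
    return out


def generate_genome(config: SyntheticConfig, rng: np.random.Generator):
    """Genome sequences, TSS table, non-repeat and polyA-exclusion masks."""
    per_chrom = config.genome_length // config.n_chromosomes
    genome: dict[str, str] = {}
    tss_rows = []
    repeat_by_chrom: dict[str, np.ndarray] = {}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(per_chrom, config.gc_content, rng)

        # polyA / polyT runs
        n_runs = rng.poisson(config.polya_rate * per_chrom)
        for _ in range(n_runs):
            run_len = int(rng.integers(config.polya_run_min, config.polya_run_max + 1))
            start = int(rng.integers(0, per_chrom - run_len))
            seq[start:start + run_len] = "A" if rng.random() < 0.5 else "T"

        # TSSs on a jittered grid, with 1-3 transcripts per gene
        n_genes = config.n_genes // config.n_chromosomes
        slot = per_chrom // (n_genes + 1)
        jitter = max(1, (slot - config.tss_spacing_min) // 2)
        tss_positions = []
        for gi in range(n_genes):
            centre = (gi + 1) * slot
            pos = int(np.clip(centre + rng.integers(-jitter, jitter + 1),
                              600, per_chrom - 600))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene_{ci + 1}_{gi:04d}"
            n_tx = 1 + int(rng.poisson(0.7))
            offs = [0] + [int(rng.integers(-300, 301)) for _ in range(n_tx - 1)]
            for ti, off in enumerate(offs):
                tpos = int(np.clip(pos + off, 0, per_chrom - 1))
                tss_rows.append({"gene_id": gene_id, "transcript_id": f"{gene_id}.t{ti}",
                                 "chrom": chrom, "tss_pos": tpos, "strand": strand})
            tss_positions.append(pos)

        # optional CpG islands over TSS +/- halfwidth
        if config.cpg_island_at_tss:
            hw = config.cpg_island_halfwidth
            for pos in tss_positions:
                s, e = max(0, pos - hw), min(per_chrom, pos + hw + 1)
                seq[s:e] = _cpg_rich_block(e - s, rng)

        # repeats: random blocks outside TSS +/- 500 (promoters are repeat-poor)
        target = config.repeat_fraction * per_chrom
        forbidden = iv.merge(iv.as_intervals(
            [(max(0, p - 500), min(per_chrom, p + 501)) for p in tss_positions]))
        blocks = []
        covered = 0
        guard = 0
        while covered < target and guard < 100_000:
            guard += 1
            ln = int(rng.exponential(1000)) + 200
            s = int(rng.integers(0, max(1, per_chrom - ln)))
            block = iv.subtract(iv.as_intervals([(s, s + ln)]), forbidden)
            if len(block):
                blocks.extend(map(tuple, block))
                covered = iv.total_length(iv.as_intervals(blocks))
        repeat_by_chrom[chrom] = iv.merge(iv.as_intervals(blocks)) if blocks \
            else np.zeros((0, 2), dtype=np.int64)
        genome[chrom] = "".join(seq)

    non_repeat = GenomeMask(role="non_repeat", by_chrom={
        c: iv.subtract(iv.as_intervals([(0, len(genome[c]))]), repeat_by_chrom[c])
        for c in genome})
    polya = polya_exclusion_mask(genome, min_run=config.polya_run_min,
                                 footprint=config.polya_footprint)
    tss = TssTable(pd.DataFrame(tss_rows))
    return genome, tss, non_repeat, polya


# ---------------------------------------------------------------------------
# weight fields over (position, strand)
# ---------------------------------------------------------------------------

class WeightField:
    """Sampling weights over mappable strand-specific positions.

    Flat layout: per chromosome, + strand mappable positions then -
    strand mappable positions, chromosomes in sorted order.
    """

    def __init__(self, mappable: MappableSpace):
        self.chroms = mappable.chroms
        self.pos: list[np.ndarray] = []       # one entry per (chrom, strand)
        self.meta: list[tuple[str, str]] = []
        for chrom in self.chroms:
            mp = mappable.mappable_positions(chrom)
            for strand in "+-":
                self.pos.append(mp)
                self.meta.append((chrom, strand))
        sizes = np.array([len(p) for p in self.pos], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(sizes)))
        self.size = int(self.offsets[-1])
        self.w = np.ones(self.size)
        self._cdf = None

    def segment(self, chrom: str, strand: str) -> slice:
        i = self.meta.index((chrom, strand))
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    def positions_of(self, chrom: str, strand: str) -> np.ndarray:
        return self.pos[self.meta.index((chrom, strand))]

    def finalise(self) -> None:
        total = self.w.sum()
        if total <= 0:
            raise ValueError("weight field sums to zero")
        self.p = self.w / total
        self._cdf = np.cumsum(self.p)
        self._cdf[-1] = 1.0

    def sample_events(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n flat indices drawn with replacement, probability ∝ weight."""
        return np.searchsorted(self._cdf, rng.random(n), side="right")

    def sample_distinct(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """k distinct flat indices via weighted Gumbel top-k."""
        with np.errstate(divide="ignore"):
            keys = np.log(self.w) + rng.gumbel(size=self.size)
        return np.argpartition(-keys, k)[:k]

    def decode(self, flat: np.ndarray) -> list[Position]:
        seg = np.searchsorted(self.offsets, flat, side="right") - 1
        out = []
        for f, s in zip(flat, seg):
            chrom, strand = self.meta[s]
            out.append((chrom, int(self.pos[s][f - self.offsets[s]]), strand))
        return out

    def encode(self, triples) -> np.ndarray:
        out = []
        for chrom, pos, strand in triples:
            i = self.meta.index((chrom, strand))
            j = np.searchsorted(self.pos[i], pos)
            if j >= len(self.pos[i]) or self.pos[i][j] != pos:
                raise ValueError(f"position {chrom}:{pos}:{strand} not mappable")
            out.append(self.offsets[i] + j)
        return np.array(out, dtype=np.int64)


def _bias_multiplier(target: float, background: float) -> float:
    """Odds multiplier turning a background fraction into a target fraction."""
    return (target * (1 - background)) / (background * (1 - target))


def build_ssb_weights(config: SyntheticConfig, genome: dict,
                      mappable: MappableSpace, tss_index: TssIndex) -> WeightField:
    wf = WeightField(mappable)
    beta = config.template_bias
    profile = np.asarray(config.enrichment_profile, dtype=float)
    # bin-width-weighted mean so e is the average +/-200 bp enrichment
    # and e = 1 leaves the field exactly flat
    widths = np.array([hi - lo + 1 for lo, hi in DISTANCE_BINS], dtype=float)
    widths[0] = 2 * DISTANCE_BINS[0][1] + 1  # +/-5 bin spans d = -5..5
    widths[1:] *= 2
    shape = profile / np.average(profile, weights=widths)
    bin_mult = 1.0 + (config.tss_enrichment_factor - 1.0) * shape

    # upstream-C multiplier calibrated against the mappable C fraction
    c_mult = None
    if config.upstream_c_bias is not None:
        nC = nTot = 0
        for chrom in wf.chroms:
            arr = np.frombuffer(genome[chrom].encode(), dtype="S1")
            mp = mappable.mappable_positions(chrom)
            nC += int((arr[mp] == b"C").sum()) + int((arr[mp] == b"G").sum())
            nTot += 2 * len(mp)
        # per-strand C fraction: + strand Cs plus - strand Cs (reference Gs)
        pC = nC / nTot
        c_mult = _bias_multiplier(config.upstream_c_bias, pC)

    for chrom in wf.chroms:
        arr = np.frombuffer(genome[chrom].encode(), dtype="S1")
        for strand in "+-":
            seg = wf.segment(chrom, strand)
            mp = wf.positions_of(chrom, strand)
            w = np.ones(len(mp))
            d, gstrand = tss_index.nearest_arrays(chrom, mp)
            near = np.abs(d) <= 200
            if near.any():
                b = bin_of(np.abs(d[near]))
                w[near] *= bin_mult[b]
                is_template = gstrand[near] != strand
                w[near] *= np.where(is_template, 2 * beta / (1 + beta), 2 / (1 + beta))
            if c_mult is not None:
                base_c = arr[mp] == (b"C" if strand == "+" else b"G")
                w[base_c] *= c_mult
            wf.w[seg] = w
    wf.finalise()
    return wf


def build_ap_weights(config: SyntheticConfig, genome: dict,
                     mappable: MappableSpace) -> WeightField:
    wf = WeightField(mappable)
    if config.ap_purine_bias is not None:
        # strand-oriented purine fraction over mappable strand-positions
        nPur = nTot = 0
        for chrom in wf.chroms:
            arr = np.frombuffer(genome[chrom].encode(), dtype="S1")
            mp = mappable.mappable_positions(chrom)
            nPur += int(((arr[mp] == b"A") | (arr[mp] == b"G")).sum())   # + strand
            nPur += int(((arr[mp] == b"T") | (arr[mp] == b"C")).sum())   # - strand
            nTot += 2 * len(mp)
        pPur = nPur / nTot
        mult = _bias_multiplier(config.ap_purine_bias, pPur)
        for chrom in wf.chroms:
            arr = np.frombuffer(genome[chrom].encode(), dtype="S1")
            for strand in "+-":
                seg = wf.segment(chrom, strand)
                mp = wf.positions_of(chrom, strand)
                pur = (arr[mp] == b"A") | (arr[mp] == b"G") if strand == "+" else \
                    (arr[mp] == b"T") | (arr[mp] == b"C")
                w = np.ones(len(mp))
                w[pur] *= mult
                wf.w[seg] = w
    wf.finalise()
    return wf


# ---------------------------------------------------------------------------
# break samples
# ---------------------------------------------------------------------------

def _events_to_sample(flat_events: np.ndarray, wf: WeightField, sample_id: str,
                      tissue: str, config: SyntheticConfig,
                      rng: np.random.Generator) -> BreakSample:
    uniq, counts = np.unique(flat_events, return_counts=True)
    depth = counts + rng.geometric(config.depth_geometric_p, size=len(uniq)) - 1
    triples = wf.decode(uniq)
    df = pd.DataFrame(triples, columns=["chrom", "pos", "strand"])
    df["depth"] = depth.astype(np.int64)
    df = df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return BreakSample(sample_id=sample_id, tissue=tissue, df=df)


def _draw_sample(n: int, wf: WeightField, pool_flat: np.ndarray, hot_fraction: float,
                 sample_id: str, tissue: str, config: SyntheticConfig,
                 rng: np.random.Generator) -> BreakSample:
    n_hot = rng.binomial(n, hot_fraction) if len(pool_flat) else 0
    hot = pool_flat[rng.integers(0, len(pool_flat), size=n_hot)] if n_hot else \
        np.empty(0, dtype=np.int64)
    bg = wf.sample_events(n - n_hot, rng)
    return _events_to_sample(np.concatenate([hot, bg]), wf, sample_id, tissue,
                             config, rng)


def generate_breaks(config: SyntheticConfig, wf: WeightField, tss_index: TssIndex,
                    rng: np.random.Generator):
    """Per-sample SSB files plus the realised hot pool and gene flags."""
    pool_flat = wf.sample_distinct(config.hot_pool_size, rng) \
        if config.hot_pool_size else np.empty(0, dtype=np.int64)
    hot_pool = wf.decode(pool_flat)
    samples = []
    for ti in range(config.n_tissues):
        tissue = f"tissue{ti + 1}"
        for si in range(config.samples_per_tissue):
            samples.append(_draw_sample(config.breaks_per_sample, wf, pool_flat,
                                        config.hot_fraction,
                                        f"{tissue}_s{si + 1}", tissue, config, rng))
    gene_flags = _gene_flags_from_pool(hot_pool, tss_index)
    return samples, hot_pool, pool_flat, gene_flags


def _gene_flags_from_pool(hot_pool: list, tss_index: TssIndex) -> pd.DataFrame:
    from .tss_enrichment import assign_to_tss

    genes = tss_index.table.genes()
    flags = pd.DataFrame({"gene_id": genes}).set_index("gene_id")
    for cls in ("template", "nontemplate"):
        flags[f"has_{cls}"] = False
        flags[f"bin_{cls}"] = "none"
    asg = assign_to_tss(set(hot_pool), tss_index, max_distance=200)
    if len(asg):
        asg = asg.copy()
        asg["bin_idx"] = bin_of(asg["abs_distance"].values)
        for cls in ("template", "nontemplate"):
            sub = asg[asg["strand_class"] == cls]
            best = sub.groupby("gene_id")["bin_idx"].min()
            present = best.index.intersection(flags.index)
            flags.loc[present, f"has_{cls}"] = True
            flags.loc[present, f"bin_{cls}"] = [BIN_LABELS[i] for i in best.loc[present]]
    return flags.reset_index()


# ---------------------------------------------------------------------------
# AP sites
# ---------------------------------------------------------------------------

def generate_ap_sites(config: SyntheticConfig, ap_wf: WeightField,
                      hot_pool: list, genome: dict, rng: np.random.Generator):
    """Per-sample AP files; the AP hot pool is partially coupled to SSBs."""
    n_pool = config.hot_pool_size
    n_coupled = int(round(config.ap_coupling * min(n_pool, len(hot_pool))))
    couplings = []
    coupled: list[Position] = []
    if n_coupled:
        chosen = rng.choice(len(hot_pool), size=n_coupled, replace=False)
        for i in chosen:
            chrom, pos, strand = hot_pool[i]
            if config.ap_coupling_mode == "direct":
                ap = (chrom, pos, strand)
            else:  # AP one base downstream, so AP-1 lands on the SSB
                ap = (chrom, pos + 1 if strand == "+" else pos - 1, strand)
                if ap[1] < 0 or ap[1] >= len(genome[chrom]):
                    continue
            coupled.append(ap)
            couplings.append((tuple(hot_pool[i]), ap))
    coupled_flat = []
    for trip in coupled:
        try:
            coupled_flat.append(int(ap_wf.encode([trip])[0]))
        except ValueError:
            couplings = [c for c in couplings if c[1] != trip]
    n_free = n_pool - len(coupled_flat)
    free_flat = ap_wf.sample_distinct(max(n_free, 0), rng) if n_free > 0 else \
        np.empty(0, dtype=np.int64)
    pool_flat = np.unique(np.concatenate([np.array(coupled_flat, dtype=np.int64),
                                          free_flat]))
    ap_pool = ap_wf.decode(pool_flat)
    n_ap = config.ap_per_sample or config.breaks_per_sample
    samples = []
    for ti in range(config.n_tissues):
        tissue = f"tissue{ti + 1}"
        for si in range(config.samples_per_tissue):
            samples.append(_draw_sample(n_ap, ap_wf, pool_flat, config.hot_fraction,
                                        f"{tissue}_ap{si + 1}", tissue, config, rng))
    return samples, ap_pool, couplings


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_GRADE_WEIGHT = {lbl: (len(BIN_LABELS) - i) / len(BIN_LABELS)
                 for i, lbl in enumerate(BIN_LABELS)}


def generate_expression(config: SyntheticConfig, gene_flags: pd.DataFrame,
                        rng: np.random.Generator) -> ExpressionMatrix:
    """Log-normal base TPM scaled up for hotspot-bearing genes.

    Ungraded: genes flagged on either strand are multiplied by
    ``expression_effect``. Graded: the multiplier is
    effect**w with w falling linearly from 1 (+/-5 bin) to 1/6
    (+/-151-200 bin) of the gene's template-strand bin.
    """
    genes = gene_flags["gene_id"].tolist()
    base = rng.lognormal(mean=1.0, sigma=1.2, size=len(genes))
    factor = np.ones(len(genes))
    gamma = config.expression_effect
    if config.expression_distance_graded:
        for i, b in enumerate(gene_flags["bin_template"]):
            if b != "none":
                factor[i] = gamma ** _GRADE_WEIGHT[b]
    else:
        has = (gene_flags["has_template"] | gene_flags["has_nontemplate"]).values
        factor[has] = gamma
    cols = {}
    sample_tissue = {}
    for ti in range(config.n_tissues):
        tissue = f"tissue{ti + 1}"
        for si in range(config.samples_per_tissue):
            sid = f"{tissue}_rna{si + 1}"
            noise = rng.lognormal(mean=0.0, sigma=config.expression_noise,
                                  size=len(genes))
            cols[sid] = base * factor * noise
            sample_tissue[sid] = tissue
    tpm = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(tpm=tpm, sample_tissue=sample_tissue)


# ---------------------------------------------------------------------------
# orchestration and analytic expectations
# ---------------------------------------------------------------------------

def generate_all(config: SyntheticConfig | None = None,
                 outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full input bundle; optionally write it to ``outdir``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.rng_seed)
    genome, tss, non_repeat, polya = generate_genome(config, rng)
    mappable = MappableSpace({c: len(s) for c, s in genome.items()},
                             non_repeat, polya)
    tss_index = TssIndex(tss)
    ssb_wf = build_ssb_weights(config, genome, mappable, tss_index)
    ssb_samples, hot_pool, _pool_flat, gene_flags = \
        generate_breaks(config, ssb_wf, tss_index, rng)
    ap_wf = build_ap_weights(config, genome, mappable)
    ap_samples, ap_pool, couplings = generate_ap_sites(config, ap_wf, hot_pool,
                                                       genome, rng)
    expr = generate_expression(config, gene_flags, rng)
    truth = SyntheticTruth(hot_pool=hot_pool, ap_pool=ap_pool,
                           couplings=couplings, gene_flags=gene_flags)
    ds = SyntheticDataset(config=config, genome=genome, non_repeat=non_repeat,
                          polya_excluded=polya, mappable=mappable, tss_table=tss,
                          ssb_samples=ssb_samples, ap_samples=ap_samples,
                          expression=expr, truth=truth,
                          ssb_weights=ssb_wf, ap_weights=ap_wf)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "ssb").mkdir(parents=True, exist_ok=True)
    (outdir / "ap").mkdir(parents=True, exist_ok=True)
    write_genome(ds.genome, outdir / "genome.fa")
    ds.non_repeat.to_bed(outdir / "non_repeat.bed")
    ds.polya_excluded.to_bed(outdir / "polya_excluded.bed")
    ds.tss_table.to_tsv(outdir / "tss.tsv")
    for s in ds.ssb_samples:
        write_breaks(s, outdir / "ssb" / f"{s.sample_id}.bed")
    for s in ds.ap_samples:
        write_breaks(s, outdir / "ap" / f"{s.sample_id}.bed")
    ds.expression.to_tsv(outdir / "expression.tsv")
    ds.truth.to_json(outdir / "truth.json")
    (outdir / "samples.tsv").write_text(
        "sample_id\ttissue\tkind\n" +
        "".join(f"{s.sample_id}\t{s.tissue}\tssb\n" for s in ds.ssb_samples) +
        "".join(f"{s.sample_id}\t{s.tissue}\tap\n" for s in ds.ap_samples) +
        "".join(f"{sid}\t{t}\trna\n"
                for sid, t in ds.expression.sample_tissue.items()))
    (outdir / "config.json").write_text(json.dumps(asdict(ds.config), indent=1))


def _inclusion_probs(ds: SyntheticDataset) -> np.ndarray:
    """Per flat strand-position probability of appearing in one sample.

    Exact under the event model: a position is present when hit by at
    least one of the Binomial(n, h) pool events (if pooled) or the
    background events.
    """
    cfg = ds.config
    wf = ds.ssb_weights
    n = cfg.breaks_per_sample
    n_hot = n * cfg.hot_fraction
    n_bg = n - n_hot
    p_bg = wf.p
    log_miss = n_bg * np.log1p(-np.minimum(p_bg, 1 - 1e-12))
    pool_flat = wf.encode(ds.truth.hot_pool)
    p_hot = np.zeros(wf.size)
    if len(pool_flat):
        p_hot[pool_flat] = 1.0 / len(pool_flat)
        log_miss = log_miss + n_hot * np.log1p(-p_hot)
    return 1.0 - np.exp(log_miss)


def _flat_bins(ds: SyntheticDataset):
    """Per flat position: |nearest TSS distance| bin index and template flag."""
    wf = ds.ssb_weights
    index = TssIndex(ds.tss_table)
    absd = np.empty(wf.size, dtype=np.int64)
    templ = np.empty(wf.size, dtype=bool)
    for (chrom, strand), i in zip(wf.meta, range(len(wf.meta))):
        seg = slice(int(wf.offsets[i]), int(wf.offsets[i + 1]))
        d, gstrand = index.nearest_arrays(chrom, wf.pos[i])
        absd[seg] = np.abs(d)
        templ[seg] = gstrand != strand
    return absd, templ


def expected_enrichment_ratio(ds: SyntheticDataset) -> float:
    """Numeric per-sample expectation of R under the realised generator state."""
    from .tss_enrichment import region_lengths

    inc = _inclusion_probs(ds)
    absd, _ = _flat_bins(ds)
    E_M200 = float(inc[absd <= 200].sum())
    E_M5000 = float(inc[absd <= 5000].sum())
    lens = region_lengths(TssIndex(ds.tss_table), ds.mappable)
    return (E_M200 / E_M5000) / (lens["L200"] / lens["L5000"])


def expected_template_ratio(ds: SyntheticDataset, bin_index: int = 0) -> float:
    """Expected template:nontemplate position count ratio in a distance bin."""
    inc = _inclusion_probs(ds)
    absd, templ = _flat_bins(ds)
    lo, hi = DISTANCE_BINS[bin_index]
    sel = (absd >= lo) & (absd <= hi)
    return float(inc[sel & templ].sum() / inc[sel & ~templ].sum())
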