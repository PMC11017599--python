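# Methods

## Coordinate and break semantics

All coordinates are 0-based, half-open internally; files use BED
dialects. A break record `(chrom, pos, strand, depth)` marks the base
whose 3′ side carries the nick, in strand orientation: on `+` the nick
lies between reference `pos` and `pos+1`, on `−` between `pos−1` and
`pos`. This convention makes the CG-context notation exact — `C|G`
means the base at `pos` is C and its strand-oriented 3′ neighbour is G;
`|CG` means the CG begins one base 3′ of the nick — and it places the
break between the centre column and the next column of a motif window.
Sequence windows are `2·flank+1`-mers centred on `pos`, reverse-
complemented for `−` strand breaks so index 0 is always 5′-most.

Whether a public break-map dialect marks the 5′ or the 3′ base of a
nick varies; the io layer is the single place to flip the convention if
data arrive in the other one.

## Mappability

Breaks are analysed inside the non-repeat mask minus a polyA-adjacency
exclusion: 3′-OH capture chemistry cannot anchor reads immediately
downstream of endogenous polyA tracts. The exclusion rule blinds the
`footprint` bases (default 1) immediately 3′, in strand orientation, of
every run of ≥ `min_run` (default 8) adenines, on both strands (a
thymine run is a `−`-strand polyA). Both parameters are configuration;
no standard exists for "adjacent". All length normalisations (`L`
terms, `LG`, bin mappable fractions `f_j`) use the same combined mask,
held as a per-chromosome boolean array with prefix sums for O(1) window
counts.

## Hotspot calling

Strand-specific triples `(chrom, pos, strand)` are called per tissue:

* sample-level: within-sample depth ≥ 2, union over the tissue's
  samples (per-tissue totals imply pooling; an intersection variant
  would be a one-line change in `call_sample_level`);
* sample-shared: depth ≥ d in ≥ 2 distinct samples (d = 1 and d = 2
  both used; d = 1 is the workhorse set downstream, the d = 2 set being
  small);
* merged cohort: sample-shared calling ignoring tissue boundaries, used
  for the SSB–AP overlap.

Hotspot *fractions* use distinct pooled break positions of the tissue
as denominator, not read counts: positions make real and simulated data
commensurable because the null generates positions. The choice is
recorded in the output metadata column `denominator`.

## Uniform-placement null

Per iteration (default 100) each sample's observed number of positions
is re-drawn uniformly, without replacement within a sample, over
mappable positions × strands; hotspots are re-called with the identical
definition and the fraction recorded. Simulated depths are resampled
from the sample's empirical depth distribution (so depth-thresholded
definitions are exercised); a constant-depth mode exists. The real
fraction is compared with the simulated vector by a two-sided
one-sample *t*-test; a zero-variance vector is reported as degenerate
with a warning rather than a p-value. Distinct-index sampling uses
collision-resolved oversampling when the draw is sparse (< capacity/3)
and a partial Fisher–Yates otherwise; with a fixed seed the whole
procedure is bit-reproducible.

## TSS statistics

Every position is assigned to its nearest TSS; equidistant ties go to
the smaller genomic coordinate, and multiple transcripts sharing a
coordinate resolve by (gene_id, transcript_id) order — all
deterministic. `template` means break strand ≠ gene strand. Signed
distances are kept in genome coordinates (strand information lives in
the template/nontemplate class, not in the distance sign).

Windows around nearby TSSs overlap; counts and lengths are therefore
defined through the nearest-TSS partition, which counts every position
and every base exactly once and makes `M`/`L` pairs consistent. The six
distance bins (|d| ≤ 5, 6–20, 21–50, 51–100, 101–150, 151–200) are
closed on both ends and partition 0–200 exactly; the ±5 bin spans 11
positions including d = 0.

Odds ratios follow `OR_i = (M_i/T_i)/(L_i/LG)` with lengths in
strand-specific *candidate positions*: each base contributes one
template-strand and one nontemplate-strand candidate (relative to its
nearest gene), so per strand class `L_i` equals the bin's mappable
bases and `LG` equals 2 × mappable bases, while for unstranded sets the
factor 2 cancels and the formula reduces to plain base-pair lengths.
This scaling is what makes a uniformly scattered set score OR = 1 in
every bin and strand class — with raw base-pair lengths a per-strand OR
would be calibrated to 0.5, which silently halves apparent strand
effects.

The aggregate profile uses 500 non-overlapping 20 bp bins over ±5 kb:
`D_j = (n_j/N)/f_j` with `f_j` the mean mappable fraction of bin j over
all TSSs and `N` the assigned positions of the strand class; `D_j` is
reported missing where `f_j = 0`. Note `f_j` deliberately averages over
*all* TSS windows (double-covering bases near TSS clusters) while `M/L`
use the nearest-TSS partition; the two normalisations answer different
questions (per-TSS average density vs. unique-event enrichment).

Paired per-tissue comparisons (e.g. hotspot R vs. all-break R) use the
one-sided exact Wilcoxon signed-rank test with zero-differences
excluded.

## SSB–AP overlap and CG context

BER produces nicks at fixed offsets from an AP site: the AP-endonuclease
cut immediately 5′ (recovered by shifting AP coordinates one base
upstream in strand orientation, "AP−1") and the short-patch
pre-ligation nick at the site itself (direct overlap). Overlap is
strand-matched by default (the BER nick inherits the AP site's strand);
a strand-agnostic flag exists for sensitivity analysis.
`OOR = (O/T)/(M/LG)` uses the same candidate-position `LG` as the ORs,
and a one-sided Fisher exact test on the 2×2 of AP-hotspot membership
among SSB positions vs. the rest of the candidate universe accompanies
it — the choice of companion test is ours.

CG context tests `C|G` and `|CG` (mutually exclusive by construction);
positions whose test would read past a contig end are excluded from the
denominator and counted, not dropped silently. The background is the
exhaustive fraction of mappable strand-positions firing the same rule,
optionally restricted to TSS windows.

## Expression association

One transcript per gene is chosen at random (seeded, recorded) where a
single representative is needed; hotspot-bearing status uses *any*
annotated TSS of the gene. Per tissue, expression is the mean TPM over
the tissue's samples, displayed as log2(TPM+1), and with/without
comparisons use the two-sided Wilcoxon rank-sum test (exact where
sample sizes permit). For the pooled distance-bin analysis a gene's bin
per strand and tissue is its most TSS-proximal bin; pooling across
tissues is a union — a gene in different bins in different tissues
joins each such group, contributing that tissue's expression value — 
with a strict most-proximal-across-tissues variant behind a flag.

## Synthetic data generator

The generator emulates exactly the statistical structure the pipeline
measures, with every parameter explicit and a truth record
(hot-position pool, per-gene flags and bins, AP–SSB couplings) emitted
alongside the files.

Default scenario: one 2 Mb chromosome, GC 0.42, 30% repeats (kept out
of TSS ± 500 bp — promoters are repeat-poor), ~200 genes with 1–3
transcripts on a jittered grid (min spacing 2 kb), CpG-enriched
± 200 bp islands at TSSs, 3 tissues × 4 samples × 20,000 break events.
This size keeps generation ~5 s and the full pipeline under a minute on
one core.

Break events are drawn from a per-(position, strand) weight field:
uniform over mappable space; within ±200 bp of the nearest TSS a
multiplier `1 + (e−1)·profile(bin)/mean(profile)` (bin-width-weighted
mean, so e is the *average* ±200 bp enrichment and e = 1 is exactly
flat — the flatness at e = 1 is what the null-calibration tests rest
on), with the profile rising toward ±5 bp; template-strand odds β
within ±200 bp (factors 2β/(1+β) and 2/(1+β), preserving total mass);
and an upstream-cytosine odds multiplier calibrated against the
realised mappable C fraction so the break-base C fraction targets the
configured value. With probability h an event instead draws uniformly,
with replacement, from a shared hot-position pool (itself sampled from
the weight field by weighted Gumbel top-k). A position's depth is its
event multiplicity plus Geometric(0.8) − 1, so singletons have depth 1
with probability 0.8. `breaks_per_sample` therefore counts *events*:
with a pool of 1,000 and h = 0.3, 6,000 events concentrate on the pool
and surface as high-depth shared positions — the only consistent
reading, since 30% of *distinct* positions could not come from a pool
smaller than the demand.

AP sites reuse the machinery with no TSS enrichment or strand bias and
a purine preference at the site; a fraction c of the AP pool is placed
on SSB pool positions — at the same coordinate ("direct") or one base
downstream so that the AP−1 shift recovers them ("offset") — making the
two overlap modes separable by construction. Expression is log-normal
base TPM (ln-scale μ = 1.0, σ = 1.2), multiplied by γ for
hotspot-bearing genes (distance-graded variant: γ^w, w falling linearly
from 1 at ±5 bp to 1/6 at ±151–200 bp), with per-sample log-normal
noise (σ = 0.25).

Analytic expectations for recovery tests are computed numerically from
the realised weight field, not from closed forms: the per-sample
inclusion probability of every candidate position is
`1 − (1−p_bg)^n_bg · (1−p_pool)^n_hot`, summed per distance bin, which
accounts for the saturation of high-weight positions that a naive
weight-share formula misses.

What the generator does *not* emulate: chromatin and replication-timing
covariates, sequence-driven mappability structure beyond polyA tracts,
CpG depletion (an iid-base genome has ~4% CG-dinucleotide frequency per
strand where mammalian genomes are CpG-poor, so synthetic CG background
fractions run high), inter-sample depth correlation, and genome-scale
sparsity. The last matters: compressing a genome 1000-fold while
keeping realistic per-sample break counts saturates TSS windows, so at
default scale essentially every gene acquires a measured hotspot and
the per-tissue with/without expression split degenerates toward
200 vs 0. Passing tests therefore show the statistics are correctly
computed and recover planted parameters at this density — not that the
pipeline's power curves match a 2.7 Gb genome. The expression test's
power and type-I behaviour are accordingly validated on balanced
constructed cohorts (200 hotspot vs 200 non-hotspot genes) drawn from
the same expression generator.

## Numerical and testing choices

* Exact interval arithmetic (merge/intersect/subtract) backs every
  length; no floating-point geometry.
* The motif difference-profile threshold is strictly greater-than 0.05
  with a 1e-9 guard so a difference of exactly the threshold is
  suppressed despite float round-off.
* Rank-sum and signed-rank tests defer to exact distributions where
  scipy provides them (small n, no ties).
* Null-calibration checks use instances with ≥ ~100 expected shared
  positions so the [0.5, 2] ratio band measures calibration rather than
  Poisson counting noise.
* The three-stringency monotonicity, strand-split/union equivalence,
  ±200 bin partition, AP-shift bijectivity and fixed-seed byte
  reproducibility of the full pipeline are asserted as invariants in
  the test suite; small randomized instances are checked exactly
  against brute-force recounts (nearest-TSS by exhaustive scan,
  per-base length scans, pure-Python set arithmetic).

## Known limitations

* Sample-shared hotspot sets overweight reproducible positions, which
  *squares* per-position sampling biases: with planted template odds
  β = 2 the hotspot-set template ratio runs above β (collision
  probability scales with weight²) while per-sample break positions
  recover β itself. Parameter-recovery tests therefore measure strand
  bias on positions, and the hotspot-set ratios are reported as
  observations.
* The D_j profile normalisation is declared in output metadata;
  alternative aggregate normalisations exist in the literature and are
  not implemented.
* No GC-, chromatin- or expression-matched nulls: the null is uniform
  over mappable space by design.
* GTF/GFF gene models are not parsed; a pre-extracted TSS table is the
  contract.
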