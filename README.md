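# breakome

Nucleotide-resolution analysis of single-strand DNA break (SSB) and
abasic (AP) site maps: hotspot detection, randomization nulls,
TSS-proximity enrichment, template-strand bias, base-excision-repair
(BER) overlap inference, sequence-context profiling, and
hotspot–expression association.

## The problem

Strand-specific sequencing of 3′-OH ends (and of AP sites) yields, per
biological sample, a genome-wide list of single-nucleotide break
positions with read depths. Two questions follow. First, do breaks
recur at the *same* nucleotides across samples more than chance allows
— i.e., are there hotspots? Second, what are those hotspots: do they
concentrate around transcription start sites (TSSs), prefer the
template strand, coincide with AP-site hotspots at the fixed offsets
BER would produce, sit in characteristic sequence contexts, and mark
highly expressed genes?

`breakome` implements this analysis end-to-end for anyone with
BED-formatted single-nucleotide break maps, a genome FASTA, a
mappability mask and a TSS table — and ships a seeded synthetic-data
generator with planted structure so every statistic can be validated by
parameter recovery before it is pointed at real data.

## Statistics implemented

With depth *d* per position within a sample, hotspots are called per
tissue as:

* **sample-level**: positions with *d* ≥ 2 within a single sample
  (union over samples);
* **sample-shared**: positions with *d* ≥ 1 (or ≥ 2) in at least two
  independent samples.

Their excess over chance is quantified by re-placing each sample's
positions uniformly over mappable space (100 iterations), re-calling
hotspots, and comparing fractions (one-sample two-sided *t*-test).

TSS proximity uses nearest-TSS assignment (ties to the smaller
coordinate) and, for a set *i* of positions:

* enrichment ratio `R_i = (M_i^200 / M_i^5000) / (L_i^200 / L_i^5000)`
  where `M` counts unique positions within ±200 bp / ±5 kb of TSSs and
  `L` the corresponding mappable lengths;
* per-distance-bin odds ratios `OR_i = (M_i / T_i) / (L_i / LG)` over
  the six bins ±5, ±6–20, ±21–50, ±51–100, ±101–150, ±151–200 bp,
  with lengths measured in strand-specific candidate positions so a
  uniform scatter scores OR = 1 in every bin;
* template/nontemplate ratios (a break on the strand opposite the gene
  strand is on the template strand);
* aggregate density profiles `D_j = (n_j / N) / f_j` over 500 × 20 bp
  bins spanning ±5 kb.

SSB–AP overlap is scored as `OOR_i = (O_i / T_i) / (M_i / LG)` in two
modes mirroring BER chemistry: direct coordinate overlap (the
pre-ligation nick 3′ of the AP site) and overlap after shifting AP
coordinates one base upstream ("AP−1", the APE1 nick), with a Fisher
exact companion test. CG-dinucleotide context (`C|G` or `|CG`, the bar
marking the nick) is compared against the exhaustive mappable-genome
background. Expression association uses Wilcoxon rank-sum tests on
log2(TPM+1), both with/without hotspot per tissue and across six
hierarchical distance bins per strand pooled over tissues.

## Worked example

`examples/` holds one short script per capability. From
`examples/01_hotspots_and_null.py` (4 samples × 4,000 break events on a
synthetic 400 kb genome, 30% of events from a shared hot pool):

```
tissue1: 4 samples, 11154 distinct break positions
  sample_level_d2            2503 hotspots (fraction 0.2244 of break positions)
  sample_shared_d1_s2         445 hotspots (fraction 0.0399 of break positions)
  sample_shared_d2_s2         212 hotspots (fraction 0.0190 of break positions)

uniform null (100 iterations): mean simulated fraction 0.00810
real/simulated ratio 4.92, t-test p = 2.56e-162
```

The shared-hotspot fraction is ~5× its uniform-null expectation: break
positions recur across samples far beyond chance. Example 02 then
recovers the planted TSS enrichment (R = 4.36 against a generator
expectation of 4.52) and the planted 2:1 template-strand odds; example
03 shows the overlap odds ratio separating the two BER nick geometries
(OOR 18.9 in the planted direct mode vs 1.1 after the AP−1 shift);
examples 04–06 cover sequence context, expression association and the
full pipeline (`breakome run-all` / `summarize` on the command line).

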