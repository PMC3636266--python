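# satchip

Linker histone H1 is the most abundant chromatin protein after the core
histones, yet mapping it by ChIP-seq is awkward: H1 is depleted rather than
enriched at most landmarks (active TSSs in particular), and its strongest
binding sites sit on tandem satellite repeats where short reads multi-map.
`satchip` implements the analysis stack for exactly this situation —
input-subtracted occupancy tracks, repeat-library read assignment with
random multiread placement, expression-stratified metagene profiles,
genome-wide track correlation, SICER-style island calling, and
nucleosome-repeat-length (NRL) estimation from MNase ladders — together
with a synthetic-data generator that reproduces the relevant signal
structure (satellite arrays with known enrichment, TSS dips scaling with
expression, digestion-time-dependent ladders) so the whole pipeline is
testable end to end with known ground truth and no external downloads.

## Core computations

- **Occupancy signal.** Reads (BED fragment intervals) are counted at their
  fragment midpoint into w-bp windows, normalized to tag counts per 10
  million mapped reads, and subtracted: IP−IN = ChIP − input, per window.
  GC% tracks are computed from sequence with N bases excluded.
- **Repeat enrichment.** A read hits a repeat consensus if its first 35
  bases align to the doubled consensus (tandem junctions included), either
  strand, with ≤ 2 mismatches; multi-hit reads are placed uniformly at
  random among hit entries with a seeded generator. Per class,
  percent mapped = 100 · reads-in-class / library total, fold enrichment =
  ChIP% / input%, significance by a two-sided Fisher exact test on the 2×2
  read-count table (computed by direct enumeration of the conditional
  hypergeometric distribution).
  For a class covering genomic fraction *s* sampled with weight *f*, the
  expected fold is *f* / (1 + *s*(*f* − 1)).
- **Metagene profiles.** Mean IP−IN in 100-bp bins over TSS ± flank,
  strand-flipped so profiles read 5′→3′, for gene groups defined by
  expression rank (deciles/quintiles), promoter mark level, or
  bivalency (K4/K27 presence).
- **Correlation.** Pearson R between tracks after summation into 1-kb
  windows, pooled genome-wide or per chromosome, NaN windows dropped
  pairwise.
- **Islands.** Windows whose counts are improbable under a uniform Poisson
  background (rate λ = N·w / (0.8·G)) are merged across gaps ≤ g and scored
  by Σ −ln p; a Monte-Carlo E-value threshold and an empirical
  Benjamini–Hochberg FDR against islands called on the input library filter
  the calls (defaults w = 200, g = 600, E = 1000, q ≤ 0.001, with a gap
  sweep over {0, 200, 400, 600}).
- **NRL.** Within each MNase digestion timepoint, polynucleosome band size
  is regressed on band number (the slope is the apparent NRL; trimming
  moves only the intercept); apparent NRLs are then regressed on digestion
  time and extrapolated to t = 0.

## Worked example

```
satchip demo-config demo.yaml
satchip all --config demo.yaml
```

builds a 300-kb genome carrying a 15-kb satellite array (ChIP sampling
weight 4, 5% monomer divergence) and 60 genes with expression-scaled TSS
dips, simulates 30k-read ChIP and input libraries plus an MNase ladder,
and runs every stage. Key outputs from the shipped config (seed 1):

`repeat_enrichment.tsv` — the satellite class captures 15.2% of ChIP reads
vs 4.0% of input reads, fold enrichment 3.8 (p ≈ 0 by the exact test). The
fold exceeds the bare closed form 3.48 for *f* = 4, *s* = 0.05 because the
demo ChIP library is additionally depleted over gene bodies, which
concentrates reads on the satellite:

```
cls       chip_pct  input_pct  fold     p_value
satMajor  15.2433   3.98667    3.82358  0
```

`islands.bed` — one broad island, covering the satellite array almost
exactly (99.8% of called bp):

```
chr1  270000  285000  island_1  31729  .
```

`correlations.tsv` — IP−IN anticorrelates with GC% (R = −0.71) because the
enriched satellite is AT-rich, mirroring the characteristic
heterochromatin-biased H1 landscape.

`nrl.tsv` — the ladder was simulated with a 200-bp zero-time repeat length
shortening by 1 bp/min; regression-extrapolation recovers
`nrl0 = 200.05 ± 1.04` bp from apparent per-timepoint NRLs of
197.3 / 196.1 / 190.5 bp at 2.5 / 5 / 10 min.

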