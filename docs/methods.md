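# Methods

This note documents the models, conventions and numerical choices behind
`satchip`, in the spirit of a methods section a maintainer can audit.

## Coordinates and windows

All coordinates are 0-based half-open throughout (BED-native). Windowed
tracks tile each chromosome as non-overlapping w-bp windows covering
[0, L); the last window may be partial. We read "w-bp sliding window" in
the occupancy-track convention as tiling rather than a per-bp sliding
average: tiling keeps read-count conservation exact (Σ window values =
library size), which the conservation tests assert, and the window size is
a parameter everywhere, so a user who wants denser sampling can shrink w.

Reads are counted at their fragment midpoint with no artificial read
extension. The simulator records the fragment interval for every read, so
midpoint counting is unbiased for the known fragment length; no extension
model is needed or assumed.

## Synthetic data model

The generator emulates three features of linker-histone ChIP data that the
downstream statistics depend on, and deliberately nothing else:

1. **Satellite enrichment with multi-mapping.** Tandem arrays are built as
   `copies` copies of a monomer, each base independently substituted at the
   divergence rate (default 5%, a realistic figure for pericentromeric
   satellite monomers vs their consensus). Multi-mapping then arises
   naturally from the tandem structure; reads are not labelled as
   multireads — the assignment module discovers that.
2. **TSS occupancy dips scaling with activity.** Each library samples
   fragment start positions with probability proportional to a per-base
   weight landscape: w(i) = class_weight(feature covering i) × Π over
   nearby TSSs of (1 − d·exp(−(i−TSS)²/2σ²)), with d = depth ×
   (expression percentile)^power. The Gaussian multiplicative dip is a
   modeling choice (no quantitative dip shape is established for real
   data); depth < 1 keeps the density positive. Default σ = 300 bp and
   depth 0.6 give dips of roughly the visible width and relative depth of
   TSS occupancy dips in published metagene plots. Gene bodies can carry a
   class weight < 1 (default 0.7 in the demo) so ChIP signal over genes
   sits below the input control, as observed for H1. The weight is
   evaluated at the fragment midpoint, matching the counting convention.
   The dip is strand-agnostic: occupancy, not transcription, is modeled.
3. **MNase ladders.** Band n at digestion time t runs at
   S(n,t) = n·(NRL₀ − r·t) + b + ε, ε ~ N(0, SD²) independently per band.
   The linear-in-time apparent shortening emulates progressive linker
   trimming; the spec rejects parameter sets where the apparent repeat
   length reaches zero within the time course.

Everything is a pure function of (spec, seed); identical seeds give
byte-identical libraries. Reads are emitted from both strands with
probability 1/2; sequencing error, PCR duplicates, GC amplification bias
and paired ends are intentionally out of scope. Consequently, passing
tests demonstrate correctness of the estimators under the stated sampling
model — not robustness to artifacts real libraries contain.

## Repeat assignment

The unit of assignment is the library entry; entries aggregate into
classes by label. A read hits an entry if its first 35 bases (the seed;
no quality trimming) match the entry's doubled consensus — two
concatenated copies, so seeds spanning tandem junctions are found — on
either strand at any offset with ≤ 2 mismatches. N never counts as a
match. A read hitting one entry at several offsets counts once; a read
hitting ≥ 2 entries is placed uniformly at random among them by a seeded
generator.

Matching is exact, not heuristic: the seed is split into
(max_mismatch + 1) parts, so any qualifying alignment contains at least
one exactly matching part (pigeonhole); candidate offsets come from k-mer
lookup of the parts and are verified by Hamming count. This scans 200k
reads against a desk-scale library in well under a second.

The Fisher exact test on the per-class 2×2 table is computed by direct
enumeration of the conditional hypergeometric distribution in log space
(two-sided: total probability of tables at most as probable as the
observed one, with the customary 1e-7 relative tie tolerance). The unit
tests cross-check it against `scipy.stats.fisher_exact` and against an
exact integer-arithmetic enumeration; agreement is ≤ 1e-12 absolute over
every table with grand total ≤ 50 and ≤ 1e-10 on random larger tables.

## Metagene profiles

Profiles are per-offset means of the track window containing each bin
center, bins being track-window-sized (default 100 bp) over anchor ±
flank. Minus-strand genes are mirrored so profiles read 5′→3′. Bins
falling off a chromosome are excluded from that offset's mean (not
zero-filled). Expression ranks break ties by stable gene-id order, and
k-partitions allocate remainders to the earlier (lower-rank) groups, so
group sizes differ by at most one. The expression-extremes scheme
partitions genes into top10/mid80/bottom10; the all-genes profile is
produced by passing no grouping, keeping "every gene in exactly one
group" true for every grouping object. Promoter mark scores average the
mark track over TSS ± 2 kb and bivalency tests overlap of TSS ± 1 kb with
the region sets (half-open); both half-widths are parameters chosen to
match the visible extent of promoter mark peaks. The distal-decay
analysis requires an explicit exclusion radius (no principled default
exists for "vicinity of another TSS"); points are dropped when their
window lies within the radius of any other gene's TSS.

## Correlation

Tracks are rebinned to the analysis window (default 1 kb) by summation
and correlated with Pearson's R, pooled across chromosomes for the
genome-wide figure (not averaged per chromosome — the per-chromosome
function exists separately, and a test exercises the Simpson-style case
where the two disagree). Windows with a missing value in either track
(all-N GC windows) are dropped pairwise; imputation would bias R.
Zero-signal windows are kept by default (`drop_zero` exposes the
alternative). Zero variance yields R = NaN, reported rather than raised.

## Island calling

Window eligibility uses the upper-tail Poisson p-value at the uniform
background rate λ = N·w / (effective_fraction·G) with eligibility
threshold p₀ = 0.2 (the published SICER default); zero-count windows are
never eligible. Eligible windows separated by ≤ gap bp of ineligible
space merge; the island score is Σ −ln p over its eligible windows.

The E-value threshold is realized by seeded Monte Carlo rather than the
analytic SICER recursion: uniform libraries of the same size are placed
over the effective genome, islands are called identically, and the score
threshold is the smallest value whose expected background island count is
≤ E. This is a deliberate simplification — exact at desk scale,
brute-force checkable, and deterministic under the seed — not a bit-exact
reimplementation of SICER v1.1.

The FDR step compares ChIP island scores against the empirical score
distribution of islands called identically on the input library
(upper-tail empirical p, Benjamini–Hochberg adjusted, keep q ≤ 0.001). A
ChIP island exceeding every input score gets empirical p = 0; with the
small island counts of desk-scale data any nonzero empirical p would be
dominated by the 1/n_input resolution, so the plain empirical fraction is
used rather than a continuity-corrected one.

Gap optimization calls islands at gaps {0, w, 2w, 3w} and keeps the gap
maximizing the aggregate score of significant islands, ties to the
smallest gap. Region annotation assigns each region by its midpoint
(gene span → gene; within 5 kb of a gene boundary → proximal; else
distal); midpoint assignment and the 5-kb proximal flank are parameters,
since neither convention is canonical.

## Quantification

- NRL: apparent NRL per timepoint is the OLS slope of band size on band
  number (intercept free, so end-trimming does not bias it);
  extrapolation to t = 0 is OLS of apparent NRL on time, reporting the
  intercept and its standard error. Linear extrapolation is the
  package's reading of "extrapolating the curves to time 0"; with three
  timepoints nothing richer is identifiable.
- H1 per nucleosome: Σᵢ(A₂₁₄,ᵢ/bondsᵢ) / ((A₂₁₄,H2B/bonds_H2B)/2) — peak
  areas adjusted by peptide-bond counts (A₂₁₄ absorbs per bond), H2B
  halved because the nucleosome carries two copies.
- qPCR quantities are treated as linear-scale signals (post standard
  curve or 2^−Ct); subtraction of a mock-RT control is meaningless on the
  Ct scale. Negative mock-subtracted targets clamp to 0 with a flag.
- Percent methylated CpG excludes unscored calls from the denominator.

## Problem sizes

The shipped demo uses a 300-kb genome with 30k-read libraries; the
acceptance script uses a 500-kb satellite genome with 200k-read libraries
for enrichment recovery, a 2-Mb / 400-gene genome with 800k-read
libraries for metagene ordering (SE per profile bin ≈ 5% of the dip
contrast, comfortably resolving the orderings tested), a 10-Mb genome
(10⁴ 1-kb windows) for correlation directionality, and 100 replicate
ladders per NRL condition. These sizes were chosen so every Monte Carlo
assertion sits ≥ 3 SE from its decision boundary while the whole suite
runs in minutes on one CPU.

## Known limitations

- The simulator's read model has no sequencing error, so seed-match
  assignment rates on synthetic satellites (set by monomer divergence)
  are optimistic relative to real libraries.
- The island caller's Monte Carlo E-value threshold becomes expensive for
  mammalian-scale genomes; at that scale the analytic SICER recursion is
  the right tool.
- Fold-enrichment SEs in the tests use the binomial delta method, which
  ignores the (tiny) covariance induced by random multiread placement.
- Metagene bins take the value of the track window containing the bin
  center; anchors not aligned to the window grid therefore sample
  slightly shifted windows rather than interpolating.
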