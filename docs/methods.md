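# Methods

## Setting

A barcode-ChIP screen couples every clone of an arrayed yeast library to one
TAP-tagged protein and one unique DNA barcode at a fixed locus (two barcodes
— promoter-proximal and terminator-proximal — for the reporter-cassette
design; one 15-bp barcode for CRISPR-inserted native-locus designs). After
crosslinking and ChIP against the shared tag on the pooled library, barcode
abundance in the IP relative to the input fraction measures each tagged
protein's crosslinking at its own barcoded locus. This package implements
everything downstream of the sequencer, plus a simulator of everything
upstream of it.

## Read extraction

Amplicons are parsed by anchor location, not by fixed offsets from the read
start: the constant region of the cassette is searched for within a
configurable window (`search_window`, default positions 0–30), accepting up
to `max_anchor_mismatches` substitutions (default 1; leftmost hit wins, so
ties are deterministic). The sample index and the clone barcode are then
sliced at configured sides/offsets relative to the anchor. Barcodes and
indexes are read off exactly — no error correction — because library
barcodes are known and well separated, and correction would silently alter
counts. Reads are processed on the sequencing strand as-is; coordinates are
0-based half-open throughout. Every read is either counted or tallied under
exactly one rejection reason (`no-anchor`, `truncated`, `ambiguous-base`),
so accepted + rejected always equals reads processed. Base qualities are
never consulted.

The raw count table drops cells with fewer than 10 reads before any further
processing; such low counts are indistinguishable from index hopping and
PCR/sequencing artifacts.

## Plate decoding

Arrayed libraries are decoded positionally from one sequencing pool per row
(16) and per column (24) of each 384-well plate. A barcode is *called* in a
pool when its count reaches `min_reads` (presets 50 and 100; default 50). A
barcode called in row and column pools of one plate maps to their
intersection; barcodes with more than one matching (row, column) pair are
rejected as multimatches, wells claimed by more than one barcode reject all
claimants as collisions, and barcodes supported on only one axis remain
unassigned (dropout is symmetric, not an error). Pairs are never formed
across plates, since pools are made per plate. The assigned map is injective
in both directions by construction.

## Normalization and scores

Each plate/fraction sample is amplified with its own index, so sequencing
yield varies per sample; this is removed by scaling each sample's counts so
all per-sample medians equal the median of medians (multiplicative on raw
counts — equivalently an additive shift after log2). Factors whose raw
input counts fail `min_input` (default 10, the global floor) in more than
two replicates are removed whole: a missing input means the strain is absent
or its barcode failed to amplify, and any IP signal over it is
uninterpretable. Binding scores are per-replicate log2(IP) − log2(input) on
normalized counts, absent wherever either side is absent. Finally, replicate
score vectors are quantile-normalized (rank-mean, average-rank ties, missing
values excluded and preserved; unequal column sizes handled by interpolating
sorted vectors onto a common quantile grid) to equalise replicate dynamic
range. The stage is placeable on counts instead of scores via
`binding_scores(..., quantile_on=...)`; scores are the default because the
dynamic-range differences being corrected are differences between replicate
ChIP efficiencies, which act on the ratio scale. Loci are always processed
separately.

## Moderated statistics

Binder calling uses a one-sample empirical-Bayes moderated *t* on the
per-replicate log-ratios (equivalent to a paired IP-vs-input contrast, the
formulation with the fewest assumptions given that the reported quantity is
the average logFC of ChIP/input). The variance prior is a scaled inverse-χ²
with parameters fitted by moments on the log scale: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of the spread of e over
its χ² sampling component identifies d0 through ψ′(d0/2), solved by
monotone bisection on d0 ∈ [1e-4, 1e6] (tolerance 1e-8; ψ′ is strictly
decreasing, so bisection is safe; out-of-range targets give an infinite d0,
i.e. complete shrinkage to s0²). Note the zero-spread corner: if the input
variances are *literally* identical the fit still applies the log-χ²
unbiasing correction, so s0² = exp(ē) rather than the common value — the
degenerate input is off-model; with genuine sampling noise around a common
variance the fit recovers that variance (both behaviours are tested, and
the whole test matches the reference Bioconductor implementation to ~1e-9
on shared inputs). p-values are two-sided — significant depletions are
biologically unexpected and their scarcity is itself a useful negative
control — with t(d0 + d_g) reference (normal at infinite d0), adjusted by
Benjamini–Hochberg; binders require strictly positive logFC and FDR < 0.01.

Condition contrasts (e.g. replication-stress vs untreated, 3 + 3
replicates) first restrict to the union of binders of the two conditions at
FDR < 0.05 — factors bound in neither condition have no interpretable
difference — then apply a two-sample moderated *t* with pooled
within-condition variance (df n_A + n_B − 2) and a prior re-estimated on
the restricted set, with BH within that set and significance at FDR < 0.05.
Factors tested at several loci keep independent per-locus results; priors
are never pooled across loci.

## Enrichment analyses

Term over-representation among binders uses the one-sided Fisher exact test
(hypergeometric upper tail) against the screen's own universe. The packaged
four-category scheme (DNA binding > RNA binding or processing > metabolism
> other, matched in that priority order) maps GO-slim process terms to
coarse functional classes; the term lists ship as package data and are
matched as exact strings against the user-supplied GO-slim collection, so
no live ontology access is needed.

Locus preference is summarised by a weighted KS running-sum enrichment:
binders are ranked by the difference of their two locus scores (descending,
name-stable ties), in-set positions add |metric|^exponent normalized by the
in-set total, out-of-set positions subtract 1/(N − n_set), and the score is
the maximum signed excursion. The exponent defaults to 1 (metric-weighted,
the common default of running-sum scoring), with 0 available. The p-value
permutes set membership over the ranked factors (gene-label permutation),
p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1), 10,000 permutations by default with
a fixed seed — the permutation null is a documented choice, as is any
permutation scheme.

## Simulator

The generator emulates the screen's design so every stage can be tested
against known truth:

* **library** — `n_strains` (default 4,000, the scale of a tagged-protein
  library) with unique random barcodes per locus (collision after 100
  redraws aborts, signalling a too-short barcode), filling 384-well plates
  row-major; a strain is a binder with probability `frac_binders` (default
  0.12, the observed binder fraction at this locus class) and binders draw
  truncated-Normal(≥0) log2 effects per locus (defaults mean 1.0, sd 0.5,
  the scale seen on screen volcano plots);
* **counts** — input ~ NegBin(depth × abundance share, dispersion α), with
  log-normal abundance (σ = 0.5, a realistic strain-fitness spread) and
  depth default 1e6 reads/sample; IP ~ NegBin(input mean × 2^effect ×
  scale_r), with scale_r log-uniform in [0.5, 2] per IP sample to exercise
  median normalization. The gamma–Poisson (NegBin, variance μ + αμ²,
  α default 0.05) is a standard overdispersed sequencing model and reduces
  to Poisson at α = 0; no noise model is prescribed by the assay itself, so
  this is an explicit stand-in;
* **reads** — one read per count unit, index + anchor + barcode, i.i.d.
  substitutions at `error_rate` (default 0.001), constant quality "I"
  (extraction never uses quality); byte-identical given the seed;
* **pools** — per plate, 16 row and 24 column pools; each strain contributes
  Poisson(`depth_per_pool`) reads to each of its two pools
  (`depth_per_pool` is expected per-strain coverage within a pool), and is
  silently omitted from a pool with probability `dropout` to exercise the
  decoder's rejection logic.

All stages derive independent streams from one seed, so truth objects,
counts, reads and pools are individually and jointly reproducible.

What the simulator does **not** model: PCR jackpots and chimeras, paired-end
reads, position- or quality-dependent error profiles, index hopping,
barcode-specific amplification bias, and cross-contamination between wells.
Passing tests therefore demonstrate correctness of the decoding and
inference machinery under a clean generative model, not robustness to every
artifact of real libraries.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run at sizes chosen to make the
checks statistically meaningful while staying quick on one CPU: round trips
at 1,000 strains × 6 replicates (≈230k reads), decode recovery on one full
384-well plate at 500× per-strain pool coverage, calibration on 20 null
screens of 4,000 factors × 6 replicates at 1e6 reads/sample, prior recovery
at G = 5,000, oracle sweeps over 1,000 random p-vectors and all 2×2 tables
with margins ≤ 12, and power runs with ~200 planted binders (log2 effect
1.0) among 4,000 factors. Monte-Carlo assertions use 3–4 SD bands;
deterministic oracle comparisons use absolute tolerances ≤ 1e-9.

Degenerate inputs are handled explicitly: empty FASTQ → empty matrix;
all-absent samples, unpaired IP/input, all-zero variances, out-of-range
p-values, gene sets disjoint from or covering the whole ranking → errors
(or warnings where the condition is survivable), never silent results.

## Known limitations

* The low-input filter threshold ("low input counts") is not prescribed by
  the assay; the default reuses the global count floor (10) in ≥ n−2
  replicates and both knobs are exposed.
* Whether quantile normalization acts on counts or on ratio scores is a
  genuine design fork; both are implemented, scores being the default (see
  above).
* The moderated-model form (one-sample on ratios vs a two-coefficient
  channel model) is an assumption matched to the reported outputs.
* Decoding performs no barcode error correction; pool counts feeding the
  decoder inherit the extraction's exact-match policy.
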