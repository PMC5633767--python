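# Methods

`hexamap` detects and genetically maps structural rearrangements —
segmental deletions, duplications and homoeologous exchanges (HEs) — in an
allopolyploid crop genome with two subgenomes (A and C, as in *Brassica
napus*), and links them to quantitative trait variation in doubled-haploid
(DH) mapping populations.  This note documents the models, the parameters
that matter, the numerical choices, and what the bundled simulator does and
does not emulate.

## The inference problem

An HE replaces a chromosome segment by the homoeologous segment of the
other subgenome.  Its signature is double: in parental whole-genome
sequencing the lost interval shows depressed read depth and the
homoeologous gained interval elevated depth; on a SNP array the markers in
the lost interval stop hybridizing on the carrier haplotype
(presence–absence, "PA"), while markers in the gained interval pick up an
extra, variant copy and read heterozygous in fully homozygous carriers
(hemi-SNP, "het").  Neither evidence stream alone is conclusive — depth
segments cannot see which haplotype travels with which, marker patterns
can be technical artifacts — so events are called by reconciling the two.

## Read-depth segmentation (`coverage`)

* **Binning.** Median depth over fixed 1000-bp bins; a bin's value is the
  median over its covered positions only, bins with no data are gap bins.
  Weighted medians use the even-count midpoint-average convention.
* **Segmentation.** Circular binary segmentation, re-implemented: on each
  (sub)segment of n bins, find the arc [i, j) maximizing the two-sample
  t-statistic between arc and complement.  We maximize the between-group
  sum of squares B(i, j) = (A − kμ)² · n / (k(n−k)) (A = arc sum, k = arc
  width), which is a monotone transform of t² at fixed total SS and hence
  permutation-equivalent; enumerating all non-wrap arcs covers the circular
  complement case by symmetry.  Significance is a sequential permutation
  test (default α = 0.01, up to 1000 permutations): permutations run in
  batches and stop early either when the final p-value is already certain
  to exceed α, or when the running estimate (1+e)/(1+m) certifies p ≤ α
  (earliest possible at ⌈1/α⌉ permutations).  Accepted arcs contribute up
  to two breakpoints; recursion continues on the sub-segments.  Arc widths
  are bounded below by `min_width_bins` (default 3).  Gap bins break the
  track into independently segmented stretches and are excluded from all
  statistics.
* **Merging / filtering.** Adjacent segments merge when their means differ
  by at most 10% of the chromosome mean ("the same mean", made operational
  for noisy means) and the intervening gap is at most 50 kb; segments
  shorter than 50 kb are absorbed into the nearest mean-compatible
  neighbour or dropped.  All reported segments are ≥ 50 kb.
* **Boundary refinement.** Merging can absorb a short transition segment
  into the wrong neighbour and drag a boundary by several bins, so each
  boundary between coordinate-adjacent segments is re-fit by exact
  single-changepoint maximum likelihood (minimum residual sum of squares)
  within a ±25-bin window, never crossing a segment midpoint.
* **Classification.** Per-chromosome mean μ and *population* SD s over
  non-gap bins (population SD keeps classification deterministic); segment
  mean > μ + k·s ⇒ duplication, < μ − k·s ⇒ deletion, else normal
  (k = 1 by default).  On heavily rearranged chromosomes μ and s are
  themselves inflated by the events — a known bias of chromosome-mean
  normalization; a robust median/MAD mode is available (`ChromStats` can be
  built by the caller) but off by default for fidelity to the standard
  rule.

## Marker classification (`markers`)

Markers are anchored physically (filter: ≥ 50 bp overlap, ≥ 95% identity,
no alignment gaps, unique hit) and classified from the two parents plus the
DH lines:

* **simple** — parents AA vs BB, lines AA/BB; codominant.
* **het** — one parent AB, other homozygous; lines AB or that homozygote.
  AB is scored as the hemi-SNP parent's allele, which resolves the locus
  codominantly because DH lines are homozygous.
* **PA** — one parent no-call, called lines uniformly show the present
  parent's allele, NC fraction near 1:1 (window 0.3–0.7).  NC is scored as
  the null-allele parent (dominant scoring made fully informative by DH
  homozygosity).
* A parent NC with lines segregating two homozygous alleles near 1:1 and
  only sporadic NC is rescued as simple with an imputed parental call
  (flagged): repeated technical failure of a parent assay should not
  discard a clean codominant marker.

Tolerances: off-pattern calls up to 5% of lines are treated as technical
errors (set missing); sporadic NC up to 10%.  Every scored marker gets the
1:1 chi-square test χ² = (c₁−c₂)²/(c₁+c₂); markers failing the gate are
excluded from mapping.  **Gate level α = 0.01**, not 0.05: at n ≈ 164,
segregation drift along a chromosome is regionally correlated, and a 0.05
gate excludes whole stretches in roughly one chromosome in ten, splitting
otherwise intact linkage groups; 0.01 retains drifted regions while still
rejecting the strong distortion typical of unmappable rearranged loci.
Cosegregating markers are binned by strict scored-vector equality
(missing-as-wildcard matching is available but off by default because it is
not transitive; wildcard-binned members are flagged).

## Linkage mapping (`linkmap`)

Recombination fraction between bins: discordant / jointly-informative lines
(truncated at 0.5); in DH populations every class, including recoded PA
markers, is fully informative.  Groups are connected components of the
graph with edges r < 0.2 (pairs with fewer than 20 jointly informative
lines are non-edges).  Within-group ordering minimizes the sum of adjacent
r (TSP-path objective): exhaustive search up to 8 bins, otherwise greedy
nearest-neighbour from several starts plus 2-opt, seeded.  This replaces
JoinMap-style ML ordering — a deliberate substitution, exact for small
groups and empirically order-accurate (Spearman ≥ 0.99 vs physical order on
the toy).  Groups are named by majority anchor chromosome and oriented so
anchor positions ascend.  Distances are Haldane, d = −50·ln(1−2r) cM,
consistent with the simulator's no-interference crossover model; a Kosambi
switch would only be meaningful with interference.

## Event calling (`hecall`)

Runs of ≥ 3 adjacent same-class PA or het markers on the map become
confident marker blocks; shorter runs are kept at single-marker confidence
rather than discarded, since isolated markers are occasionally the only
trace of an event.  Simple markers whose anchor chromosome differs from
their group's are translocated markers (duplicated copies mapping at the
homoeologous position).  Loss evidence (PA runs, deletion segments) and
gain evidence (het runs, translocated runs, duplication segments) are
clustered by physical overlap into loci; a loss locus whose homoeologous
image (piecewise-linear projection through the homoeology block table;
reversed blocks encode inversions) overlaps a gain locus with interval
Jaccard ≥ 0.25 is called an HE.  The 0.25 Jaccard is an explicit stand-in
for the qualitative "corresponding region" notion; results are insensitive
to it on the toy because true pairs overlap near-completely.  Unpaired
losses are deletions, unpaired gains duplications; same-chromosome
loss/gain contradictions are surfaced as `conflict` events, never silently
resolved.  Tiers: *validated* (marker block AND coverage segment agree),
*putative* (one evidence kind, run ≥ 3 or segment ≥ 50 kb),
*single-marker* otherwise.  This stage is deterministic.

## QTL scan (`qtl`)

Composite interval mapping is approximated by Haley–Knott regression:
expected P2 dosage at each 1-cM grid position is imputed from the nearest
informative flanking markers under Haldane transition probabilities (exact
0/1 at informative markers, 0.5 with no informative flank), and the
standardized phenotype is regressed on dosage plus forward-selected marker
cofactors (max 5, entry p < 0.001), excluding cofactors within ±10 cM of
the tested position.  LOD = (n/2)·log₁₀(RSS₀/RSS₁) against the
cofactors-only null; R² = 1 − RSS₁/RSS₀ at the peak.  QTL are local maxima
above LOD 5; two maxima are separate QTL only when parted by a valley
more than 2 LOD below the lower peak.  Support intervals are 1-LOD
(grid positions within 1 LOD of the peak).  A QTL is annotated with the
called rearrangement whose genetic span overlaps its support interval.
QGene-style exact CIM internals are not reproduced.

## The simulator (`genome`, `simulate`)

What it emulates: a two-subgenome toy genome whose A chromosomes are fully
tiled by co-linear homoeology blocks; non-overlapping parental deletions,
duplications and HEs (HE gains are the projected homoeologous images); DH
meiosis with Poisson crossovers (positions uniform, no interference),
Bernoulli start phase and chromosome doubling; array calls with the class
semantics above plus uniform miscall and missing noise (parents included);
negative-binomial per-bin read counts proportional to copy number; and an
additive single-QTL phenotype y = μ + a·carrier + N(0, σ²).

Key conventions and defaults:

* Parents and DH lines are homozygous: deletions are copy-number 0 in
  carriers and duplications +2 copies by default (`loss`/`gain`
  configurable to 1 for single-copy analyses).
* A rearranged interval travels as one haplotype: pairing is disturbed
  inside a structural heterozygote, so markers within an event's intervals
  read the event anchor's parental origin, and an HE's lost and gained
  intervals cosegregate perfectly.
* `decouple_at` models pairing disruption by a large parent-specific
  rearrangement: the two chromosome arms segregate independently, which
  reproduces the "one chromosome, two linkage groups" phenomenon.
* Depth: `mean_depth` is in reads per bin.  20× sequencing coverage with
  ~100-bp reads corresponds to ~200 reads per 1-kb bin (default 200);
  NB size defaults to the mean, i.e. variance ≈ 2× mean, a typical figure
  for binned WGS depth.
* Noise defaults: 2% missing calls, 0.5% miscalls.
* Crossovers: Poisson mean 1.5 per chromosome (≈ 150 cM genetic length).
* All stages draw seeds from one `SeedSequence`; outputs are bit-exact
  reproducible per seed.

Problem sizes: the default `GenomeConfig` is 2 homoeologous pairs × 20 Mb
with 164 lines and 50-kb marker spacing.  The test suite and the
acceptance script run the same population and marker densities on 1–3 Mb
chromosomes — the package's chosen desk-scale conditions; event sizes
(≥ 100 kb coverage events, ≥ 500 kb end-to-end events) and all
rule thresholds are unchanged, so per-event signal and noise are identical
to the larger genome.

What it does not emulate: read-level data (FASTQ/alignment), Infinium
intensity clusters (hemi-SNPs are emitted as AB calls — the array's raw
encoding of hemi-SNP classes is a modelling choice here), GC or
mappability bias in depth, crossover interference, segregation distortion
from selection, aneuploidy beyond the event model, and multi-locus or
epistatic trait architectures.  Passing tests therefore demonstrate
correctness of the algorithms under these idealized conditions, not
robustness to array-specific clustering artifacts or alignment-induced
depth structure in real data.

## Degenerate inputs and numerical conventions

Coordinates are 0-based half-open everywhere internally; BED/bedGraph
output follows UCSC conventions.  All-gap tracks segment to nothing (with
a warning); zero-variance segments never split; sd = 0 classification
falls back to strict inequality with a warning; adjacent recombination
fractions ≥ 0.5 raise rather than emit infinite distances; constant
phenotypes yield an all-zero LOD profile with a warning; ties in the arc
search resolve to the first maximum (fixed iteration order), making
segmentation deterministic given the seed.

## Known limitations

Chromosome-mean classification biases μ and s on heavily rearranged
chromosomes (keep each chromosome's rearranged fraction modest, or supply
robust stats).  The 1-SD rule cannot separate hemizygous from homozygous
deletions — segment means are reported so users can post-classify.
Grouping at rf 0.2 fragments maps when large excluded regions interrupt a
chromosome, as in real data.  The TSP ordering is a heuristic beyond 8
bins (2-opt local optimum from multiple starts).  Interval-Jaccard pairing
assumes the homoeology table is approximately co-linear per block.
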