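# Methods

This note documents the models, parameter choices and numerical decisions
behind `readermap`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and interval conventions

All coordinates are 0-based half-open (BED convention); GFF3 input is
converted on read (1-based inclusive → half-open). Book-ended intervals
merge — `[0,10)` and `[10,20)` union to `[0,20)` — mirroring standard
interval-union semantics and avoiding 1-bp artifacts. Strand is ignored in
every overlap computation (histone marks are unstranded); only promoter
windows are strand-aware, defaulting to `[TSS−1000, TSS+100)` along the
gene's strand (configurable; annotation tools differ and no single window
is canonical). A peak's *reference point* is its narrowPeak summit when
recorded, else its midpoint. Peaks are assigned to arm/center domain
classes by their midpoint: deterministic, and exactly count-conserving for
boundary-spanning peaks.

## Proximity significance (per-peak placement null)

For a query interval `q` of length `w` inside a domain segment
`[lo, hi)`, the null repositions `q` uniformly over all `hi−lo−w+1`
integer start positions within the segment, keeping the reference set
fixed. Distances are gaps between interval bounds; overlapping *or
book-ended* placements are at distance 0. The p-value is the exact
rational `#{placements with d ≤ d_obs} / #placements`, computed in closed
form as the measure of the union of per-reference windows
`[a−w−d, b+d]` intersected with the valid start range. Properties that
follow and are tested: p ∈ (0,1], p is monotone in the observed distance,
and p is stochastically ≥ uniform under the null (the statistic is
discrete, so the test is conservative). A chromosome with no references
yields p = 1 with a warning; no multiple-testing correction is applied
because the downstream rule thresholds raw p < 0.05, and the per-peak
table carries p so users can correct if they wish.

The null is confined to the query's own arm/center segment (the whole
chromosome for the unstratified mode) because every downstream analysis is
stratified by domain class; distances are still measured against all
references on the chromosome, so a reference just across a boundary is not
invisible. An observed placement that no in-segment placement can match
(possible only for boundary-straddling queries) is clamped to a count of
1, keeping p > 0.

## Signal correlation chain

Tracks are normalized to bins-per-million at 20-bp resolution (each bin's
mean per-base coverage, scaled so the genome-wide bin sum is 10⁶). Over
each merged-peak locus the 95th percentile of per-base signal is taken
with linear interpolation between order statistics — the common numerics
default, pinned for reproducibility. Signals are normalized as
`log2((s+ε)/(i+ε))` against the input track with pseudocount ε = 1
coverage unit (the zero-input behaviour is otherwise undefined; ε is a
config knob logged with every run), then standardized to Z-scores
(population SD). The log base only rescales values that the Z-score
removes; base 2 is pinned as cosmetic. Pearson matrices feed
complete-linkage hierarchical clustering on distance 1−r (scipy linkage;
deterministic for fixed input), exported as Newick with merge heights.

## Profile matrices and the heatmap criterion

Reference-point matrices span ±3000 bp in 20-bp bins (300 columns); bin
values are mean BPM signal, with windows clipped at chromosome edges
zero-padded and the row flagged. Optional smoothing is a centered moving
average over 60 bp (3 bins). Row clustering runs k-means for k = 1, 2, 3
(fixed seed, 10 restarts, rows scaled by their maximum so shape rather
than amplitude dominates); a clustering is *homogeneous* when every
cluster's mean pairwise cosine similarity of raw rows is ≥ θ_h = 0.8, and
the minimal homogeneous k is chosen. This operationalizes a visual
"no heterogeneity within clusters" judgement; θ_h is a config knob and the
per-k scores are returned.

A row is *covered* when its mean signal over the central ±500 bp exceeds
`background × 2`, with background the median genome-wide per-bin BPM value
(falling back to the mean for tracks whose median bin is zero, so the
threshold never degenerates). The pair-level heatmap-overlap flag fires
when ≥ 50% of rows are covered — a majority rule consistent with published
covered-target counts in this kind of analysis (e.g. ~85% of targets
covered for a prominent pair). Fold, core width and row fraction are all
exposed parameters.

## Graded occupancy

Grade = number of satisfied criteria among C1 `r ≥ 0.300`,
C2 `significant-overlap fraction ≥ 0.30`, C3 heatmap flag; both numeric
thresholds are inclusive, as printed in the scheme the classifier
implements. The count-of-criteria reading makes the grades mutually
exclusive and is the only self-consistent interpretation of
"grade 2 meets 2 of 3, grade 1 meets any"; zero-criteria pairs are
reported explicitly as grade 0 "none" instead of being dropped. Grades are
computed separately per domain class.

## Colocalization network

For every unordered factor pair both directional significant-overlap
fractions are computed; the edge weight is their **minimum**, which
penalizes the asymmetric case of a small peak set engulfed by a large one
(the source analysis describes weights as association specificity without
printing a formula; min is the conservative choice and both directions are
retained on the edge). Edges tier at weight ≥ 0.5 (strong) and ≥ 0.25
(moderate); below that the edge is omitted but nodes are kept. Communities
come from an in-package Louvain implementation (local moves in sorted node
order, exact-tie breaks from the seed, aggregation passes; modularity is
asserted non-decreasing per pass) with
`Q = Σ_c [W_c/W − (S_c/2W)²]` on edge weights. The implementation is
checked against exhaustive partition enumeration on a 6-node graph and
against networkx's modularity.

## ChIP QC

FRiP counts reads whose 5′ position lies inside any merged peak. The
cross-correlation profile correlates, per shift δ ∈ [0, max_shift], the +
strand 5′-occupancy vector with the − strand vector shifted left by δ
(binarized by default, per common practice; raw counts available),
averaged over chromosomes weighted by length. With background b = profile
minimum, fragment peak cc_frag = maximum outside the phantom exclusion
zone (read length ± 10 bp) and phantom value cc_read = profile at the read
length: `NSC = cc_frag / b` and `RSC = (cc_frag − b)/(cc_read − b)` — the
standard background-subtracted RSC; the plain ratio `cc_frag/cc_read` is
also reported since prose definitions of RSC vary. A phantom value at
background yields RSC = +∞ with a warning rather than an error.

## Synthetic-data generator

The generator's defaults describe a small nematode-like study system:
five 2-Mb chromosomes, arms = outer 25% per side (so arms and centers each
cover half the genome); heterochromatin marks as Poisson-placed domains at
2.5×10⁻⁵ per arm bp vs 10× fewer in centers, lengths log-normal
(median 800 bp, σ = 0.5) — dispersed small domains covering a few percent
of arms, sparse enough that overlapping a domain is individually
significant under the placement null; euchromatin marks at promoters
(H3K4me3) or gene bodies (H3K36me3/H3K79me3) of active genes, genes
center-biased (80%), half active with FPKM ≥ 1; repeats arm-biased;
reader peaks log-normal (median 300 bp, consistent with narrow
chromodomain-factor peaks) with summits recorded. Coupling is
*placement-based*: with probability θ a peak centers uniformly inside a
random target-mark domain, else uniformly in the genome — this induces all
three grading criteria simultaneously and has closed-form expectations
(expected in-mark fraction θ + (1−θ)·mark genome fraction) used in tests.
Tracks are per-base indicators × depth 20 plus per-bin Poisson noise
(rate 1/bp), so background bins are positive and the coverage-call
median is well defined.

Randomness uses one master seed expanded into an independent CRC32-keyed
stream per sub-generator, so adding a reader never perturbs mark placement
and the θ-grid can share one genome per seed.

Read simulation: ChIP fragments (length 200, read length 50) pile at peak
reference points with Gaussian jitter (σ = 30 bp); each fragment emits its
left-end + read and right-end − read independently with probability 0.5.
Background and input reads are *single-end* draws from a block-wise
log-normal intensity field (10–20-kb blocks, σ = 1.2) rather than a flat
uniform: real libraries share regional coverage structure (accessibility,
mappability) between strands, which is what gives an input library its
flat, positive cross-correlation baseline and hence NSC ≈ 1. Independent
uniform background would make the profile fluctuate around zero and the
NSC ratio meaningless — the field is the minimal structure that makes the
QC metrics behave as they do on real data. A 1% `phantom_rate` duplicates
+ reads onto the − strand at read-length offset, modeling the mapping
artifact behind the phantom peak so RSC has a finite denominator.

**What passing synthetic tests show, and what they do not.** The generator
exercises every code path with known truth: domain stratification, exact
p-values, correlation recovery, coverage calls, grading monotonicity in θ,
community recovery and QC metric recovery. It does not model genomic
sequence, mappability bias, replicate structure, antibody efficiency
differences, broad-vs-narrow peak callers or inter-mark correlations
beyond gene activity — so passing here demonstrates correctness of the
computations, not that any particular biological dataset will reach a
given grade.

## Problem sizes in the checked studies

The parameter-recovery study uses θ ∈ {0, 0.3, 0.6, 0.9} with 500-peak
readers on the 10-Mb genome over 20 seeds, sharing marks across θ within a
seed; monotonicity is asserted on the mean grade across the grid (seeds
are paired across θ, and per-seed monotonicity holds in practice, but the
mean is the stable statistic for a discrete 0–3 response). The QC study
uses a 1-Mb chromosome, a 150-peak reader at θ = 0.9, 100 fragments per
peak and 0.3 background reads per bp — sequencing depth (~0.45 reads/bp
total) in the range of typical invertebrate ChIP libraries, and enough
genome for the correlation estimator's noise (∝ 1/√L) to sit well below
the profile baseline. The null-calibration study draws 2000 uniform query
placements against 12 fixed references in a 100-kb domain.

## Known limitations

- The proximity null treats references as fixed and the query as the only
  random element; reciprocal tests are computed by swapping roles, not by
  a joint null.
- `ColocEdge` weights from peak sets of very different sizes are dominated
  by the smaller set's fraction (by design of `min`); interpret isolated
  nodes accordingly.
- The percentile extractor expands per-base values per locus; it is meant
  for peak-scale loci (10²–10⁴ bp), not whole-chromosome windows.
- bigWig input is not supported; tracks are read and written as bedGraph
  text.
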