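# readermap

Association mapping of chromatin **reader** proteins (chromodomain factors
and friends) onto **histone-modification landscapes**, from ChIP-seq peak
sets and signal tracks.

Histone marks such as H3K9me2/3 and H3K27me3 label heterochromatin —
in nematodes concentrated as dispersed small domains on chromosome *arms* —
while H3K4me3, H3K36me3 and H3K79me3 label euchromatin at the promoters and
bodies of active genes in chromosome *centers*. Reader proteins bind these
marks, and a recurring analysis task is to decide, for every (reader, mark)
pair and separately per arm/center domain class, **how strongly the
reader's binding sites track the mark** — and then to organise many factors
into a colocalization network.

`readermap` implements that analysis as a tested, reusable library plus CLI:

- **Interval layer** — BED6/narrowPeak/BED12/GFF3-lite/bedGraph readers,
  interval merging, arm/center partitioning, genomic-feature and
  repeat-family annotation, active/silent gene calls (FPKM ≥ 1 with a
  euchromatin mark vs FPKM < 1 with a heterochromatin mark).
- **Proximity significance** — for each query peak, the exact probability
  under uniform placement within its arm/center segment of lying at least
  as close to the nearest reference peak as observed:
  `p = #{placements with d ≤ d_obs} / #placements`, thresholded at
  p < 0.05; the significantly-overlapping fraction feeds the grading and
  the network.
- **Signal correlation** — bins-per-million (BPM) normalization, 95th
  percentile signal over merged peaks, input normalization,
  log₂-transform, Z-scoring, Pearson matrix, complete-linkage clustering.
- **Profile matrices** — reference-point matrices (±3 kb, 20-bp bins),
  minimal-k k-means with a homogeneity rule, and per-row "covered by mark"
  calls giving the heatmap-overlap flag.
- **Graded occupancy** — the three-criterion classifier:
  C1 `r ≥ 0.300`, C2 `significant-overlap fraction ≥ 30%`, C3 heatmap
  overlap detected; grade = number of satisfied criteria
  (3 = prominent, 2 = detectable, 1 = weak, 0 = none).
- **Colocalization network** — pairwise directional overlap fractions,
  edge weight = min of the two directions, strong/moderate tiers, and
  Louvain community detection with modularity
  `Q = Σ_c [W_c/W − (S_c/2W)²]`.
- **ChIP QC** — FRiP, strand cross-correlation profile, fragment-length
  estimate, NSC and RSC.
- **Synthetic data** — a generator for domain-structured genomes with
  marks, readers coupled at tunable strength θ, stranded reads and a
  ground-truth manifest, so the whole pipeline is testable offline.

## Worked example

Simulate a five-chromosome 10-Mb genome carrying the six-mark panel and a
reader coupled to H3K9me2 at θ = 0.9, then grade the pair on chromosome
arms (correlation over merged peaks, exact proximity p-values, profile
coverage call):

```python
from readermap import SyntheticConfig, simulate_bundle, grade_bundle_pair

bundle = simulate_bundle(SyntheticConfig(seed=1))
print(grade_bundle_pair(bundle, "reader1", "H3K9me2"))
```

```
AssociationResult(reader='reader1', mark='H3K9me2', domain_class='arm',
                  r=0.8173285531987274, sig_fraction=0.9303370786516854,
                  heatmap_flag=True, grade=3, label='prominent')
```

The planted coupling (ground truth: 88.4% of reader peaks inside H3K9me2
domains) is recovered as a grade 3 "prominent" association: the percentile
signals correlate at r = 0.82, 93% of arm peaks are significantly close to
a mark domain (p < 0.05 under the placement null), and the profile-matrix
coverage call fires. An uncoupled reader (θ = 0) grades 0–1 on the same
genome.

The classifier alone is available from the shell; given a pair whose three
criterion values are r = 0.333, significant-overlap fraction 44.3% and a
detected heatmap overlap:

```bash
$ readermap grade --r 0.333 --sig-fraction 0.443 --heatmap
{"grade": 3, "label": "prominent"}
```

Other subcommands (`simulate`, `partition`, `overlap`, `correlate`,
`matrix`, `network`, `qc`, `annotate`, `run-all`) expose the remaining
stages; `run-all` drives the full pipeline from a JSON manifest and writes
per-stage TSVs plus a deterministic `summary.json` embedding the resolved
parameter set and its hash.

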