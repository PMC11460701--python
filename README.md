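# flexiscan

Detection and characterization of **full-length excised linear intron (FLEXI)
RNAs** from paired-end RNA-seq alignments.

Short spliceosomal introns (≤300 nt) can persist after splicing as stable,
full-length linear RNAs. In end-to-end sequencing protocols they appear as
columns of continuous read pairs whose fragment boundaries coincide with the
annotated splice sites, sometimes carrying short non-templated 3′ tails that
aligners soft-clip. `flexiscan` implements the complete analysis around this
read signature:

- **Catalog** — extract introns from a GTF as gaps between consecutive exons,
  deduplicate across isoforms, classify by size (short ≤ *t*, default
  *t* = 300 nt), and flag categories: embedded snoRNA/scaRNA (containment
  required), agotron, mirtron, shared splice site with a longer intron,
  annotated/in-frame retained intron, alternative splicing.
- **Detect** — a fragment (read-pair span, soft clips excluded) is a FLEXI
  read for intron *I* iff it is continuous (no spliced alignment) and
  |start − I.start| ≤ w and |end − I.end| ≤ w with w = 3 nt. Per intron:
  read counts, RPM (= reads / mapped fragments × 10⁶), end-offset and
  length-fraction histograms, exon-junction reads.
- **Features** — GC fraction; splice-site class (U2 GU-AG / U2 GC-AG /
  U12 GU-AG / U12 AU-AC / non-canonical, with a U12 5′SS position-weight
  matrix deciding GU-AG minor-class introns); branch-point PWM scan within
  40 nt of the 3′ end; consensus frequency tables; minimum free energy via a
  pluggable backend (RNAfold adapter, or a built-in base-pair-maximization
  stub for dependency-free testing); mean per-base conservation.
- **RBP** — intersect eCLIP/PAR-CLIP-style binding-site BED intervals with
  introns (≥1 nt, same strand; multiple sites of one RBP collapse to one
  presence); rank RBPs by number of bound FLEXIs (≥30 cut); site-midpoint
  densities over normalized intron position and I / SS-I / SS-E location
  classes; ≥95 %-length CLIP read enrichment; per-intron fragment merging.
- **Stats** — group-vs-group binding-site abundance comparisons with exact
  two-sided Fisher tests, Benjamini–Hochberg adjustment and ≥1 %/≥2 %
  abundance gates; two-sample Kolmogorov–Smirnov tests with a 1,000-replicate
  Monte-Carlo false-hit control (significance rejected when >5 % of
  size-matched random subsets also reach p < 0.01); host-gene category
  enrichment.
- **Cluster** — per-RBP FLEXI subsets key-coded over/under/ns against the
  background, Gower distance (mismatch fraction on categorical codes),
  complete-linkage hierarchical clustering, dendrogram cuts, and seeded
  random-subset re-clustering (2,000 introns × 10 repeats) for non-FLEXI
  intron classes.
- **Quantify** — copies-per-cell calibration by OLS of log₁₀(copies) on
  log₁₀(RPM) over sncRNA standards with 95 % prediction intervals;
  hypergeometric read down-sampling; Pearson correlations compared by
  Fisher's r-to-z; nuclear/cytoplasmic classification by size-factor
  normalized fold change > 1.5.
- **Simulate** — a synthetic-data generator (genome FASTA, GTF, coordinate-
  sorted SAM, RBP site BEDs, conservation bedGraph, copy-number standards)
  with complete ground truth and a self-audit pass, so every stage is
  testable offline.

## Worked example

The `analysis/` scripts run the full study on the bundled simulator
(`python analysis/01_simulate.py`, then 02…06), writing tables to
`results/`. On the default conditions (seed 7):

```
$ python analysis/02_detect_flexis.py
called 134 FLEXI introns (recall 1.000, precision 1.000)
exact-boundary reads (offset 0,0): 49.4%
FLEXI reads in the 90-100% length bin: 69.0%

$ python analysis/05_cluster_rbps.py
key-code matrix: 12 row RBPs x 24 columns
clusters (k=3) vs planted: ARI = 1.000
  cluster 1: PRPF8, SF3B4, SRSF1, U2AF2
  cluster 2: AGO1, AGO2, DICER, LARP4
  cluster 3: AATF, DKC1, NOLC1, SMNDC1
```

All 134 planted FLEXIs are recovered with no false calls; about half of the
FLEXI read pairs end exactly at both splice sites (the rest within the ±3 nt
window or in the simulated out-of-window tail); and the three planted RBP
co-enrichment clusters are recovered exactly (adjusted Rand index 1.0)
from the key-coded Fisher-test matrix.

Programmatic use mirrors the scripts:

```python
from flexiscan import annotations, detect

catalog = annotations.build_intron_catalog("annotation.gtf", short_threshold=300)
fragments = detect.fragments_from_alignments("sample.bam")
calls = detect.call_flexis(fragments, catalog, "sample1", end_window=3)
```

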