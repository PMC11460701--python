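# Methods

## The detection model

A FLEXI (full-length excised linear intron) is operationally defined on
paired-end alignments. Each properly paired primary read pair is reduced to a
*fragment*: the span from the leftmost to the rightmost aligned base of the
two mates, excluding soft-clipped bases. Soft clips are excluded because
end-to-end RNA-seq chemistry appends non-templated nucleotides to cDNA 3′
ends; counting them in the span would push genuine full-length reads outside
the calling window. A fragment is *continuous* when neither mate's alignment
contains a reference skip (CIGAR `N`).

A continuous fragment is a FLEXI read for catalog intron *I* iff

    |frag_start − I.start| ≤ w   and   |frag_end − I.end| ≤ w,

with window w = 3 nt by default. Offsets are recorded signed, negative =
inside the intron, positive = extending into the flanking exon (the rule
itself only uses the absolute values). All coordinates are 0-based half-open;
GTF input is converted on read, BED is native.

Rare fragments satisfying the rule for two introns (only possible for introns
closer than 2w) are assigned to the intron with the smaller total absolute
offset; exact ties are skipped with a warning. Only read pairs contribute;
unpaired reads are ignored. Every fragment overlapping an intron by ≥1 nt
counts toward that intron's total (the denominator of the full-length
fraction), and pairs with one mate fully inside the intron and the other
extending past a boundary are tallied as exon-junction reads. RPM uses all
primary properly paired fragments in the sample as denominator unless an
explicit total is supplied.

## Sequence features

- **Splice-site class.** Terminal dinucleotides split introns into AU-AC
  (minor spliceosome), GU-AG, GC-AG, and non-canonical. GU-AG introns are
  minor-class only when their first 12 nt score at least the threshold
  against the U12 5′ splice-site PWM; otherwise they are major-class. PWMs
  are log₂-odds against a uniform background, built from editable frequency
  TSVs shipped with the package (seeded from the published U2/U12 consensus);
  the default threshold is 60 % of the consensus sequence's own score. This
  replaces external motif-search tools so the package runs self-contained;
  the threshold is configurable because any fixed cut is a judgment call.
- **Branch point.** The best PWM position within the final 40 nt of the
  intron, excluding the last 3 nt (the 3′ splice site itself); ties resolve
  to the position closest to the 3′ end; below-threshold maxima return null.
- **Folding.** MFE is backend-pluggable. The default `StubFolder` is a
  Nussinov-style base-pair-maximization dynamic program (Watson–Crick pairs
  only, fixed −1 per pair, minimum loop 3), numba-compiled. It is explicitly
  **not thermodynamic**: scores are a structure-capacity proxy that keep the
  pipeline testable with no external folder. Restricting to Watson–Crick
  pairs preserves an exact symmetry under complement-and-reverse, which the
  tests exploit. An `RnaFoldBackend` adapter calls RNAfold when present. In
  the feature table MFE is computed for sequences up to 400 nt — the
  characterization targets short introns, and the cubic-time fold would
  otherwise dominate runtime on long introns.
- **Conservation.** The per-intron score is the arithmetic mean over all
  intron bases; positions absent from the bedGraph contribute 0 (the usual
  convention for missing conservation data); a chromosome absent from the
  track gives null.

## Binding-site statistics

Sites intersect introns on ≥1 nt same-strand overlap with no minimum
fraction; multiple sites of one RBP on one intron collapse to a single
presence, but all site midpoints are retained. Midpoints are expressed as
percent of intron length (mirrored on the minus strand), so values outside
[0, 100] mark sites extending into the exons.

The I / SS-I / SS-E location call codifies what is otherwise a visual read
of a density plot: a peak is a local maximum ≥ 0.5 × the global maximum of
the 2 %-binned midpoint density; a bimodal density with one peak within 15
percentage points of each splice site is SS-I when both peak midpoints lie
inside [0, 100] % and SS-E when both lie outside; everything else is
interior (I). Both parameters are exposed; with few sites spread over
variable intron lengths the fixed 0.5 peak criterion is conservative and
borderline bimodal profiles fall back to I.

Group-vs-group comparisons build one 2×2 table per RBP — (bound, unbound)
in group A vs group B, where group totals count *all* introns in the group,
not only those carrying sites — and use a two-sided Fisher exact test with
Benjamini–Hochberg adjustment across the RBPs of one comparison. An RBP is
keyed `over`/`under` only when it also passes the abundance gate: its share
of all collapsed site presences reaches ≥1 % (intron-class comparisons) or
≥2 % (subset/cluster analyses) in at least one group. Fisher p-values are
computed in-package from exact integer hypergeometric weights (the sum of
probabilities of all tables at most as probable as the observed one, ties
decided in exact arithmetic). This makes batch computation over many tables
fast and tie handling bit-reproducible; unit tests verify agreement with
both an independent exact-rational oracle and `scipy.stats.fisher_exact`.

The Kolmogorov–Smirnov subset test guards against small-sample artifacts
with a Monte-Carlo control: when a subset's two-sample KS p falls below 0.01,
1,000 size-matched random subsets are drawn (without replacement) from the
pool and tested against their complements; the original significance is
rejected as a false hit when more than 5 % of replicates also reach p < 0.01.
The subset is compared against its complement rather than the full pool
(the statistically standard construction; a `background="all"` switch gives
the inclusive variant).

## Co-enrichment clustering

Row RBPs (default: those with sites on ≥30 FLEXIs, minus an editable
core-spliceosome exclusion list) each define the subset of FLEXIs carrying
their site. For every column RBP the Fisher/BH/≥2 % machinery above keys the
cell over/under/ns. Gower's distance on purely categorical codes reduces to
the fraction of mismatching columns — over and under are deliberately
unordered categories with no partial credit, since the key codes carry no
metric. Complete-linkage agglomeration (scipy) builds the dendrogram; the
cluster count is a user parameter (default 6) because the reference analyses
cut the tree visually. For non-FLEXI intron classes the same procedure runs
on 2,000-intron random subsets, repeated 10 times, seeded; populations
smaller than the subset size fall back to a single full-set run.

## Quantification

Copies per cell come from ordinary least squares of log₁₀(copies) on
log₁₀(RPM) over sncRNA standards (≥3 required; nonpositive values dropped).
Intervals are 95 % *prediction* intervals (t-based, including the residual
variance), since single new RPM values are converted — a confidence-interval
switch exists for the regression-mean band. Down-sampling to match read
depths is a multivariate hypergeometric draw (without replacement), exactly
total-preserving and seeded. Abundance correlations use Pearson r on log₂
values and Fisher's r-to-z for comparisons.

Nuclear/cytoplasmic calls normalize the two count vectors by median-of-ratios
size factors (total-count fallback when <10 introns are nonzero in both
fractions), add a 0.5 pseudocount, and classify cytoplasmic when
fc = cyt/nuc > 1.5 and nuclear when 1/fc > 1.5 (strict, so swapping fractions
exactly swaps labels). This replaces a shrinkage-based differential test with
a transparent fold-change rule: no dispersion estimation is performed, and
the threshold itself (1.5) is kept.

## The synthetic-data generator

`simulate.SimConfig` defaults define the study conditions: ~60 genes × 3
introns on one chromosome with random strand; intron lengths 60–300 nt
(short) or 320–1,200 nt (long, 15 %); GU…AG ends with a branch-point
consensus planted 25 nt upstream of the 3′ end for major-class introns and
AU…AC ends for the 6 % minor-class introns; 85 % of short introns planted as
FLEXIs with 20–60 continuous read pairs each, end offsets drawn mostly at 0
(70 %) within ±3 nt plus a 10 % out-of-window tail, and 30 % of reads
carrying 1–3 nt soft-clipped 3′ tails; fragmented sub-intron pairs on the
remaining introns; exonic and exon-junction pairs; three 4-RBP co-enrichment
clusters planted on disjoint 40-intron subsets (site probability 1) over 12
background RBPs at 5 % site rate; a slope 1 / intercept 2 / sd 0.1 log-log
copy-number model over 12 standards; and a conservation track giving 20 % of
introns mean 0.9 and the rest 0.15. The generator self-audits every emitted
file against its ground truth before returning and is bit-reproducible per
seed.

What it deliberately does **not** emulate: sequencing errors and quality
strings, alignment ambiguity and multimapping, intron-lariat/circular forms,
expression dynamics, batch effects, or overlapping gene structures. Passing
tests therefore demonstrate correctness of the *computational* procedures
under a clean read model — boundary rules, statistics, recovery of planted
structure — not robustness to the full noise spectrum of real libraries.

## Numerical and design notes

- Catalog order is deterministic (sorted by coordinates); gene attribution
  for coordinate-identical introns from different genes is the
  lexicographically first gene id.
- "Alternatively spliced" is approximated as: absent from ≥1 overlapping
  transcript of the same gene.
- The in-frame retained-intron flag needs a CDS phase and genome sequence;
  without either it is null, never guessed.
- All randomness flows through `numpy.random.default_rng` seeds derived from
  one root seed; pipeline manifests record version, seed, thresholds, and
  sha256 checksums of every output table, and two runs with identical inputs
  are byte-identical.
- Analysis problem sizes (10,000-fragment detector comparisons, 1,000
  null-calibration replicates, 500 regression simulations, 20-seed cluster
  corruption) were chosen so the whole study reruns in about a minute on one
  CPU while keeping Monte-Carlo standard errors well inside the asserted
  margins.
- Known limitations: single-end libraries are not supported; the location
  classifier is a conservative surrogate for a visual call; the folding stub
  ranks structure capacity, not stability; Fisher tests treat introns as
  exchangeable units (no host-gene random effects).
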