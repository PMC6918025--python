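# Methods

## The inference problem

A pooled library of uniquely barcoded random T-DNA insertion mutants is grown
competitively on a carbon source; insertions in genes required for growth on
that source deplete relative to the neutral background. Counting barcodes
before and after growth therefore measures per-gene fitness genome-wide in a
single culture. In parallel, bulk RNA-seq on the same conditions measures
which genes are transcriptionally induced. The package implements both
readouts and their integration: a gene specifically induced on the target
sugar *and* specifically required for growth on it is a pathway candidate.

## Fitness model and statistics

**Strain scores.** For barcode *b*, raw score = log2((n·s + pc)/(n₀ + pc))
with pseudocount pc = 1 and s the ratio of time-zero to experimental library
size. The depth scaling removes sequencing-depth differences exactly for
large counts; the pseudocount bounds scores when either count is zero (a
zero/zero strain scores 0). Scores are then centred to zero mean per sample,
which presumes most insertions are neutral in any one condition — the
synthetic pools include intergenic insertions so this anchor is genuine.
Replicate *i* of a condition is paired with time-zero replicate *i*: each
pool aliquot carries its own reference.

**Gene aggregation.** All observations of a gene (barcodes × replicates)
pool into a single weighted mean with weights equal to the harmonic mean of
the pseudocounted depths, w = 2/(1/(n₀+pc) + 1/(n+pc)). The field describes
this step as a depth-weighted "harmonic mean" aggregation; a literal
harmonic mean of signed log-ratios is undefined whenever scores cross zero,
so the implemented reading is a weighted arithmetic mean of scores whose
weights are harmonic means of depths. This reproduces the intended behavior
(shallow observations are down-weighted) and is well defined everywhere.

**T-statistic.** T = fitness/√V with V = max(V_count, V_emp). V_count
propagates per-observation count noise through the log ratio by the delta
method (Var log2 X ≈ (1/ln2)²/X for Poisson X), giving a floor that prevents
a gene with one deep, lucky barcode from reaching huge T by chance agreement;
V_emp is the weighted variance of the observation scores around the gene mean
divided by the number of observations (m−1 denominator), capturing
inconsistency between barcodes and between replicates. A single-observation
gene has V_emp = 0 and relies on the count floor alone. |T| > 3 is the
conventional significance cut; it is a config default, not hard-coded.
Between-condition comparisons use rel = f_A − f_B and
rel_T = rel/√(V_A + V_B), treating conditions as independent.

**Degenerate inputs.** Zero variance (possible only with infinite counts)
reports T = 0 with a warning. Genes with no scored barcodes are absent from
the fitness table and flagged "not evaluable" in the integrated report rather
than silently dropped — in real libraries these are typically essential
genes.

## Insertion-to-gene assignment

An insertion is assigned to every gene whose full annotated span contains its
position; strand is ignored (a T-DNA insertion disrupts the locus regardless
of orientation), and insertions in overlapping genes count toward each. A
central-fraction option (e.g. keep only the middle 80% of the span) is
exposed for libraries where terminal insertions may retain function, but is
off by default: no such rule is assumed.

## Expression analysis

FPKM uses annotated transcript length and per-sample library size. The
differential test is a one-way ANOVA on log2(FPKM+1) across conditions: the
quadrant analysis consumes only condition means, fold changes and an
adjusted p-value, so a dispersion-modelling count test (DESeq2-style) is
deliberately not reimplemented here; the +1 offset bounds the transform at
zero counts. Genes with zero variance across all samples get p = 1. BH
adjustment gives q-values. The prefilter keeps genes with q < 0.05, maximum
condition-mean FPKM ≥ 5 and maximum pairwise fold change ≥ 2 (computed as
max-mean over min-mean; infinite when the minimum is zero). Retained genes
are clustered on 1 − Pearson correlation of their mean-FPKM profiles with
average linkage; the tree is cut at a fixed k (default 3, one cluster per
condition in the emulated design; height cutting is available through
scipy directly). Genes are sorted by id before linkage so the dendrogram,
and hence any tie resolution, is reproducible; labels are renumbered by
cluster size descending.

## Quadrant filter

Thresholds (FPKM > 5, fold ≥ 2, q < 0.05, relative fitness < −1, relative
T < −3) are compared against each reference condition separately and must
pass against all of them. The "2-fold depletion of mutants" phrasing and the
"relative fitness < −1" phrasing are treated as the same rule on the log2
scale. One published candidate gene (the glyceraldehyde reductase, printed
fitness −0.8 vs 0.0/0.1) does not satisfy the stated −1 cutoff as printed —
likely rounding or inclusion of additional low-sugar conditions in the
original call; this package applies the stated rule as written rather than
special-casing, so that gene fails `fitness_pass` on the printed values.

## Synthetic data: what it emulates and what it does not

The generators reproduce the study design: three carbon-source conditions
(d-galUA, d-glucose, glycerol), three biological replicates, growth for
g = 6 generations (midpoint of the typical 5–7 range), multinomial
sequencing at 10⁶ reads per sample, log-normal time-zero strain abundances
(σ = 1), ~3 barcoded insertions per gene plus 10% intergenic neutral
insertions, and negative-binomial RNA-seq counts (dispersion 0.05, log-normal
baseline with median 200 expected counts, σ = 1). Library complexity and
depth are desk-scale choices — a few hundred genes rather than a genome —
sized so that every statistical property under test (null calibration,
planted-effect recovery) is measured at the design's per-barcode depth of a
few hundred reads, which is what controls the statistics.

Selection acts multiplicatively: post-growth abundance ∝ a₀·2^(g·(1+f)), so
a rare strain with per-generation fitness f shows an expected raw log2 ratio
of about g·f against a mostly-neutral background. The generators do not
simulate PCR chimeras, barcode sequencing errors (beyond optional read
truncation), chromosomal-position effects, batch effects, or gene-length
biases in RNA-seq. Passing tests therefore demonstrate correctness and
calibration of the inference on an idealized screen, not robustness to
every artifact of real libraries.

## Kinetics

Absorbance slopes from NAD(P)H-linked assays convert to specific activities
via Beer–Lambert: |slope|/(ε·path) in mM/min, times reaction volume, to
nmol/s (nkat), per mg protein. ε defaults to 6.22 mM⁻¹cm⁻¹ (NADPH at
340 nm); path length is an explicit input because plate-well optical path
depends on fill volume, and whether initial-slope windows are used is the
caller's choice upstream. Michaelis–Menten parameters are fitted by direct
nonlinear least squares (not Lineweaver–Burk, which biases under additive
noise) with the deterministic initializer Vmax₀ = max(v), Km₀ = S at the
point nearest Vmax₀/2, bounded to the positive quadrant. Standard errors are
asymptotic (from the Jacobian); with ≥3 distinct concentrations spanning Km
the fit recovers noiseless parameters to machine-level precision.

## Numerical and design choices

- Pseudocount 1 throughout the fitness math; weights use raw (unscaled)
  counts, matching the "relative sequencing depth" reading.
- Mean (not median) centring for score normalization, as stated by the
  method description; with ≥90% neutral strains the two differ negligibly.
- Barcode-to-pool matching is exact; flank matching tolerance is
  configurable (default strict), reverse-complement scanning optional.
  Exactness keeps every read auditable: counted + unmapped + unextractable
  equals the read total per sample, always.
- All generators take their randomness from a single seed via independent
  named streams, so any stage is reproducible in isolation.

## Known limitations

- The ANOVA-on-log-FPKM test is anticonservative for very low counts and is
  not a substitute for count-based DE models when the goal is a calibrated
  genome-wide DE list; here it only feeds a coarse fold/significance filter.
- The T-statistic's variance floor is conservative by construction (max of
  two estimators), so per-gene p-values derived from it would not be
  uniform under the null; |T| > 3 is a screening rule, not an exact test.
- Gene fitness pools replicates and barcodes into one weighted mean;
  replicate-level gene scores can be had by passing single-replicate count
  matrices, but no replicate-variance decomposition is reported.
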