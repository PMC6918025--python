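# poolfit

Functional-genomics inference for carbon-utilization pathway discovery in
microbes, built around the design used to map d-galacturonic-acid (d-galUA)
catabolism in the oleaginous yeast *Rhodosporidium toruloides*: a pooled,
sequence-barcoded random insertional mutant library is grown competitively on
each carbon source and read out by barcode sequencing (BarSeq / RB-TDNA-seq),
in parallel with bulk RNA-seq on the same conditions. Genes that are both
transcriptionally induced on the target sugar and required for growth on it
are called pathway candidates.

The package is for computational biologists running (or simulating) such
screens: it takes barcode-bearing FASTQ reads or precomputed count tables and
produces gene-level fitness calls, expression tables, and the integrated
candidate report — plus a synthetic-data generator with planted ground truth
so the whole pipeline can be validated without any sequencing data, and a
small enzymology module for follow-up Michaelis–Menten characterization.

## The model

**Strain fitness.** For a barcoded insertion strain *b*, with count *n* after
growth and *n₀* in the time-zero reference (experimental library depth-scaled
to the time-zero library size, pseudocount 1):

    score_b = log2((n_b + 1) / (n0_b + 1))

Scores are centred to zero mean per sample — most insertions are neutral in
any one condition, so the pool average anchors zero. Scores are not divided
by the number of generations *g*; a strain with per-generation fitness *f*
depletes by roughly *g·f* log2 units.

**Gene fitness.** Strain scores are aggregated over all observations
(insertions × replicates) of a gene with weights
*wᵢ = 2 / (1/(n₀ᵢ+1) + 1/(nᵢ+1))* — the harmonic mean of the pseudocounted
depths, so poorly sequenced strains count less:

    fitness_g = Σ wᵢ·scoreᵢ / Σ wᵢ

**Consistency T-statistic.** Significance uses a variance floor: the larger
of the count-noise variance propagated from Poisson-level counting error,

    V_count = (1/ln2)² · Σ wᵢ²·(1/(n₀ᵢ+1) + 1/(nᵢ+1)) / (Σ wᵢ)²

and the empirical weighted variance of the gene's observation scores (the
disagreement between barcodes and between replicates). Then
*T = fitness / √max(V_count, V_emp)*, with |T| > 3 conventionally significant.

**Expression.** FPKM_gs = counts·10⁹/(libsize·length); genes are tested with
a one-way ANOVA on log2(FPKM+1) across conditions, BH-adjusted, filtered
(q < 0.05, max FPKM ≥ 5, max fold ≥ 2) and clustered on 1 − Pearson
correlation with average linkage.

**Quadrant filter.** A gene is a candidate for the target condition when,
against *every* reference condition, FPKM_target > 5 and
FPKM_target ≥ 2·FPKM_ref with q < 0.05 (induced), and relative fitness
< −1 with relative T < −3 (required). Applied to the published seven-gene
candidate table for d-galUA vs glycerol and d-glucose, the expression rule
passes exactly 7 genes.

## Worked example

Plant a four-gene pathway (50-fold induction, per-generation fitness −0.8 on
d-galUA) among 500 neutral genes, and run the whole pipeline:

```python
import pandas as pd
import poolfit as pf

pathway = ["g0010", "g0050", "g0200", "g0400"]
cfg = pf.SimConfig(
    n_genes=500,
    fitness_effects={g: {"dgalua": -0.8} for g in pathway},
    induced_genes={g: {"dgalua": 50.0} for g in pathway},
    seed=7,
)
pool, genes, truth = pf.simulate_pool(cfg)
t0, dg = pf.simulate_barseq_counts(pool, truth, "dgalua", cfg)
_, gly = pf.simulate_barseq_counts(pool, truth, "gly", cfg)
_, glc = pf.simulate_barseq_counts(pool, truth, "dglc", cfg)
gf = pf.fit_gene_fitness(pool, t0, {"dgalua": dg, "gly": gly, "dglc": glc})

counts, conds, _ = pf.simulate_rnaseq_counts(genes, cfg)
lengths = pd.Series({g.gene_id: g.length_nt for g in genes})
expr = pf.expression_table(counts, lengths, conds)

report = pf.candidate_table(expr, gf, "dgalua", ["gly", "dglc"])
print(report[["fitness_dgalua", "fitness_gly", "fitness_dglc",
              "rel_score_gly", "rel_t_gly"]].round(2))
```

```
         fitness_dgalua  fitness_gly  fitness_dglc  rel_score_gly  rel_t_gly
gene_id
g0010             -4.71        -0.03         -0.01          -4.68     -15.03
g0050             -4.77        -0.01         -0.01          -4.76     -41.93
g0200             -4.73         0.03          0.03          -4.76     -47.84
g0400             -4.72        -0.06         -0.07          -4.67     -34.68
```

Exactly the four planted genes are called. Their gene fitness on d-galUA is
about −4.7, matching the expectation *g·f = 6·(−0.8) = −4.8* for a rare
deleterious strain, while both reference conditions sit at zero; the
relative T-statistics are far past the −3 cutoff.

The kinetics module fits saturation data by direct nonlinear least squares:

```python
rates = pf.simulate_mm_assay(7.0, 553.0, [1, 2, 5, 10, 20, 50],
                             noise_sd=11.06, seed=5)   # 2% Vmax noise
fit = pf.fit_michaelis_menten(rates)
print(f"Km = {fit.km:.2f} +/- {fit.km_se:.2f} mM, "
      f"Vmax = {fit.vmax:.0f} +/- {fit.vmax_se:.0f} nkat/mg")
```

```
Km = 7.55 +/- 0.51 mM, Vmax = 569 +/- 13 nkat/mg
```

A command-line interface mirrors the library
(`poolfit count | fitness | expression | integrate | kinetics`); see
`poolfit --help`.

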