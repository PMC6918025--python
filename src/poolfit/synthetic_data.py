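"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline targets: a pooled,
sequence-barcoded random insertional mutant library grown competitively for
about six generations on each of three carbon sources, read out by barcode
sequencing; and a matching three-condition, three-replicate bulk RNA-seq
experiment with condition-specific induced gene sets.

Generative model for the pool: strain time-zero abundances are log-normal;
a strain carrying an insertion in a gene with per-generation fitness ``f``
(0 = neutral) changes abundance over ``g`` generations as

    a_end  proportional to  a_0 * 2**(g * (1 + f))

so that for a rare strain in a mostly-neutral pool the expected raw log2
count ratio is about ``g * f``.  Sequencing is multinomial at a fixed depth
per sample.  RNA-seq counts are negative binomial around
baseline * induced-fold means with a single global dispersion.

All generators are deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_counts import CountMatrix, FlankConfig
from .kinetics import michaelis_menten
from .pool_model import Gene, Insertion, InsertionPool, assign_insertions

#: Synthetic amplicon flanks (the architecture, not any real primer set).
DEFAULT_FLANKS = FlankConfig(
    pre_flank="GATGTCCACGAGGTCTCT",
    post_flank="CGTACGCTGCAGGTCGAC",
    barcode_length=20,
)

DEFAULT_CONDITIONS = ("dgalua", "dglc", "gly")

_GENE_LENGTH = 1500
_GENE_GAP = 500


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generators.

    Defaults mirror the emulated design: three carbon sources, three
    biological replicates, growth for 6 generations (midpoint of the 5-7
    range typical for these competitions), a desk-scale library of a few
    hundred genes with ~3 barcoded insertions each plus 10% intergenic
    (neutral-anchor) insertions, sequencing depth 1e6 reads per sample,
    log-normal time-zero abundance spread sigma = 1, and mildly
    overdispersed RNA-seq counts (dispersion 0.05).

    ``fitness_effects`` maps gene_id -> condition -> per-generation fitness
    (0 neutral, negative deleterious); ``induced_genes`` maps gene_id ->
    condition -> expression fold (>= 1).
    """

    n_genes: int = 500
    barcodes_per_gene_mean: float = 3.0
    intergenic_fraction: float = 0.1
    generations: float = 6.0
    depth_per_sample: int = 1_000_000
    n_replicates: int = 3
    conditions: tuple = DEFAULT_CONDITIONS
    fitness_effects: dict = field(default_factory=dict)
    induced_genes: dict = field(default_factory=dict)
    rnaseq_dispersion: float = 0.05
    rnaseq_baseline_median: float = 200.0
    rnaseq_baseline_sigma: float = 1.0
    abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.barcodes_per_gene_mean <= 0:
            raise ValueError("n_genes and barcodes_per_gene_mean must be positive")
        if not 0 <= self.intergenic_fraction <= 1:
            raise ValueError("intergenic_fraction must be in [0, 1]")
        if self.generations <= 0 or self.depth_per_sample < 1:
            raise ValueError("generations and depth_per_sample must be positive")
        if self.n_replicates < 1 or not self.conditions:
            raise ValueError("need >= 1 replicate and >= 1 condition")
        if self.rnaseq_dispersion < 0 or self.abundance_sigma <= 0:
            raise ValueError("dispersion must be >= 0 and abundance_sigma > 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        # distinct, reproducible stream per generator
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthTable:
    """Planted ground truth accompanying a synthetic dataset.

    ``fitness`` and ``expression_fold`` are gene -> condition maps (missing
    entries mean neutral / fold 1); ``abundance`` holds each barcode's true
    time-zero relative abundance (sums to 1).
    """

    fitness: dict = field(default_factory=dict)
    expression_fold: dict = field(default_factory=dict)
    abundance: dict = field(default_factory=dict)

    def fitness_of(self, gene_id: str, condition: str) -> float:
        return self.fitness.get(gene_id, {}).get(condition, 0.0)

    def fold_of(self, gene_id: str, condition: str) -> float:
        return self.expression_fold.get(gene_id, {}).get(condition, 1.0)


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            bc = "".join(bases[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_pool(
    config: SimConfig,
) -> tuple[InsertionPool, list[Gene], TruthTable]:
    """Generate a barcoded insertion pool over a synthetic genome.

    Genes are tiled without overlap on a single scaffold; each gene receives
    ``max(1, Poisson(barcodes_per_gene_mean))`` insertions placed uniformly
    within its span, and an ``intergenic_fraction`` of additional neutral
    insertions land in the gaps between genes.  Time-zero strain abundances
    are log-normal(0, abundance_sigma^2), normalized to sum to 1.
    """
    rng = config.rng(stream=1)
    scaffold = "scaffold_1"
    genes = []
    for i in range(config.n_genes):
        start = i * (_GENE_LENGTH + _GENE_GAP) + _GENE_GAP + 1
        genes.append(
            Gene(
                gene_id=f"g{i + 1:04d}",
                scaffold=scaffold,
                start=start,
                end=start + _GENE_LENGTH - 1,
                strand="+" if i % 2 == 0 else "-",
                length_nt=_GENE_LENGTH,
                description="synthetic gene",
            )
        )

    k_per_gene = np.maximum(
        1, rng.poisson(config.barcodes_per_gene_mean, size=config.n_genes)
    )
    n_genic = int(k_per_gene.sum())
    n_intergenic = int(round(config.intergenic_fraction * n_genic))
    barcodes = _random_barcodes(rng, n_genic + n_intergenic)

    insertions = []
    bi = 0
    for gene, k in zip(genes, k_per_gene):
        positions = rng.integers(gene.start, gene.end + 1, size=k)
        for pos in positions:
            insertions.append(
                Insertion(
                    barcode=barcodes[bi],
                    scaffold=scaffold,
                    position=int(pos),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            bi += 1
    for _ in range(n_intergenic):
        gap_idx = int(rng.integers(0, config.n_genes))
        gap_start = gap_idx * (_GENE_LENGTH + _GENE_GAP) + 1
        pos = int(rng.integers(gap_start, gap_start + _GENE_GAP))
        insertions.append(
            Insertion(
                barcode=barcodes[bi],
                scaffold=scaffold,
                position=pos,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        bi += 1

    pool = assign_insertions(
        InsertionPool(insertions, genome_name="synthetic"), genes
    )
    a0 = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(pool))
    a0 /= a0.sum()
    truth = TruthTable(
        fitness={g: dict(v) for g, v in config.fitness_effects.items()},
        expression_fold={g: dict(v) for g, v in config.induced_genes.items()},
        abundance=dict(zip(pool.barcodes, a0)),
    )
    return pool, genes, truth


def _barcode_fitness(
    pool: InsertionPool, truth: TruthTable, condition: str
) -> np.ndarray:
    effects = []
    for ins in pool:
        f = sum(
            truth.fitness_of(g, condition) for g in ins.assigned_genes
        )
        effects.append(f)
    return np.array(effects)


def simulate_barseq_counts(
    pool: InsertionPool,
    truth: TruthTable,
    condition: str,
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix]:
    """Simulate barcode counts before and after competitive growth.

    Post-growth abundance of barcode b is proportional to
    ``a0_b * 2**(g * (1 + f_true(gene(b), condition)))``; each replicate's
    time-zero and grown samples are independent multinomial draws of
    ``depth_per_sample`` reads.  Returns (time-zero matrix, condition
    matrix), each with one column per replicate.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition: {condition!r}")
    rng = config.rng(stream=2 + list(config.conditions).index(condition))
    barcodes = pool.barcodes
    a0 = np.array([truth.abundance[b] for b in barcodes])
    f = _barcode_fitness(pool, truth, condition)
    a_end = a0 * 2.0 ** (config.generations * (1.0 + f))
    a_end /= a_end.sum()

    t0_cols, cond_cols = {}, {}
    for rep in range(config.n_replicates):
        t0_cols[f"t0:{rep + 1}"] = rng.multinomial(config.depth_per_sample, a0)
        cond_cols[f"{condition}:{rep + 1}"] = rng.multinomial(
            config.depth_per_sample, a_end
        )
    t0 = CountMatrix(counts=pd.DataFrame(t0_cols, index=barcodes))
    cond = CountMatrix(counts=pd.DataFrame(cond_cols, index=barcodes))
    return t0, cond


def simulate_rnaseq_counts(
    genes: list[Gene],
    config: SimConfig,
) -> tuple[pd.DataFrame, dict, TruthTable]:
    """Simulate a genes-by-samples RNA-seq count matrix.

    Baseline per-gene expected counts are log-normal around
    ``rnaseq_baseline_median``; the mean under a condition is baseline times
    the planted induced fold; counts are negative binomial with global
    dispersion alpha (variance mu + alpha * mu^2), or Poisson when alpha=0.

    Returns (counts, sample -> condition map, truth with the planted folds).
    """
    rng = config.rng(stream=10)
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.lognormal(
        mean=np.log(config.rnaseq_baseline_median),
        sigma=config.rnaseq_baseline_sigma,
        size=len(gene_ids),
    )
    truth = TruthTable(
        expression_fold={g: dict(v) for g, v in config.induced_genes.items()}
    )

    cols = {}
    conditions = {}
    alpha = config.rnaseq_dispersion
    for cond in config.conditions:
        fold = np.array([truth.fold_of(g, cond) for g in gene_ids])
        mu = baseline * fold
        for rep in range(config.n_replicates):
            sample = f"{cond}:{rep + 1}"
            if alpha > 0:
                r = 1.0 / alpha
                p = r / (r + mu)
                counts = np.where(mu > 0, rng.negative_binomial(r, p), 0)
            else:
                counts = rng.poisson(mu)
            cols[sample] = counts
            conditions[sample] = cond
    counts = pd.DataFrame(cols, index=gene_ids)
    return counts, conditions, truth


def simulate_fastq(
    abundances: dict,
    depth: int,
    path,
    flanks: FlankConfig = DEFAULT_FLANKS,
    seed: int = 0,
    read_length: int | None = None,
    truncate_rate: float = 0.0,
) -> pd.Series:
    """Write a synthetic barcode-amplicon FASTQ and return the drawn counts.

    Each read is ``pre_flank + barcode + post_flank`` padded with A to
    ``read_length``; barcodes are drawn multinomially from ``abundances``
    (barcode -> relative abundance).  With ``truncate_rate``, a read is cut
    off just before the 3' flank (and is then unextractable).  Quality is
    constant.  Returns the realized per-barcode read counts.
    """
    rng = np.random.default_rng(seed)
    barcodes = list(abundances)
    probs = np.array([abundances[b] for b in barcodes], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(depth, probs) if depth > 0 else np.zeros(len(probs), int)

    full_len = len(flanks.pre_flank) + flanks.barcode_length + len(flanks.post_flank)
    if read_length is None:
        read_length = full_len
    if read_length < full_len:
        raise ValueError("read_length shorter than the amplicon architecture")

    reads = np.repeat(np.arange(len(barcodes)), counts)
    rng.shuffle(reads)
    truncated = rng.random(len(reads)) < truncate_rate
    with open(path, "w") as fh:
        for i, (bi, trunc) in enumerate(zip(reads, truncated)):
            seq = flanks.pre_flank + barcodes[bi]
            if not trunc:
                seq += flanks.post_flank
                seq += "A" * (read_length - len(seq))
            fh.write(f"@read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")
    return pd.Series(counts, index=barcodes)


def simulate_mm_assay(
    km: float,
    vmax: float,
    substrate_concs,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate a Michaelis-Menten rate table.

    v_i = Vmax * S_i / (Km + S_i) + Gaussian(0, noise_sd^2), truncated at 0.
    Returns a tidy table with columns S (mM), v (nkat/mg), replicate.
    """
    if km <= 0 or vmax <= 0:
        raise ValueError("Km and Vmax must be positive")
    rng = np.random.default_rng(seed)
    s = np.asarray(substrate_concs, dtype=float)
    rows = []
    for rep in range(1, n_replicates + 1):
        v = michaelis_menten(s, vmax, km)
        if noise_sd > 0:
            v = np.maximum(0.0, v + rng.normal(0.0, noise_sd, size=len(s)))
        rows.append(pd.DataFrame({"S": s, "v": v, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)
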