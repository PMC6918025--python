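"""Strain and gene fitness scoring for pooled barcoded mutant libraries.

The competitive-growth readout is a log2 ratio per barcoded strain: counts in
the experimental sample versus the time-zero reference, with the experimental
library depth-scaled to the time-zero library size and a pseudocount guarding
zeros.  Per-sample scores are centred to zero mean (most insertions are
neutral in any one condition, so the pool average anchors zero).

Strain scores are aggregated per gene as a weighted mean over all
observations (barcodes x replicates), each observation weighted by the
harmonic mean of its pseudocounted time-zero and experimental depths — deeply
sequenced strains are more reliable and count more.  Significance comes from
a consistency T-statistic: the gene score divided by the square root of a
variance that is the larger of

* a count-noise floor ``V_count`` propagated from Poisson-level counting
  error of each observation, and
* the empirical weighted variance of the gene's observation scores around
  their mean, ``V_emp``, which captures disagreement between barcodes and
  between replicates.

``|T| > 3`` is the conventional significance threshold.  Gene scores are not
scaled by the number of generations grown; a score of about ``g * f`` is
expected for a rare strain with per-generation fitness ``f`` after ``g``
generations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcode_counts import CountMatrix
from .pool_model import InsertionPool

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
#: |T| above this marks a significant fitness effect.
T_SIGNIFICANCE = 3.0

_LOG2_SQ_INV = 1.0 / math.log(2) ** 2  # (1/ln 2)^2, delta-method factor


@dataclass(frozen=True)
class GeneFitness:
    """Aggregated per-gene, per-condition fitness call."""

    gene_id: str
    condition: str
    fitness: float
    variance: float
    t: float
    n_barcodes: int
    n_observations: int


def strain_fitness(
    n0, n, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Raw per-strain fitness: log2((n*scale + pc) / (n0 + pc)).

    ``scale`` rescales the experimental sample to the time-zero library size
    so that differences in sequencing depth do not masquerade as fitness.
    Inputs are aligned count vectors over the same barcodes.
    """
    n0 = np.asarray(n0, dtype=float)
    n = np.asarray(n, dtype=float)
    if n0.shape != n.shape:
        raise ValueError(
            f"mismatched barcode sets: {n0.shape} time-zero vs {n.shape} sample"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    total_n = n.sum()
    scale = n0.sum() / total_n if total_n > 0 else 1.0
    return np.log2((n * scale + pseudocount) / (n0 + pseudocount))


def normalize_fitness(scores) -> np.ndarray:
    """Centre one sample's strain scores to zero mean."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to normalize")
    return scores - scores.mean()


def observation_weights(
    n0, n, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Harmonic mean of the pseudocounted time-zero and sample depths.

    Used to weight observations when aggregating to gene level: the weight is
    small whenever either count is small, i.e. whenever the log ratio is
    noisy.
    """
    n0 = np.asarray(n0, dtype=float) + pseudocount
    n = np.asarray(n, dtype=float) + pseudocount
    return 2.0 / (1.0 / n0 + 1.0 / n)


def build_observation_table(
    pool: InsertionPool,
    t0: CountMatrix,
    condition_counts: dict[str, CountMatrix],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-(barcode, replicate, condition) normalized scores and weights.

    ``t0`` and each condition matrix must share barcode rows and have the
    same number of replicate columns; replicate i of a condition is paired
    with time-zero replicate i (each pool aliquot carries its own reference).
    Scores are normalized to zero mean per sample over all pool barcodes,
    including intergenic ones, which anchor the neutral background.

    Returns a long DataFrame with columns barcode, gene_id, condition,
    replicate, n0, n, score, weight; barcodes without an assigned gene have
    gene_id NA (they participate in normalization but not in aggregation).
    """
    bc_to_genes = pool.barcode_to_genes()
    barcodes = t0.counts.index
    frames = []
    for condition, cm in condition_counts.items():
        if not cm.counts.index.equals(barcodes):
            raise ValueError(
                f"condition {condition}: barcode rows differ from time zero"
            )
        if cm.counts.shape[1] != t0.counts.shape[1]:
            raise ValueError(
                f"condition {condition}: replicate count differs from time zero"
            )
        for rep, (t0_col, col) in enumerate(
            zip(t0.counts.columns, cm.counts.columns)
        ):
            n0 = t0.counts[t0_col].to_numpy(dtype=float)
            n = cm.counts[col].to_numpy(dtype=float)
            score = normalize_fitness(strain_fitness(n0, n, pseudocount))
            weight = observation_weights(n0, n, pseudocount)
            frames.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "condition": condition,
                        "replicate": rep,
                        "n0": n0,
                        "n": n,
                        "score": score,
                        "weight": weight,
                    }
                )
            )
    obs = pd.concat(frames, ignore_index=True)
    # one row per (observation, assigned gene); multi-gene insertions
    # contribute to each gene they disrupt
    gene_lists = obs["barcode"].map(
        lambda b: sorted(bc_to_genes.get(b, ())) or [None]
    )
    obs = obs.loc[obs.index.repeat(gene_lists.str.len())].reset_index(drop=True)
    obs["gene_id"] = [g for genes in gene_lists for g in genes]
    return obs


def gene_fitness(
    observations: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Aggregate observation scores to per-gene, per-condition fitness calls.

    For each gene g and condition, over its observations i:

        fitness_g = sum(w_i * score_i) / sum(w_i)
        V_count   = (1/ln2)^2 * sum(w_i^2 * (1/(n0_i+pc) + 1/(n_i+pc)))
                    / (sum w_i)^2
        V_emp     = sum(w_i * (score_i - fitness_g)^2)
                    / (sum(w_i) * (m - 1))          for m >= 2, else 0
        t_g       = fitness_g / sqrt(max(V_count, V_emp))

    Genes with zero observations are simply absent from the output.
    """
    obs = observations.dropna(subset=["gene_id"])
    rows = []
    for (gene_id, condition), grp in obs.groupby(
        ["gene_id", "condition"], sort=True
    ):
        w = grp["weight"].to_numpy(dtype=float)
        s = grp["score"].to_numpy(dtype=float)
        n0 = grp["n0"].to_numpy(dtype=float)
        n = grp["n"].to_numpy(dtype=float)
        wsum = w.sum()
        fitness = float((w * s).sum() / wsum)
        inv_depth = 1.0 / (n0 + pseudocount) + 1.0 / (n + pseudocount)
        v_count = float(_LOG2_SQ_INV * (w**2 * inv_depth).sum() / wsum**2)
        m = len(grp)
        v_emp = (
            float((w * (s - fitness) ** 2).sum() / (wsum * (m - 1)))
            if m >= 2
            else 0.0
        )
        variance = max(v_count, v_emp)
        if variance == 0.0:
            logger.warning(
                "gene %s/%s: zero variance, reporting t=0", gene_id, condition
            )
            t = 0.0
        else:
            t = fitness / math.sqrt(variance)
        rows.append(
            (
                gene_id,
                condition,
                fitness,
                variance,
                t,
                grp["barcode"].nunique(),
                m,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "condition", "fitness", "variance", "t",
            "n_barcodes", "n_observations",
        ],
    )


def gene_t_statistic(
    observations: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Consistency T-statistic for one gene's observations (see gene_fitness)."""
    if len(observations) == 0:
        raise ValueError("gene has no observations")
    obs = observations.copy()
    obs["gene_id"] = obs.get("gene_id", "gene")
    obs["condition"] = obs.get("condition", "cond")
    return float(gene_fitness(obs, pseudocount)["t"].iloc[0])


def relative_fitness(
    gf_a: GeneFitness | pd.Series, gf_b: GeneFitness | pd.Series
) -> tuple[float, float]:
    """Between-condition relative fitness and relative T for one gene.

    rel_score = fitness_A - fitness_B;
    rel_t = (fitness_A - fitness_B) / sqrt(V_A + V_B).
    """
    get = lambda gf, f: getattr(gf, f) if hasattr(gf, f) else gf[f]
    if get(gf_a, "gene_id") != get(gf_b, "gene_id"):
        raise ValueError("relative fitness requires the same gene")
    if get(gf_a, "condition") == get(gf_b, "condition"):
        raise ValueError("relative fitness requires two different conditions")
    rel = get(gf_a, "fitness") - get(gf_b, "fitness")
    var = get(gf_a, "variance") + get(gf_b, "variance")
    rel_t = rel / math.sqrt(var) if var > 0 else 0.0
    return float(rel), float(rel_t)


def fit_gene_fitness(
    pool: InsertionPool,
    t0: CountMatrix,
    condition_counts: dict[str, CountMatrix],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Full fitness pipeline: counts -> normalized strain scores -> gene table.

    Returns a tidy DataFrame (gene_id, condition, fitness, variance, t,
    n_barcodes, n_observations), one row per gene x condition.
    """
    obs = build_observation_table(pool, t0, condition_counts, pseudocount)
    return gene_fitness(obs, pseudocount)


def write_gene_fitness(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_fitness(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
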