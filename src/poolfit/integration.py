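"""Expression-fitness quadrant analysis: candidate-gene calling.

A gene is called a candidate for utilization of the target carbon source when
it is both specifically induced on the target (FPKM above a floor, at least a
minimum fold above every reference condition, significant adjusted p) and
specifically required for growth on it (relative fitness below -1 and
relative T below -3 against every reference condition).  Requiring both data
types to agree discards transcriptional bystanders and pleiotropic growth
genes alike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the quadrant filter (all on the scales of the inputs).

    ``max_rel_fitness`` / ``max_rel_t`` are upper bounds on the relative
    fitness score and relative T-statistic (both negative: the mutant must
    do worse on the target).  A relative fitness below -1 corresponds to at
    least a 2-fold drop in mutant abundance on the log2 scale.
    """

    min_fpkm: float = 5.0
    min_fold: float = 2.0
    max_q: float = 0.05
    max_rel_fitness: float = -1.0
    max_rel_t: float = -3.0

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must be > 1")
        if self.max_rel_fitness >= 0 or self.max_rel_t >= 0:
            raise ValueError("max_rel_fitness and max_rel_t must be < 0")


def expression_pass(
    gene_row: pd.Series,
    target: str,
    references: list[str],
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """Target-specific induction test for one expression-table row.

    True iff q < max_q, the target condition mean FPKM exceeds min_fpkm, and
    the target mean is at least min_fold times every reference mean.
    """
    q = gene_row["q"]
    target_fpkm = gene_row[f"mean_{target}"]
    if not (q < thresholds.max_q and target_fpkm > thresholds.min_fpkm):
        return False
    return all(
        target_fpkm >= thresholds.min_fold * gene_row[f"mean_{ref}"]
        for ref in references
    )


def _fitness_lookup(gene_fitness: pd.DataFrame) -> pd.DataFrame:
    return gene_fitness.set_index(["gene_id", "condition"])


def fitness_pass(
    gene_rows: pd.DataFrame,
    target: str,
    references: list[str],
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """Target-specific fitness-requirement test for one gene.

    ``gene_rows`` holds that gene's per-condition fitness rows (columns
    condition, fitness, variance).  True iff against every reference the
    relative fitness is below max_rel_fitness and the relative T below
    max_rel_t.  Raises KeyError when a condition is missing; callers decide
    whether missing data means "not evaluable".
    """
    by_cond = gene_rows.set_index("condition")
    f_t = by_cond.loc[target, "fitness"]
    v_t = by_cond.loc[target, "variance"]
    for ref in references:
        f_r = by_cond.loc[ref, "fitness"]
        v_r = by_cond.loc[ref, "variance"]
        rel = f_t - f_r
        var = v_t + v_r
        rel_t = rel / math.sqrt(var) if var > 0 else 0.0
        if not (rel < thresholds.max_rel_fitness and rel_t < thresholds.max_rel_t):
            return False
    return True


def candidate_table(
    expression: pd.DataFrame,
    gene_fitness: pd.DataFrame,
    target: str,
    references: list[str],
    thresholds: FilterThresholds = FilterThresholds(),
    extended: bool = False,
) -> pd.DataFrame:
    """Candidate genes passing both the expression and the fitness filter.

    ``expression`` is an expression table (index gene_id, columns
    ``mean_<cond>``, ``q``); ``gene_fitness`` a tidy per-gene fitness table.
    The default output holds only passing genes; with ``extended=True`` every
    gene in the shared universe is reported with its per-filter flags, and
    genes lacking fitness data in some condition are flagged
    ``evaluable=False`` rather than silently dropped.

    Columns: per-condition mean FPKM and fitness, per-reference rel_score_*
    and rel_t_*, expression_pass, fitness_pass, evaluable, passes.
    """
    conditions = [target, *references]
    fit_wide_f = gene_fitness.pivot(
        index="gene_id", columns="condition", values="fitness"
    )
    fit_wide_v = gene_fitness.pivot(
        index="gene_id", columns="condition", values="variance"
    )
    universe = expression.index.intersection(fit_wide_f.index).sort_values()
    if len(universe) == 0:
        raise ValueError("expression and fitness tables share no genes")

    rows = []
    for gene in universe:
        expr_row = expression.loc[gene]
        rec: dict = {"gene_id": gene}
        for c in conditions:
            rec[f"fpkm_{c}"] = expr_row.get(f"mean_{c}", np.nan)
        rec["q"] = expr_row["q"]
        e_pass = expression_pass(expr_row, target, references, thresholds)
        evaluable = gene in fit_wide_f.index and not any(
            c not in fit_wide_f.columns or pd.isna(fit_wide_f.at[gene, c])
            for c in conditions
        )
        f_pass = False
        if evaluable:
            f_t = fit_wide_f.at[gene, target]
            v_t = fit_wide_v.at[gene, target]
            for c in conditions:
                rec[f"fitness_{c}"] = fit_wide_f.at[gene, c]
            f_pass = True
            for ref in references:
                rel = f_t - fit_wide_f.at[gene, ref]
                var = v_t + fit_wide_v.at[gene, ref]
                rel_t = rel / math.sqrt(var) if var > 0 else 0.0
                rec[f"rel_score_{ref}"] = rel
                rec[f"rel_t_{ref}"] = rel_t
                if not (
                    rel < thresholds.max_rel_fitness
                    and rel_t < thresholds.max_rel_t
                ):
                    f_pass = False
        else:
            logger.info("gene %s: missing fitness data, not evaluable", gene)
        rec["expression_pass"] = e_pass
        rec["fitness_pass"] = f_pass
        rec["evaluable"] = evaluable
        rec["passes"] = e_pass and f_pass
        rows.append(rec)

    report = pd.DataFrame(rows).set_index("gene_id")
    if extended:
        return report
    return report[report["passes"]]


def scatter_export(
    expression: pd.DataFrame,
    gene_fitness: pd.DataFrame,
    target: str,
    reference: str,
    thresholds: FilterThresholds = FilterThresholds(),
    expr_pseudo: float = 1.0,
) -> pd.DataFrame:
    """Per-gene coordinates for a relative fitness vs induction scatter plot.

    One row per gene with both data types: ``dlog2_expr`` =
    log2((FPKM_target + pseudo) / (FPKM_reference + pseudo)), ``dfitness`` =
    fitness_target - fitness_reference, ``rel_t``, and the two pass flags
    against this single reference.  All values finite.
    """
    fit_wide_f = gene_fitness.pivot(
        index="gene_id", columns="condition", values="fitness"
    )
    fit_wide_v = gene_fitness.pivot(
        index="gene_id", columns="condition", values="variance"
    )
    for c in (target, reference):
        if c not in fit_wide_f.columns:
            raise ValueError(f"condition {c!r} absent from fitness table")
    universe = expression.index.intersection(fit_wide_f.index).sort_values()
    ft = fit_wide_f.loc[universe, target]
    fr = fit_wide_f.loc[universe, reference]
    evaluable = ~(ft.isna() | fr.isna())
    universe = universe[evaluable]

    et = expression.loc[universe, f"mean_{target}"].astype(float)
    er = expression.loc[universe, f"mean_{reference}"].astype(float)
    dexpr = np.log2((et + expr_pseudo) / (er + expr_pseudo))
    dfit = fit_wide_f.loc[universe, target] - fit_wide_f.loc[universe, reference]
    var = fit_wide_v.loc[universe, target] + fit_wide_v.loc[universe, reference]
    rel_t = np.where(var > 0, dfit / np.sqrt(var), 0.0)
    q = expression.loc[universe, "q"].astype(float)

    out = pd.DataFrame(
        {
            "dlog2_expr": dexpr,
            "dfitness": dfit,
            "rel_t": rel_t,
            "expression_pass": (
                (q < thresholds.max_q)
                & (et > thresholds.min_fpkm)
                & (et >= thresholds.min_fold * er)
            ),
            "fitness_pass": (
                (dfit < thresholds.max_rel_fitness)
                & (rel_t < thresholds.max_rel_t)
            ),
        },
        index=universe,
    )
    return out
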