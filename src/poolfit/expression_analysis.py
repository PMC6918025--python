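"""FPKM expression tables, differential testing, and profile clustering.

Gene-level RNA-seq counts are converted to FPKM (fragments per kilobase of
transcript per million mapped reads), tested for differential expression
across conditions with a one-way ANOVA on log2(FPKM+1) followed by
Benjamini-Hochberg adjustment, filtered for expression level / fold change /
significance, and clustered by profile shape (1 - Pearson correlation
distance, average linkage).

The ANOVA is a deliberately simple test: the downstream quadrant analysis
only consumes condition means, fold changes and an adjusted p-value, so a
dispersion-modelling count test is not required here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_FPKM = 5.0
DEFAULT_MIN_FOLD = 2.0
DEFAULT_MAX_Q = 0.05
DEFAULT_K = 3


def fpkm(counts: pd.DataFrame, lengths: pd.Series, libsizes=None) -> pd.DataFrame:
    """FPKM matrix from a genes-by-samples count matrix.

    FPKM_gs = counts_gs * 1e9 / (libsize_s * length_g), with library sizes
    defaulting to column sums.  Every counted gene must have a length.
    """
    lengths = pd.Series(lengths)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(
            f"missing gene lengths for: {', '.join(map(str, missing[:5]))}"
        )
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1")
    if libsizes is None:
        libsizes = counts.sum(axis=0)
    libsizes = pd.Series(libsizes, index=counts.columns).astype(float)
    if (libsizes < 1).any():
        raise ValueError("library sizes must be >= 1")
    return counts.astype(float) * 1e9 / lengths.values[:, None] / libsizes.values


def condition_means(fpkm_matrix: pd.DataFrame, conditions: dict) -> pd.DataFrame:
    """Mean FPKM per condition (columns ordered by first appearance)."""
    cond = pd.Series({s: conditions[s] for s in fpkm_matrix.columns})
    order = list(dict.fromkeys(cond))
    return fpkm_matrix.T.groupby(cond).mean().T[order]


def max_fold_change(means: pd.DataFrame) -> pd.Series:
    """Largest pairwise fold change between condition means, per gene.

    Computed as max(mean)/min(mean); infinite when the minimum is zero and
    the maximum is not, NaN only if all means are zero.
    """
    hi = means.max(axis=1)
    lo = means.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = hi / lo
    fold[(hi == 0) & (lo == 0)] = np.nan
    return fold


def differential_test(fpkm_matrix: pd.DataFrame, conditions: dict) -> pd.Series:
    """One-way ANOVA p-value per gene on log2(FPKM+1) across conditions.

    Genes with zero variance across all samples get p = 1 by convention
    (no evidence of change).  Requires >= 2 conditions with >= 2 replicates.
    """
    cond = pd.Series({s: conditions[s] for s in fpkm_matrix.columns})
    groups = [
        np.log2(fpkm_matrix.loc[:, cond[cond == c].index].to_numpy() + 1.0)
        for c in dict.fromkeys(cond)
    ]
    if len(groups) < 2 or any(g.shape[1] < 2 for g in groups):
        raise ValueError("need >= 2 conditions with >= 2 replicates each")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.f_oneway(*groups, axis=1)
    p = pd.Series(p, index=fpkm_matrix.index)
    total_var = np.concatenate(groups, axis=1).var(axis=1)
    p[total_var == 0] = 1.0
    # within-group variance 0 but between-group signal: p -> 0
    p = p.fillna(0.0).clip(0.0, 1.0)
    p[total_var == 0] = 1.0
    return p


def bh_adjust(p) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = pd.Series(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.empty:
        return p
    _, q, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    return pd.Series(q, index=p.index)


def prefilter_genes(
    table: pd.DataFrame,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    min_fold: float = DEFAULT_MIN_FOLD,
    max_q: float = DEFAULT_MAX_Q,
) -> pd.Index:
    """Genes passing the differential-expression prefilter.

    Keeps genes with q < max_q, a maximum condition-mean FPKM of at least
    min_fpkm (drops uniformly low expression), and a maximum pairwise fold
    change of at least min_fold.  ``table`` is an expression table with
    ``q``, ``max_fold`` and ``mean_<condition>`` columns (see
    :func:`expression_table`).
    """
    mean_cols = [c for c in table.columns if c.startswith("mean_")]
    keep = (
        (table["q"] < max_q)
        & (table[mean_cols].max(axis=1) >= min_fpkm)
        & (table["max_fold"] >= min_fold)
    )
    return table.index[keep.fillna(False)]


def cluster_genes(fpkm_matrix: pd.DataFrame, k: int = DEFAULT_K) -> pd.Series:
    """Cluster gene expression profiles into k groups.

    Distance is 1 - Pearson correlation between gene profiles; linkage is
    average.  Labels are integers 1..k ordered by cluster size descending
    (ties broken by the lexicographically smallest member gene id), so label
    1 is always the largest cluster.  Zero-variance profiles are an error:
    filter first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = fpkm_matrix.sort_index().to_numpy(dtype=float)
    index = fpkm_matrix.index.sort_values()
    if (X.std(axis=1) == 0).any():
        bad = index[X.std(axis=1) == 0]
        raise ValueError(
            f"zero-variance profiles cannot be clustered: {list(bad[:5])}"
        )
    if len(index) <= k:
        raw = np.arange(1, len(index) + 1)
    else:
        dist = pdist(X, metric="correlation")
        Z = hierarchy.linkage(dist, method="average")
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=index, name="cluster")
    sizes = labels.value_counts()
    order = sorted(
        sizes.index,
        key=lambda c: (-sizes[c], min(labels.index[labels == c])),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(remap).reindex(fpkm_matrix.index)


def expression_table(
    counts: pd.DataFrame,
    lengths: pd.Series,
    conditions: dict,
    libsizes=None,
    k: int = DEFAULT_K,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    min_fold: float = DEFAULT_MIN_FOLD,
    max_q: float = DEFAULT_MAX_Q,
) -> pd.DataFrame:
    """Full expression pipeline: counts -> FPKM, means, test, filter, cluster.

    Returns one row per gene with per-condition mean FPKM (``mean_<cond>``),
    ``max_fold``, ``p``, ``q``, ``retained`` (prefilter outcome) and
    ``cluster`` (1..k for retained genes, NA otherwise).
    """
    fpkm_matrix = fpkm(counts, lengths, libsizes)
    means = condition_means(fpkm_matrix, conditions)
    table = means.add_prefix("mean_")
    table["max_fold"] = max_fold_change(means)
    table["p"] = differential_test(fpkm_matrix, conditions)
    table["q"] = bh_adjust(table["p"])
    retained = prefilter_genes(table, min_fpkm, min_fold, max_q)
    table["retained"] = table.index.isin(retained)
    table["cluster"] = pd.NA
    if len(retained) > 0:
        profile = means.loc[retained]
        nonzero_var = profile.std(axis=1) > 0
        if nonzero_var.any():
            labels = cluster_genes(profile.loc[nonzero_var], k)
            table.loc[labels.index, "cluster"] = labels
    return table


def write_expression_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
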