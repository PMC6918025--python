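import numpy as np
import pandas as pd
import pytest

import poolfit as pf


@pytest.fixture
def three_genes():
    return [
        pf.Gene("g1", "s1", 1000, 2000, "+", 1001, "toy"),
        pf.Gene("g2", "s1", 3000, 4000, "-", 1001, "toy"),
        pf.Gene("g3", "s2", 100, 700, "+", 601, "toy"),
    ]


@pytest.fixture
def small_pool(three_genes):
    insertions = [
        pf.Insertion("A" * 20, "s1", 1500, "+"),
        pf.Insertion("C" * 20, "s1", 2500, "+"),
        pf.Insertion("G" * 20, "s1", 3500, "-"),
        pf.Insertion("T" * 20, "s2", 300, "+"),
    ]
    return pf.assign_insertions(pf.InsertionPool(insertions), three_genes)


@pytest.fixture
def flanks():
    return pf.FlankConfig(pre_flank="ACGTACGTAC", post_flank="TTGGCCAATT")


def random_observation_table(rng, max_barcodes=10, max_count=10_000):
    """A random small per-observation table for oracle comparisons."""
    n_bc = int(rng.integers(1, max_barcodes + 1))
    n_rep = int(rng.integers(1, 4))
    n_genes = int(rng.integers(1, 4))
    gene_of = rng.integers(0, n_genes, size=n_bc)
    rows = []
    for rep in range(n_rep):
        n0 = rng.integers(0, max_count + 1, size=n_bc)
        n = rng.integers(0, max_count + 1, size=n_bc)
        rows.append((n0, n))
    return n_bc, n_rep, gene_of, rows
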