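"""Fitness math: hand-checked examples, invariants, and an independent oracle.

The oracle is a deliberately plain, loop-based reimplementation of the
scoring formulas (log2 ratio with depth scaling and pseudocount, per-sample
mean centring, harmonic-depth weights, weighted gene mean, count-noise /
empirical variance floor) kept free of any shared code with the package.
"""

import math

import numpy as np
import pandas as pd
import pytest

import poolfit as pf
from poolfit.fitness_analysis import observation_weights


# ---------------------------------------------------------------------------
# straight-line oracle
# ---------------------------------------------------------------------------

def oracle_sample_scores(n0, n, pc=1.0):
    scale = sum(n0) / sum(n) if sum(n) > 0 else 1.0
    raw = [math.log2((b * scale + pc) / (a + pc)) for a, b in zip(n0, n)]
    mean = sum(raw) / len(raw)
    return [s - mean for s in raw]


def oracle_gene_stats(observations, pc=1.0):
    """observations: list of (n0, n, score) for one gene. Returns (f, V, t)."""
    ws, ss = [], []
    for n0, n, score in observations:
        w = 2.0 / (1.0 / (n0 + pc) + 1.0 / (n + pc))
        ws.append(w)
        ss.append(score)
    wsum = sum(ws)
    fitness = sum(w * s for w, s in zip(ws, ss)) / wsum
    v_count = (
        (1.0 / math.log(2)) ** 2
        * sum(
            w * w * (1.0 / (n0 + pc) + 1.0 / (n + pc))
            for w, (n0, n, _) in zip(ws, observations)
        )
        / wsum**2
    )
    m = len(observations)
    if m >= 2:
        v_emp = sum(w * (s - fitness) ** 2 for w, s in zip(ws, ss)) / (
            wsum * (m - 1)
        )
    else:
        v_emp = 0.0
    v = max(v_count, v_emp)
    t = fitness / math.sqrt(v) if v > 0 else 0.0
    return fitness, v, t


# ---------------------------------------------------------------------------
# hand-checked worked examples
# ---------------------------------------------------------------------------

class TestStrainFitness:
    def test_equal_counts_equal_depth_score_zero(self):
        # two barcodes keep total depth equal on both sides
        s = pf.strain_fitness([100, 300], [100, 300])
        assert np.allclose(s, 0.0)

    def test_fourfold_increase(self):
        s = pf.strain_fitness([100, 300], [400, 0])
        assert s[0] == pytest.approx(math.log2(401 / 101), abs=1e-12)
        assert s[0] == pytest.approx(1.9893, abs=1e-4)

    def test_zero_counts_guarded_by_pseudocount(self):
        s = pf.strain_fitness([0, 10], [0, 10])
        assert np.isfinite(s).all()
        assert s[0] == pytest.approx(0.0)

    def test_depth_scaling_removes_library_size(self):
        n0 = np.array([500, 1500, 3000])
        n = np.array([500, 1500, 3000])
        deeper = pf.strain_fitness(n0, n * 10)
        assert np.allclose(deeper, 0.0, atol=0.01)  # pseudocount-level residue

    def test_mismatched_sets_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            pf.strain_fitness([1, 2], [1, 2, 3])


class TestNormalizeFitness:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([1.0, -1.0, 0.0], [1.0, -1.0, 0.0]),
            ([2.0, 2.0, 2.0], [0.0, 0.0, 0.0]),
            (
                [1.9893, 0.0, -1.9577],
                [1.97877, -0.01053, -1.96823],
            ),
        ],
    )
    def test_hand_examples(self, scores, expected):
        assert np.allclose(pf.normalize_fitness(scores), expected, atol=1e-4)

    def test_post_normalization_mean_is_zero(self):
        rng = np.random.default_rng(0)
        s = pf.normalize_fitness(rng.normal(size=1000) * 5)
        assert abs(s.mean()) < 1e-12


def _obs_frame(n0, n, scores=None, gene="g", pc=1.0):
    n0 = np.asarray(n0, float)
    n = np.asarray(n, float)
    if scores is None:
        scores = np.log2((n + pc) / (n0 + pc))
    return pd.DataFrame(
        {
            "barcode": [f"b{i}" for i in range(len(n0))],
            "gene_id": gene,
            "condition": "c",
            "replicate": 0,
            "n0": n0,
            "n": n,
            "score": scores,
            "weight": observation_weights(n0, n, pc),
        }
    )


class TestGeneFitness:
    def test_single_barcode_equals_strain_score(self):
        obs = _obs_frame([100], [400])
        gf = pf.gene_fitness(obs)
        assert gf["fitness"].iloc[0] == pytest.approx(math.log2(401 / 101))
        assert gf["n_barcodes"].iloc[0] == 1

    def test_equal_weights_give_arithmetic_mean(self):
        obs = _obs_frame([100, 100], [100, 100], scores=[2.0, 0.0])
        assert pf.gene_fitness(obs)["fitness"].iloc[0] == pytest.approx(1.0)

    def test_two_barcode_hand_example(self):
        # weights (161.36, 41.35), scores (1.9893, -1.9577) -> 1.184
        obs = _obs_frame([100, 100], [400, 25])
        gf = pf.gene_fitness(obs)
        assert np.allclose(obs["weight"], [161.356, 41.355], atol=1e-2)
        assert gf["fitness"].iloc[0] == pytest.approx(1.184, abs=1e-3)

    def test_weighted_mean_containment(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n0 = rng.integers(0, 1000, size=6)
            n = rng.integers(0, 1000, size=6)
            obs = _obs_frame(n0, n)
            f = pf.gene_fitness(obs)["fitness"].iloc[0]
            assert obs["score"].min() - 1e-12 <= f <= obs["score"].max() + 1e-12


class TestGeneTStatistic:
    def test_all_zero_scores_give_t_zero(self):
        obs = _obs_frame([100, 200], [100, 200], scores=[0.0, 0.0])
        assert pf.gene_fitness(obs)["t"].iloc[0] == 0.0

    def test_single_deep_barcode_hand_example(self):
        # fitness -3.0015, V_count = 2.0814*(1/1001 + 1/125) -> t ~ -21.9
        obs = _obs_frame([1000], [124])
        gf = pf.gene_fitness(obs)
        assert gf["fitness"].iloc[0] == pytest.approx(-3.0015, abs=1e-4)
        assert gf["variance"].iloc[0] == pytest.approx(0.018731, abs=1e-5)
        assert gf["t"].iloc[0] == pytest.approx(-21.9, abs=0.05)

    def test_empirical_variance_dominates_inconsistent_scores(self):
        # two equal-weight deep observations, scores (-1, -3): V_emp = 1
        obs = _obs_frame([10**6, 10**6], [10**6, 10**6], scores=[-1.0, -3.0])
        gf = pf.gene_fitness(obs)
        assert gf["variance"].iloc[0] == pytest.approx(1.0, rel=1e-6)
        assert gf["t"].iloc[0] == pytest.approx(-2.0, rel=1e-6)


class TestRelativeFitness:
    def test_between_condition_difference(self):
        a = pf.GeneFitness("RTO4_11882", "dgalua", -4.0, 0.01, -40, 3, 9)
        b = pf.GeneFitness("RTO4_11882", "dglc", 0.3, 0.01, 3, 3, 9)
        rel, _ = pf.relative_fitness(a, b)
        assert rel == pytest.approx(-4.3)

    def test_identical_sides_give_zero(self):
        a = pf.GeneFitness("g", "c1", -2.0, 0.1, -6, 2, 6)
        b = pf.GeneFitness("g", "c2", -2.0, 0.1, -6, 2, 6)
        assert pf.relative_fitness(a, b) == (0.0, 0.0)

    def test_variance_pooling(self):
        a = pf.GeneFitness("g", "c1", -3.0, 0.25, -6, 2, 6)
        b = pf.GeneFitness("g", "c2", 0.0, 0.25, 0, 2, 6)
        rel, rel_t = pf.relative_fitness(a, b)
        assert rel == pytest.approx(-3.0)
        assert rel_t == pytest.approx(-3 / math.sqrt(0.5), abs=1e-3)

    def test_same_condition_is_error(self):
        a = pf.GeneFitness("g", "c1", -3.0, 0.25, -6, 2, 6)
        with pytest.raises(ValueError, match="different conditions"):
            pf.relative_fitness(a, a)

    def test_different_gene_is_error(self):
        a = pf.GeneFitness("g1", "c1", -3.0, 0.25, -6, 2, 6)
        b = pf.GeneFitness("g2", "c2", 0.0, 0.25, 0, 2, 6)
        with pytest.raises(ValueError, match="same gene"):
            pf.relative_fitness(a, b)


# ---------------------------------------------------------------------------
# oracle equivalence on random small instances
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_pipeline_matches_oracle_over_many_seeds(self):
        """Strain scores, gene fitness and t agree with the straight-line
        reimplementation to 1e-10 on random <=10-barcode instances."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_bc = int(rng.integers(2, 11))
            n_rep = int(rng.integers(1, 4))
            gene_of = rng.integers(0, 3, size=n_bc)

            barcodes = [f"b{i:02d}" for i in range(n_bc)]
            genes = [
                pf.Gene(f"g{k}", "s1", 1000 * k + 1, 1000 * k + 500, "+", 500)
                for k in range(3)
            ]
            def acgt_barcode(i):
                digits = np.base_repr(i, base=4).zfill(20)
                return "".join("ACGT"[int(d)] for d in digits)

            insertions = [
                pf.Insertion(
                    acgt_barcode(i), "s1", 1000 * gene_of[i] + 100 + i, "+"
                )
                for i in range(n_bc)
            ]
            pool = pf.assign_insertions(pf.InsertionPool(insertions), genes)

            t0_cols = {
                f"t0:{r}": rng.integers(0, 10_001, size=n_bc)
                for r in range(n_rep)
            }
            c_cols = {
                f"c:{r}": rng.integers(0, 10_001, size=n_bc)
                for r in range(n_rep)
            }
            index = pool.barcodes
            t0 = pf.CountMatrix(counts=pd.DataFrame(t0_cols, index=index))
            cm = pf.CountMatrix(counts=pd.DataFrame(c_cols, index=index))

            got = pf.fit_gene_fitness(pool, t0, {"c": cm}).set_index("gene_id")

            # oracle: accumulate normalized scores per replicate, then per gene
            per_gene: dict[str, list] = {}
            for r in range(n_rep):
                n0 = list(t0_cols[f"t0:{r}"])
                n = list(c_cols[f"c:{r}"])
                scores = oracle_sample_scores(n0, n)
                for i in range(n_bc):
                    g = f"g{gene_of[i]}"
                    per_gene.setdefault(g, []).append((n0[i], n[i], scores[i]))
            for g, observations in per_gene.items():
                f, v, t = oracle_gene_stats(observations)
                assert got.loc[g, "fitness"] == pytest.approx(f, abs=1e-10)
                assert got.loc[g, "variance"] == pytest.approx(v, abs=1e-10)
                assert got.loc[g, "t"] == pytest.approx(t, abs=1e-10)
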