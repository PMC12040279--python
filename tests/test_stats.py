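import numpy as np
import pytest
from scipy import stats as sps

from netqtl.io_model import ExpressionMatrix, ProcessingState, preprocess
from netqtl.networks import group_by_genotype
from netqtl.simulate import SimConfig, simulate_dataset
from netqtl.spectral import pmd_sparse_eigen
from netqtl.stats import (
    ScanConfig,
    baseline_local_test,
    empirical_pvalue,
    permutation_pvalue,
    scan,
    stat_max,
    stat_sum,
    stat_tensor,
    stat_tensor_sq,
)
from tests.conftest import planted_tensor


class TestStatistics:
    def test_zero_tensor_gives_zero_for_all(self):
        D = np.zeros((5, 5, 3))
        assert stat_tensor(D) == 0.0
        assert stat_tensor_sq(D) == 0.0
        assert stat_max(D) == 0.0
        assert stat_sum(D) == 0.0

    def test_planted_tensor_statistic(self):
        D, _, _ = planted_tensor(p=20, support=4, lam=2.5, seed=2)
        assert stat_tensor(D, R=4, seed=0) == pytest.approx(2.5, rel=1e-6)
        assert stat_tensor_sq(D, R=4, seed=0) == pytest.approx(6.25, rel=1e-6)

    def test_tensor_equals_sstd_lambda(self):
        from netqtl.spectral import sstd

        rng = np.random.default_rng(0)
        slides = rng.standard_normal((8, 8, 3))
        slides = 0.5 * (slides + slides.transpose(1, 0, 2))
        assert stat_tensor(slides, R=4, seed=3) == sstd(slides, 4, seed=3).Lambda

    def test_max_from_slide_oracle(self):
        M = np.diag([2.0, 0.0])
        slides = np.stack([M, np.zeros_like(M), -M], axis=2)
        assert stat_max(slides, R=2) == pytest.approx(2.0, abs=1e-8)

    def test_max_dominates_each_slide(self):
        rng = np.random.default_rng(1)
        slides = rng.standard_normal((6, 6, 3))
        slides = 0.5 * (slides + slides.transpose(1, 0, 2))
        smax = stat_max(slides, R=3)
        for l in range(3):
            assert smax >= pmd_sparse_eigen(slides[:, :, l], 3).lambda_ - 1e-12

    def test_sum_dominates_max(self):
        rng = np.random.default_rng(2)
        slides = rng.standard_normal((6, 6, 3))
        slides = 0.5 * (slides + slides.transpose(1, 0, 2))
        assert stat_sum(slides, R=6) >= stat_max(slides, R=6) - 1e-12

    def test_genotype_relabel_invariance(self):
        # swapping the A and B genotype labels permutes/negates the slides;
        # both statistics are invariant (checked with R = p, where the
        # solvers are exact)
        rng = np.random.default_rng(3)
        mats = []
        for _ in range(3):
            a = 0.1 * rng.standard_normal((8, 8))
            mats.append(a + a.T)
        n_a, n_h, n_b = mats
        orig = np.stack([n_b - n_a, n_h - n_a, n_h - n_b], axis=2)
        swap = np.stack([n_a - n_b, n_h - n_b, n_h - n_a], axis=2)
        assert stat_max(orig, R=8) == pytest.approx(stat_max(swap, R=8), abs=1e-8)
        assert stat_tensor(orig, R=8, restarts=10, seed=0) == pytest.approx(
            stat_tensor(swap, R=8, restarts=10, seed=0), abs=1e-6
        )


class TestEmpiricalPvalue:
    def test_two_exceedances(self):
        p, exceed = empirical_pvalue(2.0, [1.0, 2.0, 3.0, 1.0])
        assert p == 0.5
        assert exceed == 2

    def test_no_exceedance_gives_zero(self):
        p, _ = empirical_pvalue(10.0, [1.0, 2.0, 3.0])
        assert p == 0.0

    def test_plus_one_correction(self):
        p, _ = empirical_pvalue(10.0, [1.0] * 99, plus_one=True)
        assert p == pytest.approx(0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, [])


def _sim(n=60, p=12, chroms=4, effect=0.0, seed=0):
    cfg = SimConfig(n=n, n_genes=p, n_chrom=chroms, effect_size=effect, seed=seed, snqtl_index=3)
    expr, geno, gmap, truth = simulate_dataset(cfg)
    return preprocess(expr, top_k=p), geno, gmap, truth


class TestPermutationPvalue:
    def test_identical_expression_gives_p_one(self):
        expr, geno, gmap, _ = _sim(seed=5)
        # every sample identical (all-zero residuals) -> every permuted
        # statistic equals S
        const = np.zeros((expr.n_genes, expr.n_samples))
        expr = ExpressionMatrix(
            const, expr.gene_ids, expr.sample_ids, ProcessingState.RESIDUALIZED
        )
        groups = group_by_genotype(geno, geno.marker_ids[0], min_group=1)
        cfg = ScanConfig(statistic="max", min_group=1, seed=0)
        S, p, exceed = permutation_pvalue(expr, groups, cfg, 20, gmap=gmap)
        assert p == 1.0
        assert exceed == 20

    def test_deterministic_given_rng(self):
        expr, geno, gmap, _ = _sim(seed=6)
        groups = group_by_genotype(geno, geno.marker_ids[2], min_group=1)
        cfg = ScanConfig(statistic="tensor", min_group=1, seed=1)
        out1 = permutation_pvalue(expr, groups, cfg, 15, gmap=gmap, rng=np.random.default_rng(9))
        out2 = permutation_pvalue(expr, groups, cfg, 15, gmap=gmap, rng=np.random.default_rng(9))
        assert out1 == out2

    def test_b_use_validation(self):
        expr, geno, gmap, _ = _sim(seed=7)
        groups = group_by_genotype(geno, geno.marker_ids[0], min_group=1)
        cfg = ScanConfig(min_group=1)
        with pytest.raises(ValueError):
            permutation_pvalue(expr, groups, cfg, 0, gmap=gmap)


class TestScan:
    def test_null_scan_roughly_uniform(self):
        expr, geno, gmap, _ = _sim(n=80, seed=8)
        cfg = ScanConfig(statistic="tensor", B0=40, seed=3, min_group=5, screen_only=True)
        result = scan(expr, geno, gmap, cfg)
        tested = result.table[result.table["stage"] != "untestable"]
        assert len(tested) > 5
        assert tested["p_value"].between(0, 1).all()
        assert 0.2 < tested["p_value"].mean() < 0.8

    def test_planted_marker_reaches_stage_two(self):
        expr, geno, gmap, truth = _sim(n=200, p=20, chroms=5, effect=1.0, seed=9)
        cfg = ScanConfig(statistic="tensor", B0=30, B=60, seed=4, min_group=5)
        result = scan(expr, geno, gmap, cfg)
        row = result.table.set_index("marker_id").loc[truth["planted_marker"]]
        assert row["stage"] == "confirmed"
        assert row["p_value"] <= 0.05

    def test_fixed_seed_reproducible(self, tmp_path):
        expr, geno, gmap, _ = _sim(seed=10)
        cfg = ScanConfig(statistic="max", B0=20, seed=11, min_group=3, screen_only=True)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        scan(expr, geno, gmap, cfg).to_tsv(a)
        scan(expr, geno, gmap, cfg).to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_stage_labels_present(self):
        expr, geno, gmap, _ = _sim(seed=12)
        cfg = ScanConfig(B0=10, B=20, seed=0, min_group=30)  # min_group huge -> untestable
        result = scan(expr, geno, gmap, cfg)
        assert (result.table["stage"] == "untestable").all()


def _baseline_oracle(expr, geno, gmap, marker_id):
    """Independent two-step reconstruction: per-pair OLS F-tests, then Bonferroni."""
    row = geno.codes[geno.marker_ids.index(marker_id)]
    keep = row >= 0
    d = row[keep].astype(float)
    X = expr.values[:, keep]
    z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    chrom = gmap.chrom_of(expr.gene_ids)
    pvals = []
    p = X.shape[0]
    for j in range(p):
        for k in range(j + 1, p):
            if chrom[j] == chrom[k]:
                continue
            y = z[j] * z[k]
            slope, _, r, pv, _ = sps.linregress(d, y)
            pvals.append(pv)
    return min(1.0, len(pvals) * min(pvals))


class TestBaseline:
    def test_matches_independent_reimplementation(self):
        expr, geno, gmap, _ = _sim(n=50, p=10, chroms=5, effect=0.8, seed=13)
        marker = geno.marker_ids[4]
        ours = baseline_local_test(expr, geno, gmap, marker)
        oracle = _baseline_oracle(expr, geno, gmap, marker)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_perfect_linear_pair_p_near_zero(self):
        # one cross-chromosome pair whose co-expression is exactly linear in
        # dosage with no noise
        n = 30
        rng = np.random.default_rng(0)
        dosage = np.repeat([0, 1, 2], n // 3)
        signs = np.tile([1.0, -1.0], n // 2)  # balanced within each class
        g1 = signs
        g2 = signs * dosage  # z1 * z2 proportional to signs^2 * dosage = dosage
        g3 = rng.standard_normal(n)
        vals = np.vstack([g1, g2, g3])
        vals -= vals.mean(1, keepdims=True)
        expr = ExpressionMatrix(
            vals, ["a", "b", "c"], [f"s{i}" for i in range(n)], ProcessingState.RESIDUALIZED
        )
        import pandas as pd

        from netqtl.io_model import GeneMap, GenotypeMatrix

        gmap = GeneMap(
            pd.DataFrame(
                {"gene_id": ["a", "b", "c"], "chrom": [1, 2, 3], "pos": [1, 1, 1]}
            ).set_index("gene_id")
        )
        geno = GenotypeMatrix(
            dosage[None, :].astype(np.int8), ["m1"], expr.sample_ids
        )
        p = baseline_local_test(expr, geno, gmap, "m1")
        assert p < 1e-6

    def test_single_class_untestable(self):
        expr, geno, gmap, _ = _sim(seed=14)
        import numpy as np

        from netqtl.io_model import GenotypeMatrix

        mono = GenotypeMatrix(
            np.zeros((1, expr.n_samples), dtype=np.int8), ["m1"], expr.sample_ids
        )
        assert np.isnan(baseline_local_test(expr, mono, gmap, "m1"))

    def test_null_is_conservative(self):
        # Bonferroni-combined p under the null should be stochastically >= uniform
        ps = []
        for seed in range(15):
            expr, geno, gmap, _ = _sim(n=60, p=10, chroms=5, effect=0.0, seed=100 + seed)
            ps.append(baseline_local_test(expr, geno, gmap, geno.marker_ids[3]))
        assert np.mean(ps) > 0.3
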