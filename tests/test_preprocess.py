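"""Genotype QC, expression filtering, INT and principal components."""

from math import comb
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from transqtl.io import ExpressionMatrix, GenotypeMatrix, VariantRecord
from transqtl.preprocess import (
    QcThresholds,
    compute_pcs,
    filter_genotypes,
    filter_low_expression,
    hwe_exact_p,
    inverse_normal_transform,
)


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration of the conditional heterozygote-count
    distribution (independent of the log-space implementation)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    weights = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_b = n - het - hom_a
        if hom_a < 0 or hom_b < 0:
            continue
        # number of genotype assignments: multinomial times 2^het phases
        weights[het] = Fraction(
            comb(n, het) * comb(n - het, hom_a) * 2**het
        )
    total = sum(weights.values())
    observed = weights[n_ab]
    p = sum(w for w in weights.values() if w <= observed) / total
    return float(p)


class TestHweExact:
    def test_balanced_table_has_p_one(self):
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_heterozygote_deficit(self):
        assert hwe_exact_p(50, 0, 50) < 1e-6

    @pytest.mark.parametrize(
        "counts", [(25, 50, 25), (50, 0, 50), (3, 5, 2), (0, 10, 0), (7, 1, 9)]
    )
    def test_matches_exact_rational_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_allele_relabelling_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = rng.integers(0, 40, size=3)
            if a + b + c == 0:
                continue
            assert hwe_exact_p(a, b, c) == pytest.approx(
                hwe_exact_p(c, b, a), rel=1e-12
            )

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)


def _matrix(columns: dict[str, np.ndarray], r2=None) -> GenotypeMatrix:
    names = list(columns)
    variants = [
        VariantRecord("chr1", 100 * (i + 1), "A", "G",
                      imputation_r2=(r2 or {}).get(v, float("nan")))
        for i, v in enumerate(names)
    ]
    dosages = np.column_stack([columns[v] for v in names])
    n = dosages.shape[0]
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)


class TestFilterGenotypes:
    def test_exclusion_reasons(self):
        n = 200
        rng = np.random.default_rng(1)
        good = rng.binomial(2, 0.3, n).astype(float)
        rare = np.zeros(n)
        rare[:2] = 1.0  # MAF 0.005
        mono = np.zeros(n)
        missing = good.copy()
        missing[: n // 4] = np.nan
        hwe_bad = np.concatenate([np.zeros(n // 2), np.full(n // 2, 2.0)])
        low_r2 = rng.binomial(2, 0.4, n).astype(float)
        gm = _matrix(
            {"good": good, "rare": rare, "mono": mono, "miss": missing,
             "hwe": hwe_bad, "lowr2": low_r2},
            r2={"lowr2": 0.2},
        )
        kept, report = filter_genotypes(gm)
        reasons = dict(zip(report["variant_id"], report["reason"]))
        assert kept.variant_ids == [gm.variant_ids[0]]
        assert reasons[gm.variant_ids[1]] == "maf"
        assert reasons[gm.variant_ids[2]] == "maf"
        assert reasons[gm.variant_ids[3]] == "missingness"
        assert reasons[gm.variant_ids[4]] == "hwe"
        assert reasons[gm.variant_ids[5]] == "imputation_r2"

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        gm = _matrix(
            {f"v{i}": rng.binomial(2, 0.3, 100).astype(float) for i in range(10)}
        )
        once, _ = filter_genotypes(gm)
        twice, report = filter_genotypes(once)
        assert twice.variant_ids == once.variant_ids
        assert report.empty

    def test_empty_result_is_explicit(self):
        gm = _matrix({"mono": np.zeros(50)})
        kept, report = filter_genotypes(gm)
        assert len(kept.variants) == 0
        assert len(report) == 1


class TestLowExpressionFilter:
    def _tpm(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            [f"s{i}" for i in range(values.shape[0])],
            [f"g{j}" for j in range(values.shape[1])],
            values,
            "TPM",
        )

    def test_removal_rule_and_boundary(self):
        n = 100
        low = np.full(n, 0.5)
        low[:4] = 5.0  # 96% below 1 -> removed
        high = np.full(n, 10.0)  # kept
        boundary = np.full(n, 0.5)
        boundary[:5] = 5.0  # exactly 95% below 1 -> removed (inclusive)
        em = self._tpm(np.column_stack([low, high, boundary]))
        kept = filter_low_expression(em)
        assert kept.gene_ids == ["g1"]

    def test_requires_tpm_unit(self):
        em = ExpressionMatrix(["s1", "s2", "s3"], ["g"], np.ones((3, 1)), "INT")
        with pytest.raises(ValueError):
            filter_low_expression(em)


class TestInverseNormalTransform:
    def test_three_point_example(self):
        out = inverse_normal_transform(np.array([3.0, 1.0, 2.0]))
        expected = stats.norm.ppf([2.5 / 3, 0.5 / 3, 1.5 / 3])
        assert np.allclose(out, expected, atol=1e-4)
        assert out == pytest.approx([0.9674, -0.9674, 0.0], abs=1e-4)

    def test_ties_get_equal_values(self):
        out = inverse_normal_transform(np.array([1.0, 1.0, 2.0]))
        assert out[0] == out[1]

    def test_permutation_preserves_value_multiset(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        a = np.sort(inverse_normal_transform(x))
        b = np.sort(inverse_normal_transform(x[rng.permutation(50)]))
        assert np.allclose(a, b)

    def test_constant_and_short_inputs_raise(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.ones(10))
        with pytest.raises(ValueError):
            inverse_normal_transform(np.array([1.0, 2.0]))

    def test_output_is_normal_for_continuous_input(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=500)  # heavily skewed input
        out = inverse_normal_transform(x)
        assert abs(out.mean()) < 1e-6
        assert stats.shapiro(out).pvalue > 0.01


class TestComputePcs:
    def test_rank_one_structure_dominates_pc1(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=100)
        loadings = rng.normal(size=20)
        x = np.outer(scores, loadings) + 1e-3 * rng.normal(size=(100, 20))
        pcs = compute_pcs(x, 3)
        total_var = ((x - x.mean(0)) ** 2).sum()
        assert (pcs["PC1"] ** 2).sum() / total_var > 0.99

    def test_scores_are_orthogonal(self):
        rng = np.random.default_rng(6)
        pcs = compute_pcs(rng.normal(size=(50, 10)), 5).to_numpy()
        cross = pcs.T @ pcs
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8

    def test_k_zero_and_k_too_large(self):
        x = np.random.default_rng(7).normal(size=(10, 4))
        assert compute_pcs(x, 0).shape == (10, 0)
        with pytest.raises(ValueError):
            compute_pcs(x, 5)


def test_qc_threshold_defaults_are_the_documented_screen():
    th = QcThresholds()
    assert (th.maf_min, th.hwe_p_min, th.missingness_max) == (0.01, 1e-6, 0.05)
    assert (th.imputation_r2_min, th.low_expr_tpm) == (0.4, 1.0)
    assert (th.low_expr_sample_frac, th.n_expr_pcs, th.n_geno_pcs) == (0.95, 6, 6)
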