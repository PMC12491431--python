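"""Fixed and random-effects meta-analysis closed forms and recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transqtl.meta import dersimonian_laird, heterogeneity, ivw_fixed, meta_analyse


class TestIvwFixed:
    def test_equal_weights_give_the_arithmetic_mean(self):
        out = ivw_fixed([0.5, 0.3], [0.1, 0.1])
        assert out["beta_fixed"] == pytest.approx(0.4, abs=1e-12)
        assert out["se_fixed"] == pytest.approx(200**-0.5, abs=1e-10)

    def test_unequal_weights(self):
        out = ivw_fixed([0.5, 0.5], [0.1, 0.2])
        assert out["beta_fixed"] == pytest.approx(0.5, abs=1e-12)
        assert out["se_fixed"] == pytest.approx(125**-0.5, abs=1e-10)

    def test_single_cohort_passthrough(self):
        out = ivw_fixed([0.7], [0.05])
        assert out["beta_fixed"] == pytest.approx(0.7, abs=1e-12)
        assert out["se_fixed"] == pytest.approx(0.05, abs=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            ivw_fixed([0.1, 0.2], [0.0, 0.1])


class TestHeterogeneity:
    def test_identical_betas_give_zero(self):
        out = heterogeneity([0.4, 0.4, 0.4], [0.1, 0.2, 0.3])
        assert out["Q"] == pytest.approx(0.0, abs=1e-12)
        assert out["I2"] == 0.0

    def test_hand_evaluated_small_q_clips_to_zero(self):
        out = heterogeneity([0.0, 1.0], [1.0, 1.0])
        assert out["Q"] == pytest.approx(0.5, abs=1e-12)
        assert out["I2"] == 0.0

    def test_hand_evaluated_large_q(self):
        out = heterogeneity([0.0, 2.0], [0.1, 0.1])
        assert out["Q"] == pytest.approx(200.0, abs=1e-9)
        assert out["I2"] == pytest.approx(0.995, abs=1e-10)

    def test_requires_two_cohorts(self):
        with pytest.raises(ValueError):
            heterogeneity([0.5], [0.1])


class TestDerSimonianLaird:
    def test_hand_evaluated_example(self):
        out = dersimonian_laird([0.0, 2.0], [0.1, 0.1])
        assert out["tau2"] == pytest.approx(1.99, abs=1e-10)
        assert out["beta_re"] == pytest.approx(1.0, abs=1e-12)
        assert out["se_re"] == pytest.approx(1.0, abs=1e-10)
        assert out["p_re"] == pytest.approx(0.31731, abs=1e-4)

    def test_homogeneous_input_collapses_to_fixed(self):
        betas, ses = [0.35, 0.36], [0.4, 0.4]
        fixed = ivw_fixed(betas, ses)
        re = dersimonian_laird(betas, ses)
        assert re["tau2"] == 0.0
        assert re["beta_re"] == pytest.approx(fixed["beta_fixed"], abs=1e-12)
        assert re["se_re"] == pytest.approx(fixed["se_fixed"], abs=1e-12)

    def test_identical_stats_give_zero_tau2(self):
        out = dersimonian_laird([0.2] * 5, [0.1] * 5)
        assert out["tau2"] == 0.0
        assert out["beta_re"] == pytest.approx(0.2, abs=1e-12)

    @given(
        betas=st.lists(st.floats(-2, 2), min_size=2, max_size=8),
        ses=st.lists(st.floats(0.01, 1.5), min_size=8, max_size=8),
    )
    @settings(max_examples=100, derandomize=True)
    def test_random_effects_se_never_below_fixed(self, betas, ses):
        ses = ses[: len(betas)]
        re = dersimonian_laird(betas, ses)
        fixed = ivw_fixed(betas, ses)
        assert re["se_re"] >= fixed["se_fixed"] - 1e-12

    def test_tau2_recovery_smoke(self):
        """Mean DL estimate tracks the true between-study variance."""
        rng = np.random.default_rng(21)
        tau2_true = 0.05
        ses = np.full(9, 0.05)
        estimates = [
            dersimonian_laird(
                rng.normal(0.2, np.sqrt(tau2_true + ses**2)), ses
            )["tau2"]
            for _ in range(300)
        ]
        assert np.mean(estimates) == pytest.approx(tau2_true, rel=0.15)


def _cohort_table(cohort, records):
    rows = []
    for vid, gid, beta, se in records:
        chrom, pos, ref, alt = vid.split("_")
        rows.append(
            {
                "cohort_id": cohort, "variant_id": vid, "chrom": chrom,
                "pos": int(pos), "ref": ref, "alt": alt, "gene_id": gid,
                "beta": beta, "se": se, "pvalue": 0.5, "n": 100, "maf": 0.3,
            }
        )
    return pd.DataFrame(rows)


class TestMetaAnalyse:
    def test_matches_scalar_helpers(self):
        t1 = _cohort_table("c1", [("chr1_100_A_G", "g1", 0.5, 0.1),
                                  ("chr1_200_C_T", "g2", -0.2, 0.3)])
        t2 = _cohort_table("c2", [("chr1_100_A_G", "g1", 0.3, 0.1)])
        out = meta_analyse([t1, t2], random_effects=True).set_index(
            ["variant_id", "gene_id"]
        )
        pooled = out.loc[("chr1_100_A_G", "g1")]
        ref = ivw_fixed([0.5, 0.3], [0.1, 0.1])
        assert pooled["beta_fixed"] == pytest.approx(ref["beta_fixed"], abs=1e-12)
        assert pooled["k"] == 2
        single = out.loc[("chr1_200_C_T", "g2")]
        assert single["k"] == 1
        assert single["beta_fixed"] == pytest.approx(-0.2, abs=1e-12)
        assert np.isnan(single["Q"])
        assert single["beta_re"] == pytest.approx(-0.2, abs=1e-12)

    def test_vectorized_path_equals_helpers_on_random_input(self):
        rng = np.random.default_rng(22)
        tables = []
        for c in range(4):
            recs = [
                (f"chr1_{100 * (v + 1)}_A_G", f"g{g}",
                 rng.normal(), rng.uniform(0.05, 0.5))
                for v in range(5)
                for g in range(3)
                if rng.random() < 0.8  # unbalanced panels
            ]
            if recs:
                tables.append(_cohort_table(f"c{c}", recs))
        out = meta_analyse(tables, random_effects=True)
        stacked = pd.concat(tables)
        for _, row in out.iterrows():
            grp = stacked[
                (stacked["variant_id"] == row["variant_id"])
                & (stacked["gene_id"] == row["gene_id"])
            ]
            ref = ivw_fixed(grp["beta"], grp["se"])
            assert row["beta_fixed"] == pytest.approx(ref["beta_fixed"], abs=1e-10)
            assert row["se_fixed"] == pytest.approx(ref["se_fixed"], abs=1e-10)
            if len(grp) >= 2:
                dl = dersimonian_laird(grp["beta"], grp["se"])
                assert row["tau2"] == pytest.approx(dl["tau2"], abs=1e-10)
                assert row["beta_re"] == pytest.approx(dl["beta_re"], abs=1e-10)

    def test_allele_mismatch_raises(self):
        t1 = _cohort_table("c1", [("chr1_100_A_G", "g1", 0.5, 0.1)])
        t2 = _cohort_table("c2", [("chr1_100_A_G", "g1", 0.3, 0.1)])
        t2.loc[:, "ref"], t2.loc[:, "alt"] = "G", "A"
        with pytest.raises(ValueError, match="allele mismatch"):
            meta_analyse([t1, t2])

    def test_fixed_effect_matches_mega_analysis(self):
        """IVW pool equals one big regression with cohort indicators on
        homogeneous data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(23)
        beta_true = 0.3
        tables, frames = [], []
        for c in range(3):
            n = 220
            g = rng.binomial(2, 0.4, n).astype(float)
            y = beta_true * g + rng.normal(size=n)
            x = sm.add_constant(g)
            fit = sm.OLS(y, x).fit()
            tables.append(
                _cohort_table(f"c{c}", [("chr1_100_A_G", "g1",
                                         fit.params[1], fit.bse[1])])
            )
            frames.append(pd.DataFrame({"g": g, "y": y, "cohort": c}))
        pooled = meta_analyse(tables).iloc[0]["beta_fixed"]
        mega = pd.concat(frames, ignore_index=True)
        dummies = pd.get_dummies(mega["cohort"], drop_first=False).astype(float)
        x = np.column_stack([dummies, mega["g"]])
        fit = sm.OLS(mega["y"], x).fit()
        assert pooled == pytest.approx(fit.params.iloc[-1], rel=0.02)
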