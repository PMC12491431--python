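"""Fixed-effect and random-effects meta-analysis of per-cohort statistics.

Fixed effects use inverse-variance weighting (w_i = 1/se_i^2) with a normal
reference for the pooled z, the large-sample convention for meta z-scores
(per-cohort p-values use the t).  Heterogeneity is summarised by Cochran's
Q, I^2 = max(0, (Q - df) / Q), and the DerSimonian-Laird moment estimate of
the between-study variance tau^2; random-effects estimates re-weight by
1 / (se_i^2 + tau^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ivw_fixed",
    "heterogeneity",
    "dersimonian_laird",
    "meta_analyse",
]


def _check(betas, ses) -> tuple[np.ndarray, np.ndarray]:
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1 or betas.size == 0:
        raise ValueError("need matching non-empty 1-d beta and se arrays")
    if not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("all standard errors must be finite and > 0")
    return betas, ses


def ivw_fixed(betas, ses) -> dict[str, float]:
    """Inverse-variance-weighted fixed-effect pool of one (variant, gene)
    pair across cohorts.  Returns beta, se, z and the two-sided normal p."""
    betas, ses = _check(betas, ses)
    w = ses**-2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    return {
        "beta_fixed": beta,
        "se_fixed": se,
        "z_fixed": z,
        "p_fixed": float(np.clip(2 * stats.norm.sf(abs(z)), 5e-324, 1.0)),
        "k": betas.size,
    }


def heterogeneity(betas, ses, beta_fixed: float | None = None) -> dict[str, float]:
    """Cochran's Q, its df = k - 1, and I^2 (clipped at 0; 0 when Q = 0)."""
    betas, ses = _check(betas, ses)
    if betas.size < 2:
        raise ValueError("heterogeneity requires k >= 2 cohorts")
    if beta_fixed is None:
        beta_fixed = ivw_fixed(betas, ses)["beta_fixed"]
    w = ses**-2
    q = float((w * (betas - beta_fixed) ** 2).sum())
    df = betas.size - 1
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q)
    return {"Q": q, "df": df, "I2": i2}


def dersimonian_laird(betas, ses) -> dict[str, float]:
    """DerSimonian-Laird random-effects estimate for k >= 2 cohorts.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)); the pooled effect
    re-weights by w*_i = 1 / (se_i^2 + tau^2), with a normal z and two-sided
    p.  When Q <= df the estimate collapses onto the fixed-effect result.
    """
    betas, ses = _check(betas, ses)
    if betas.size < 2:
        raise ValueError("random-effects meta-analysis requires k >= 2 cohorts")
    fixed = ivw_fixed(betas, ses)
    het = heterogeneity(betas, ses, fixed["beta_fixed"])
    w = ses**-2
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (het["Q"] - het["df"]) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta_re = float((w_star * betas).sum() / w_star.sum())
    se_re = float(w_star.sum() ** -0.5)
    z = beta_re / se_re
    return {
        "tau2": tau2,
        "beta_re": beta_re,
        "se_re": se_re,
        "z_re": z,
        "p_re": float(np.clip(2 * stats.norm.sf(abs(z)), 5e-324, 1.0)),
        **het,
    }


def meta_analyse(
    cohort_tables: list[pd.DataFrame] | dict[str, pd.DataFrame],
    random_effects: bool = False,
) -> pd.DataFrame:
    """Pool per-cohort association tables over (variant, gene) pairs.

    Pairs present in a single cohort carry that cohort's estimate with
    k = 1 and undefined heterogeneity (NaN Q / I2 / tau2); the study design
    this emulates meta-analysed unbalanced gene panels, so singletons are
    legitimate.  Alleles must agree across cohorts for a shared variant id
    (no silent flipping).

    Returns one row per pair with the fixed-effect fields, heterogeneity
    diagnostics and, when ``random_effects`` is set, DerSimonian-Laird
    fields.
    """
    if isinstance(cohort_tables, dict):
        cohort_tables = list(cohort_tables.values())
    if not cohort_tables:
        raise ValueError("no cohort tables supplied")
    stacked = pd.concat(cohort_tables, ignore_index=True)
    if stacked.empty:
        raise ValueError("all cohort tables are empty")

    alleles = stacked.groupby("variant_id")[["ref", "alt"]].nunique()
    clash = alleles[(alleles["ref"] > 1) | (alleles["alt"] > 1)]
    if not clash.empty:
        raise ValueError(
            f"allele mismatch across cohorts for {clash.index[0]!r}; "
            "harmonize alleles before meta-analysis"
        )

    if np.any(stacked["se"].to_numpy() <= 0) or not np.all(
        np.isfinite(stacked["se"].to_numpy())
    ):
        raise ValueError("all standard errors must be finite and > 0")

    stacked = stacked.reset_index(drop=True)
    pair_key, pair_index = pd.factorize(
        pd.MultiIndex.from_arrays([stacked["variant_id"], stacked["gene_id"]]),
        sort=True,
    )
    n_pairs = len(pair_index)

    # scatter per-cohort stats into dense (pairs x slots) arrays
    slot = np.zeros(len(stacked), dtype=int)
    order = np.argsort(pair_key, kind="stable")
    counts = np.bincount(pair_key, minlength=n_pairs)
    slot[order] = np.arange(len(stacked)) - np.repeat(
        np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
    )
    k_max = counts.max()
    B = np.full((n_pairs, k_max), np.nan)
    S = np.full((n_pairs, k_max), np.nan)
    B[pair_key, slot] = stacked["beta"].to_numpy()
    S[pair_key, slot] = stacked["se"].to_numpy()

    present = np.isfinite(S)
    k = present.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(present, S**-2, 0.0)
        sw = w.sum(axis=1)
        beta_fixed = (w * np.where(present, B, 0.0)).sum(axis=1) / sw
        se_fixed = sw**-0.5
        z_fixed = beta_fixed / se_fixed
        p_fixed = np.clip(2 * stats.norm.sf(np.abs(z_fixed)), 5e-324, 1.0)

        q = (w * np.where(present, (B - beta_fixed[:, None]) ** 2, 0.0)).sum(axis=1)
        df = k - 1
        i2 = np.where(q > 0, np.maximum(0.0, (q - df) / np.where(q > 0, q, 1.0)), 0.0)
        q = np.where(k >= 2, q, np.nan)
        i2 = np.where(k >= 2, i2, np.nan)

    first = np.full(n_pairs, -1, dtype=int)
    first[pair_key[::-1]] = np.arange(len(stacked))[::-1]
    n_total = np.bincount(pair_key, weights=stacked["n"].to_numpy(),
                          minlength=n_pairs).astype(int)
    maf_avg = np.bincount(
        pair_key, weights=(stacked["maf"] * stacked["n"]).to_numpy(),
        minlength=n_pairs,
    ) / np.maximum(n_total, 1)

    out = pd.DataFrame(
        {
            "variant_id": [p[0] for p in pair_index],
            "chrom": stacked["chrom"].to_numpy()[first],
            "pos": stacked["pos"].to_numpy()[first],
            "ref": stacked["ref"].to_numpy()[first],
            "alt": stacked["alt"].to_numpy()[first],
            "gene_id": [p[1] for p in pair_index],
            "n": n_total,
            "maf": maf_avg,
            "k": k,
            "beta_fixed": beta_fixed,
            "se_fixed": se_fixed,
            "z_fixed": z_fixed,
            "p_fixed": p_fixed,
            "Q": q,
            "df": np.maximum(df, 0),
            "I2": i2,
        }
    )
    if random_effects:
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = sw - (w**2).sum(axis=1) / sw
            tau2 = np.where(
                (k >= 2) & (denom > 0),
                np.maximum(0.0, (np.nan_to_num(q) - df) / np.where(denom > 0, denom, 1.0)),
                0.0,
            )
            w_star = np.where(present, 1.0 / (S**2 + tau2[:, None]), 0.0)
            sw_star = w_star.sum(axis=1)
            beta_re = (w_star * np.where(present, B, 0.0)).sum(axis=1) / sw_star
            se_re = sw_star**-0.5
            z_re = beta_re / se_re
        out["tau2"] = np.where(k >= 2, tau2, np.nan)
        out["beta_re"] = beta_re
        out["se_re"] = se_re
        out["z_re"] = z_re
        out["p_re"] = np.clip(2 * stats.norm.sf(np.abs(z_re)), 5e-324, 1.0)
    return out
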