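"""Approximate-Bayes-factor colocalisation with lead-variant imputation.

Under the single-causal-variant assumption, each variant's evidence for
association with a trait is summarised by the Wakefield approximate Bayes
factor

    log ABF = 1/2 log(se^2 / (se^2 + W)) + z^2/2 * W / (se^2 + W)

with prior effect variance W.  Enumerating which variant (if any) is causal
for each trait gives five hypotheses: H0 neither trait has a causal variant
in the region, H1/H2 only trait 1/2 does, H3 both do but at distinct
variants, H4 both share one causal variant.  Posterior probabilities
PP0-PP4 follow from per-hypothesis sums of ABF products with priors
p1, p2, p12, evaluated in log space throughout.

When only a lead variant's statistic is available for one trait (a common
situation for published GWAS), a full regional profile is imputed from an
LD panel: z_j = r(j, lead) * z_lead, with the standard error back-solved
from each variant's allele frequency under a standardized-trait model —
the point-estimation approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import GenotypeMatrix

__all__ = [
    "ColocConfig",
    "ColocResult",
    "wakefield_log_abf",
    "coloc_abf",
    "compute_ld",
    "poemcoloc_impute",
]


@dataclass(frozen=True)
class ColocConfig:
    """Priors and effect-variance for ABF colocalisation.

    ``p1``/``p2``: prior that a given variant is causal for trait 1/2 only;
    ``p12``: prior that it is causal for both.  ``w_quant``/``w_cc`` are the
    prior effect variances for quantitative (0.2^2, standardized scale) and
    case-control (0.15^2, log-odds scale) traits, the established ABF
    convention.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = 0.2**2
    w_cc: float = 0.15**2

    def __post_init__(self):
        for p in (self.p1, self.p2, self.p12):
            if not (0 < p < 1):
                raise ValueError("priors must lie in (0, 1)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if min(self.w_quant, self.w_cc) <= 0:
            raise ValueError("prior effect variances must be > 0")

    def w_for(self, trait_type: str) -> float:
        if trait_type == "quantitative":
            return self.w_quant
        if trait_type == "case-control":
            return self.w_cc
        raise ValueError(f"unknown trait type {trait_type!r}")


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    config: ColocConfig

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def best_hypothesis(self) -> int:
        return int(np.argmax(self.as_array()))


def wakefield_log_abf(beta, se, w: float):
    """Log approximate Bayes factor for one association statistic.

    Increasing in |beta/se| at fixed se and w; tends to 0 as w -> 0.
    """
    if w <= 0:
        raise ValueError(f"prior effect variance must be > 0, got {w}")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    v = se**2
    z2 = (beta / se) ** 2
    shrink = v / (v + w)
    out = 0.5 * np.log(shrink) + 0.5 * z2 * (1.0 - shrink)
    return float(out) if out.ndim == 0 else out


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b > a:
        raise ValueError("logsumexp difference would be negative")
    if a == b:
        return float("-inf")
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    config: ColocConfig = ColocConfig(),
    trait1: str = "quantitative",
    trait2: str = "quantitative",
) -> ColocResult:
    """Colocalise two regional association profiles.

    Inputs need columns ``variant_id``, ``beta``, ``se``; the variant
    intersection is taken (a warning is issued when under 80% of either
    panel is retained).  Returns PP0-PP4 summing to 1 within 1e-10.
    """
    import warnings

    s1 = stats1.set_index("variant_id")
    s2 = stats2.set_index("variant_id")
    shared = s1.index.intersection(s2.index)
    if len(shared) < 1:
        raise ValueError("no shared variants between the two datasets")
    if len(shared) < 0.8 * min(len(s1), len(s2)):
        warnings.warn(
            f"only {len(shared)} of {min(len(s1), len(s2))} variants shared "
            "between the two datasets",
            stacklevel=2,
        )
    l1 = wakefield_log_abf(
        s1.loc[shared, "beta"].to_numpy(), s1.loc[shared, "se"].to_numpy(),
        config.w_for(trait1),
    )
    l2 = wakefield_log_abf(
        s2.loc[shared, "beta"].to_numpy(), s2.loc[shared, "se"].to_numpy(),
        config.w_for(trait2),
    )
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    log_s1 = logsumexp(l1)
    log_s2 = logsumexp(l2)
    log_s12 = logsumexp(l1 + l2)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(config.p1) + log_s1
    lh[2] = np.log(config.p2) + log_s2
    # H3: two distinct causal variants -> sum over ordered pairs minus diagonal
    if len(l1) > 1:
        lh[3] = (
            np.log(config.p1) + np.log(config.p2)
            + _log_diff_exp(log_s1 + log_s2, log_s12)
        )
    else:
        lh[3] = float("-inf")
    lh[4] = np.log(config.p12) + log_s12

    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(*pp, n_variants=len(shared), config=config)


def compute_ld(gm: GenotypeMatrix, lead_variant_id: str) -> pd.DataFrame:
    """Pearson correlation of every panel variant's dosages with the lead's.

    Returns variant_id, r and r2; constant columns get NaN and a flag.
    """
    vids = gm.variant_ids
    if lead_variant_id not in vids:
        raise ValueError(f"lead variant {lead_variant_id!r} not in the panel")
    d = gm.dosages.copy()
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(means, idx[1])
    centered = d - d.mean(axis=0)
    sd = centered.std(axis=0)
    lead = centered[:, vids.index(lead_variant_id)]
    lead_sd = lead.std()
    if lead_sd == 0:
        raise ValueError(f"lead variant {lead_variant_id!r} has constant dosage")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered * lead[:, None]).mean(axis=0) / (sd * lead_sd)
    r[sd == 0] = np.nan
    return pd.DataFrame(
        {
            "variant_id": vids,
            "r": r,
            "r2": r**2,
            "degenerate": sd == 0,
        }
    )


def poemcoloc_impute(
    lead_variant_id: str,
    lead_z: float,
    panel: GenotypeMatrix,
    n: int,
    ld: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Impute a full regional profile from one lead statistic via LD.

    ``z_j = r(j, lead) * z_lead`` for every panel variant; the standard
    error is back-solved as ``1 / sqrt(2 n maf_j (1 - maf_j))`` under a
    standardized-trait model, and ``beta_j = z_j * se_j``.  Degenerate
    (monomorphic) panel variants are dropped.
    """
    if ld is None:
        ld = compute_ld(panel, lead_variant_id)
    mafs = panel.maf()
    keep = (~ld["degenerate"].to_numpy()) & (mafs > 0) & (mafs < 1)
    r = ld["r"].to_numpy()[keep]
    maf = mafs[keep]
    z = r * lead_z
    se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
    return pd.DataFrame(
        {
            "variant_id": np.array(panel.variant_ids)[keep],
            "beta": z * se,
            "se": se,
            "z": z,
            "n": n,
            "maf": maf,
        }
    )
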