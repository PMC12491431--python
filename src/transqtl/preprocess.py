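"""Per-cohort genotype QC, expression filtering, rank-based inverse normal
transformation, and covariate construction.

Default thresholds follow standard imputed-genotype practice for eQTL
mapping: drop variants with MAF < 0.01, Hardy-Weinberg exact p < 1e-6,
missingness > 0.05, or imputation R2 < 0.4; drop genes whose TPM is below 1
in at least 95% of samples; use six expression and six genotype principal
components as covariates alongside sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "filter_genotypes",
    "hwe_exact_p",
    "filter_low_expression",
    "inverse_normal_transform",
    "compute_pcs",
    "build_covariates",
]


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    missingness_max: float = 0.05
    imputation_r2_min: float = 0.4
    low_expr_tpm: float = 1.0
    low_expr_sample_frac: float = 0.95
    n_expr_pcs: int = 6
    n_geno_pcs: int = 6

    def __post_init__(self):
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0.0 < self.hwe_p_min < 1.0):
            raise ValueError("hwe_p_min must lie in (0, 1)")
        if not (0.0 <= self.missingness_max <= 1.0):
            raise ValueError("missingness_max must lie in [0, 1]")
        if not (0.0 <= self.imputation_r2_min <= 1.0):
            raise ValueError("imputation_r2_min must lie in [0, 1]")
        if not (0.0 < self.low_expr_sample_frac <= 1.0):
            raise ValueError("low_expr_sample_frac must lie in (0, 1]")
        if min(self.n_expr_pcs, self.n_geno_pcs) < 0:
            raise ValueError("PC counts must be >= 0")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (two-sided exact test, no mid-p correction).  Invariant
    under allele relabelling.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # heterozygote count shares the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    # log P(n_het | allele counts) up to a shared constant
    log_p = np.array(
        [
            n_ab * np.log(2.0)
            - (lgamma(n_aa + 1) + lgamma(n_ab + 1) + lgamma(n_bb + 1))
            for n_ab, n_aa, n_bb in zip(hets, homs_minor, homs_major)
        ]
    )
    log_p -= log_p.max()
    prob = np.exp(log_p)
    prob /= prob.sum()
    observed = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= observed * (1 + 1e-12)].sum()))


def _hwe_from_dosages(column: np.ndarray) -> float:
    """HWE p from a hard-call dosage column; NaN when calls are not hard."""
    obs = column[np.isfinite(column)]
    if obs.size == 0:
        return float("nan")
    rounded = np.round(obs)
    if np.max(np.abs(obs - rounded)) > 1e-6:
        return float("nan")  # fractional dosages carry no HWE information
    counts = [(rounded == k).sum() for k in (0, 1, 2)]
    return hwe_exact_p(*counts)


# ---------------------------------------------------------------------------
# genotype filtering
# ---------------------------------------------------------------------------

def filter_genotypes(
    gm: GenotypeMatrix, th: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the variant QC screen; returns the retained matrix and an
    exclusion report (variant_id, reason, value), one row per failed check.

    Checks, in reported order: computable/non-zero MAF >= ``maf_min``,
    missingness <= ``missingness_max``, imputation R2 >= ``r2_min`` (skipped
    when the score is missing), HWE exact p >= ``hwe_p_min`` (hard calls
    only).  Idempotent: a retained matrix passes unchanged on re-filter.
    """
    maf = gm.maf()
    missing = gm.missingness()
    r2 = gm.imputation_r2()

    exclusions: list[tuple[str, str, float]] = []
    keep = np.ones(len(gm.variants), dtype=bool)
    for j, vid in enumerate(gm.variant_ids):
        if not np.isfinite(maf[j]):
            exclusions.append((vid, "maf_undefined", float("nan")))
            keep[j] = False
            continue
        if maf[j] < th.maf_min:
            exclusions.append((vid, "maf", float(maf[j])))
            keep[j] = False
            continue
        if missing[j] > th.missingness_max:
            exclusions.append((vid, "missingness", float(missing[j])))
            keep[j] = False
            continue
        if np.isfinite(r2[j]) and r2[j] < th.imputation_r2_min:
            exclusions.append((vid, "imputation_r2", float(r2[j])))
            keep[j] = False
            continue
        hwe = _hwe_from_dosages(gm.dosages[:, j])
        if np.isfinite(hwe) and hwe < th.hwe_p_min:
            exclusions.append((vid, "hwe", float(hwe)))
            keep[j] = False

    report = pd.DataFrame(exclusions, columns=["variant_id", "reason", "value"])
    filtered = gm.subset_variants(keep).with_refreshed_maf()
    return filtered, report


# ---------------------------------------------------------------------------
# expression filtering and transformation
# ---------------------------------------------------------------------------

def filter_low_expression(
    em: ExpressionMatrix, th: QcThresholds = QcThresholds()
) -> ExpressionMatrix:
    """Remove genes whose TPM is below ``low_expr_tpm`` in at least
    ``low_expr_sample_frac`` of samples (boundary inclusive).  Requires a
    TPM-tagged matrix."""
    if em.unit != "TPM":
        raise ValueError(
            f"low-expression filter requires TPM input, got unit {em.unit!r}"
        )
    frac_low = (em.values < th.low_expr_tpm).mean(axis=0)
    return em.subset_genes(frac_low < th.low_expr_sample_frac)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform of one vector:
    ``Phi^-1((rank - 0.5) / n)`` with average ranks for ties.

    Strictly monotone among untied values; the output mean is ~0 by the
    symmetry of the offset.  Missing values stay missing.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    obs = values[mask]
    if obs.size < 3:
        raise ValueError(f"need >= 3 non-missing values, got {obs.size}")
    if np.ptp(obs) == 0:
        raise ValueError("constant vector: all ranks tied")
    ranks = stats.rankdata(obs, method="average")
    out = np.full(values.shape, np.nan)
    out[mask] = stats.norm.ppf((ranks - 0.5) / obs.size)
    return out


def int_transform_matrix(em: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the inverse normal transform per gene; retags the unit INT."""
    values = np.column_stack(
        [inverse_normal_transform(em.values[:, j]) for j in range(len(em.gene_ids))]
    )
    return ExpressionMatrix(em.sample_ids, em.gene_ids, values, "INT")


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def compute_pcs(matrix: np.ndarray, k: int, prefix: str = "PC") -> pd.DataFrame:
    """Top-``k`` principal-component scores of a samples x features matrix.

    The matrix is centered per feature internally; scores come from the
    thin SVD, ordered by decreasing explained variance, mutually orthogonal.
    ``k = 0`` returns an empty frame (a valid empty covariate block).
    """
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if k == 0:
        return pd.DataFrame(index=range(n))
    if k > min(n, p):
        raise ValueError(f"k = {k} exceeds min(samples, features) = {min(n, p)}")
    centered = matrix - matrix.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(scores, columns=[f"{prefix}{i + 1}" for i in range(k)])


def standardize_dosages(gm: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, per-variant standardized dosages (for genotype PCs)."""
    d = gm.dosages.copy()
    means = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(means, inds[1])
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return (d - means) / sd


def build_covariates(
    gm: GenotypeMatrix,
    em: ExpressionMatrix,
    sex: np.ndarray | None = None,
    th: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Covariate block for the association scan: sex (if supplied), the top
    expression PCs of the INT matrix, and the top genotype PCs of
    standardized dosages.  Rows follow the expression sample order."""
    if gm.sample_ids != em.sample_ids:
        raise ValueError("genotype and expression samples are not aligned")
    blocks = []
    if sex is not None:
        sex = np.asarray(sex, dtype=float)
        if sex.shape != (em.n_samples,):
            raise ValueError("sex vector length must match the sample count")
        blocks.append(pd.DataFrame({"sex": sex}))
    n_expr = min(th.n_expr_pcs, em.n_samples - 1, len(em.gene_ids))
    n_geno = min(th.n_geno_pcs, gm.n_samples - 1, len(gm.variants))
    blocks.append(compute_pcs(em.values, n_expr, prefix="ePC"))
    blocks.append(compute_pcs(standardize_dosages(gm), n_geno, prefix="gPC"))
    out = pd.concat(blocks, axis=1)
    out.index = pd.Index(em.sample_ids)
    return out
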