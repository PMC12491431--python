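"""Replication of discovery trans loci in an independent cohort.

Two criteria, reported side by side:

1. the discovery lead variant-gene pair is nominally significant
   (p < 0.05) in the replication cohort with a concordant direction of
   effect;
2. the Storey pi1 statistic over the replication p-values of the locus's
   discovery FDR-5% target genes exceeds 0.5 (pi1 estimates the proportion
   of truly non-null associations in the set).

Criterion 1 is the primary verdict; criterion 2 is always reported
alongside, and decides alone only when the lead pair is absent from the
replication data.  Alleles are harmonized by flipping beta when ref/alt are
swapped; strand-ambiguous (A/T, C/G) variants are excluded rather than
guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .io import parse_variant_id

__all__ = [
    "ReplicationResult",
    "harmonize_effect",
    "lead_pair_replicates",
    "storey_pi0",
    "storey_pi1",
    "locus_replicates",
    "replicate_loci",
]


@dataclass
class ReplicationResult:
    locus_id: str
    lead_variant_id: str
    lead_gene: str
    lead_pair_p_rep: float  # NaN when the pair is missing
    lead_beta_rep: float
    lead_sign_concordant: bool | None
    criterion1_pass: bool | None  # None = pair missing in replication
    pi1: float
    n_target_p_used: int
    criterion2_pass: bool
    verdict: str  # replicated | not_replicated | deferred-to-criterion-2

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1


def harmonize_effect(
    disc_ref: str, disc_alt: str, rep_ref: str, rep_alt: str, rep_beta: float
) -> float | None:
    """Replication beta on the discovery allele orientation.

    Returns None when the variant is strand-ambiguous (A/T or C/G) or the
    allele pairs do not match either orientation.
    """
    if {disc_ref, disc_alt} in ({"A", "T"}, {"C", "G"}):
        return None
    if (rep_ref, rep_alt) == (disc_ref, disc_alt):
        return rep_beta
    if (rep_ref, rep_alt) == (disc_alt, disc_ref):
        return -rep_beta
    return None


def lead_pair_replicates(
    beta_discovery: float, beta_rep: float, p_rep: float, alpha: float = 0.05
) -> bool:
    """Nominal significance with concordant effect direction."""
    return bool(p_rep < alpha and np.sign(beta_rep) == np.sign(beta_discovery))


def storey_pi0(pvalues, lambda_fixed: float | None = None) -> float:
    """Storey estimate of the null proportion pi0.

    pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    grid lambda = 0.05, 0.10, ..., 0.95, smoothed by a cubic smoothing
    spline and read off at lambda = 0.95.  For fewer than 100 p-values the
    grid estimate is unstable and a fixed lambda = 0.5 is used instead.
    The result is clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if lambda_fixed is None and m < 100:
        lambda_fixed = 0.5
    if lambda_fixed is not None:
        pi0 = (p > lambda_fixed).sum() / (m * (1 - lambda_fixed))
        return float(np.clip(pi0, 0.0, 1.0))
    grid = np.arange(0.05, 0.96, 0.05)
    pi0_grid = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
    # heavily smoothed (~3 effective df) cubic, inverse-variance weighted:
    # var(pi0_hat(lambda)) ~ lambda / (m (1 - lambda)), so the noisy
    # estimates near lambda = 0.95 carry less weight in the trend
    weights = np.sqrt((1.0 - grid) / grid)
    spline = UnivariateSpline(grid, pi0_grid, w=weights, k=3,
                              s=float(len(grid)))
    return float(np.clip(spline(grid[-1]), 0.0, 1.0))


def storey_pi1(pvalues, **kwargs) -> float:
    """pi1 = 1 - pi0: estimated proportion of non-null replication
    p-values.  Invariant to permutation of the input."""
    return 1.0 - storey_pi0(pvalues, **kwargs)


def locus_replicates(
    criterion1: bool | None, pi1: float, pi1_threshold: float = 0.5
) -> tuple[bool, str]:
    """Combine the two criteria into a verdict.

    Criterion 1 is primary; when the lead pair is missing (criterion1 is
    None) the verdict defers to criterion 2.  Both flags are surfaced in
    the result table regardless of the verdict.
    """
    criterion2 = bool(pi1 > pi1_threshold)
    if criterion1 is None:
        return criterion2, "deferred-to-criterion-2"
    return bool(criterion1), ("replicated" if criterion1 else "not_replicated")


def replicate_loci(
    locus_summary: pd.DataFrame,
    fdr_targets: dict[str, pd.DataFrame],
    replication_stats: pd.DataFrame,
    pi1_threshold: float = 0.5,
) -> pd.DataFrame:
    """Evaluate every candidate locus in a replication summary table.

    ``fdr_targets`` maps locus_id to its discovery FDR table (gene_id /
    significant columns); ``replication_stats`` is a per-cohort summary
    table from the replication dataset.
    """
    rep = replication_stats.set_index(["variant_id", "gene_id"])
    rows = []
    for locus in locus_summary.itertuples():
        disc_ref, disc_alt = parse_variant_id(locus.lead_variant_id)[2:]
        lead_key = (locus.lead_variant_id, locus.lead_gene)
        c1: bool | None = None
        p_rep = float("nan")
        beta_rep = float("nan")
        concordant: bool | None = None
        if lead_key in rep.index:
            r = rep.loc[lead_key]
            harmonized = harmonize_effect(
                disc_ref, disc_alt, str(r["ref"]), str(r["alt"]), float(r["beta"])
            )
            if harmonized is not None:
                beta_rep = harmonized
                p_rep = float(r["pvalue"])
                concordant = bool(
                    np.sign(beta_rep) == np.sign(float(locus.lead_beta))
                )
                c1 = lead_pair_replicates(
                    float(locus.lead_beta), beta_rep, p_rep
                )

        targets = fdr_targets.get(locus.locus_id)
        target_genes = (
            targets.loc[targets["significant"], "gene_id"].tolist()
            if targets is not None
            else []
        )
        rep_at_lead = replication_stats[
            (replication_stats["variant_id"] == locus.lead_variant_id)
            & replication_stats["gene_id"].isin(target_genes)
        ]
        target_p = rep_at_lead["pvalue"].to_numpy()
        pi1 = storey_pi1(target_p) if target_p.size else float("nan")
        c2 = bool(pi1 > pi1_threshold) if np.isfinite(pi1) else False
        verdict_pass, verdict = (
            locus_replicates(c1, pi1 if np.isfinite(pi1) else 0.0, pi1_threshold)
        )
        rows.append(
            {
                "locus_id": locus.locus_id,
                "lead_variant_id": locus.lead_variant_id,
                "lead_gene": locus.lead_gene,
                "lead_pair_p_rep": p_rep,
                "lead_beta_rep": beta_rep,
                "lead_sign_concordant": concordant,
                "criterion1_pass": c1,
                "pi1": pi1,
                "pi0": 1.0 - pi1 if np.isfinite(pi1) else float("nan"),
                "n_target_p_used": int(target_p.size),
                "criterion2_pass": c2,
                "replicated": verdict_pass,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)
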