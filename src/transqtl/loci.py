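"""From genome-wide meta statistics to candidate trans loci.

The funnel: assign pairs to cis/trans by a +/-5 Mb window around the gene
body; clump each gene's trans associations to independent lead variants by
greedily removing everything within +/-1.5 Mb of the best remaining variant
(down to a suggestive lead threshold of 1e-11); merge leads across genes
into loci by the same radius; flag each member target that shares high
cross-mappability (score >= 1) with any protein-coding gene in the +/-1.5 Mb
cis region of the locus lead; and call a locus a candidate when its lead
passes 1e-11 and at least five crossmap-clean targets pass 5e-8.  Per-locus
target sets are then defined by Benjamini-Hochberg FDR over all non-cis
genes tested at the lead variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CrossmapTable, GeneRecord
from .enrichment import bh_adjust

__all__ = [
    "LocusThresholds",
    "TransLocus",
    "classify_cis_trans",
    "is_trans_table",
    "clump_per_gene",
    "aggregate_loci",
    "crossmap_filter",
    "call_candidate_loci",
    "per_locus_fdr",
    "locus_report",
]


@dataclass(frozen=True)
class LocusThresholds:
    cis_window: float = 5_000_000.0
    clump_radius: float = 1_500_000.0
    lead_p_max: float = 1e-11
    target_p_max: float = 5e-8
    min_targets: int = 5
    crossmap_max: float = 1.0  # fail when score >= this
    fdr_level: float = 0.05

    def __post_init__(self):
        if min(self.cis_window, self.clump_radius) < 0:
            raise ValueError("windows must be non-negative")
        for p in (self.lead_p_max, self.target_p_max, self.fdr_level):
            if not (0 < p <= 1):
                raise ValueError("probability thresholds must lie in (0, 1]")
        if self.min_targets < 1:
            raise ValueError("min_targets must be >= 1")


@dataclass
class TransLocus:
    """One clumped trans locus with its member target genes.

    ``members`` has one row per target gene with columns gene_id, pvalue,
    beta, crossmap_pass, crossmap_reason; ``lead_p`` is the minimum member
    p at the lead variant.
    """

    lead_variant_id: str
    chrom: str
    pos: int
    lead_gene: str
    lead_p: float
    members: pd.DataFrame
    nearest_cis_gene: str | None = None
    n_targets_sig: int = 0
    is_candidate: bool = False
    fdr_targets: pd.DataFrame | None = field(default=None, repr=False)


def classify_cis_trans(
    chrom: str, pos: int, gene: GeneRecord, th: LocusThresholds = LocusThresholds()
) -> str:
    """``cis`` iff the variant lies on the gene's chromosome within
    ``cis_window`` of the gene body (inclusive boundary, 0 inside), else
    ``trans``."""
    if gene is None:
        raise ValueError("gene has no annotation")
    return "cis" if gene.distance_to(chrom, pos) <= th.cis_window else "trans"


def is_trans_table(
    stats: pd.DataFrame,
    annotation: dict[str, GeneRecord],
    th: LocusThresholds = LocusThresholds(),
) -> np.ndarray:
    """Vectorized trans mask for a summary table (requires chrom/pos/gene_id)."""
    missing = set(stats["gene_id"]) - set(annotation)
    if missing:
        raise ValueError(f"unannotated gene(s): {sorted(missing)[:5]}")
    mask = np.empty(len(stats), dtype=bool)
    for i, (chrom, pos, gid) in enumerate(
        zip(stats["chrom"], stats["pos"], stats["gene_id"])
    ):
        mask[i] = annotation[gid].distance_to(str(chrom), int(pos)) > th.cis_window
    return mask


def clump_per_gene(
    stats: pd.DataFrame, th: LocusThresholds = LocusThresholds(),
    p_column: str = "p_fixed",
) -> pd.DataFrame:
    """Greedy distance clumping of one gene's trans associations.

    Repeatedly takes the smallest-p remaining variant as a lead and removes
    all variants within ``clump_radius`` on its chromosome, until no variant
    at or below ``lead_p_max`` remains.  Returns leads in selection order.
    """
    if stats.empty:
        return stats.head(0)
    work = stats.sort_values(p_column, kind="stable")
    chrom = work["chrom"].to_numpy()
    pos = work["pos"].to_numpy(dtype=float)
    pval = work[p_column].to_numpy()
    alive = np.ones(len(work), dtype=bool)
    leads: list[int] = []
    while True:
        remaining = np.flatnonzero(alive)
        if remaining.size == 0 or pval[remaining[0]] > th.lead_p_max:
            break
        lead = remaining[0]
        leads.append(lead)
        near = (chrom == chrom[lead]) & (np.abs(pos - pos[lead]) <= th.clump_radius)
        alive &= ~near
    return work.iloc[leads].reset_index(drop=True)


def aggregate_loci(
    leads: pd.DataFrame,
    meta_stats: pd.DataFrame,
    annotation: dict[str, GeneRecord],
    th: LocusThresholds = LocusThresholds(),
    p_column: str = "p_fixed",
) -> list[TransLocus]:
    """Merge per-gene leads into loci and collect member target genes.

    Leads within ``clump_radius`` of each other on one chromosome merge
    into a single locus led by the smallest-p variant.  Members are the
    genes that contributed a merged lead plus every gene with meta
    ``p < target_p_max`` at the locus lead, restricted to trans genes.
    """
    if leads.empty:
        return []
    work = leads.sort_values(p_column, kind="stable").reset_index(drop=True)
    alive = np.ones(len(work), dtype=bool)
    loci: list[TransLocus] = []
    by_variant = dict(tuple(meta_stats.groupby("variant_id", sort=False)))
    for i in range(len(work)):
        if not alive[i]:
            continue
        lead = work.iloc[i]
        same = (
            (work["chrom"] == lead["chrom"])
            & ((work["pos"] - lead["pos"]).abs() <= th.clump_radius)
            & alive
        )
        merged = work[same]
        alive &= ~same.to_numpy()

        member_genes = set(merged["gene_id"])
        at_lead = by_variant.get(lead["variant_id"], meta_stats.head(0))
        at_lead = at_lead[
            is_trans_table(at_lead, annotation, th)
        ] if not at_lead.empty else at_lead
        member_genes |= set(at_lead.loc[at_lead[p_column] < th.target_p_max,
                                        "gene_id"])
        rows = at_lead[at_lead["gene_id"].isin(member_genes)]
        members = pd.DataFrame(
            {
                "gene_id": rows["gene_id"].to_numpy(),
                "pvalue": rows[p_column].to_numpy(),
                "beta": rows["beta_fixed"].to_numpy()
                if "beta_fixed" in rows else rows["beta"].to_numpy(),
            }
        ).sort_values("pvalue", kind="stable", ignore_index=True)

        lead_p = float(members["pvalue"].min()) if not members.empty else float(lead[p_column])
        lead_gene = (
            str(members.iloc[0]["gene_id"]) if not members.empty else str(lead["gene_id"])
        )
        loci.append(
            TransLocus(
                lead_variant_id=str(lead["variant_id"]),
                chrom=str(lead["chrom"]),
                pos=int(lead["pos"]),
                lead_gene=lead_gene,
                lead_p=lead_p,
                members=members,
                nearest_cis_gene=_nearest_cis_gene(
                    str(lead["chrom"]), int(lead["pos"]), annotation
                ),
            )
        )
    loci.sort(key=lambda l: l.lead_p)
    return loci


def _nearest_cis_gene(chrom, pos, annotation) -> str | None:
    best, best_d = None, float("inf")
    for gene in annotation.values():
        d = gene.distance_to(chrom, pos)
        if d < best_d:
            best, best_d = gene.gene_id, d
    return best


def crossmap_filter(
    target_gene: str,
    lead_chrom: str,
    lead_pos: int,
    annotation: dict[str, GeneRecord],
    crossmap: CrossmapTable | None,
    th: LocusThresholds = LocusThresholds(),
) -> tuple[bool, str | None]:
    """Cross-mappability screen for one target at one locus lead.

    Fails iff any protein-coding gene overlapping the +/-``clump_radius``
    window around the lead has symmetrized crossmap score >= ``crossmap_max``
    with the target; returns (pass, offending cis gene or None).  A missing
    crossmap table passes everything (filter disabled).
    """
    if crossmap is None:
        return True, None
    for gene in annotation.values():
        if gene.biotype != "protein_coding":
            continue
        if gene.distance_to(lead_chrom, lead_pos) > th.clump_radius:
            continue
        if crossmap.score(target_gene, gene.gene_id) >= th.crossmap_max:
            return False, gene.gene_id
    return True, None


def call_candidate_loci(
    loci: list[TransLocus],
    annotation: dict[str, GeneRecord],
    crossmap: CrossmapTable | None,
    th: LocusThresholds = LocusThresholds(),
) -> list[TransLocus]:
    """Annotate each locus with crossmap flags and candidacy.

    A locus is a candidate iff its lead p <= ``lead_p_max`` and at least
    ``min_targets`` member genes pass both ``target_p_max`` and the
    crossmap screen.  Mutates and returns the loci list.
    """
    for locus in loci:
        passes, reasons = [], []
        for gid in locus.members["gene_id"]:
            ok, reason = crossmap_filter(
                gid, locus.chrom, locus.pos, annotation, crossmap, th
            )
            passes.append(ok)
            reasons.append(reason)
        locus.members["crossmap_pass"] = passes
        locus.members["crossmap_reason"] = reasons
        sig = (locus.members["pvalue"] < th.target_p_max) & locus.members[
            "crossmap_pass"
        ]
        locus.n_targets_sig = int(sig.sum())
        locus.is_candidate = (
            locus.lead_p <= th.lead_p_max and locus.n_targets_sig >= th.min_targets
        )
    return loci


def per_locus_fdr(
    lead_variant_id: str,
    meta_stats: pd.DataFrame,
    annotation: dict[str, GeneRecord],
    th: LocusThresholds = LocusThresholds(),
    p_column: str = "p_fixed",
) -> pd.DataFrame:
    """Benjamini-Hochberg target set at one locus lead.

    The universe is every gene tested at the lead variant minus genes in
    the lead's cis window; returns the universe with q-values and a
    ``significant`` flag at ``fdr_level`` (possibly empty target set).
    """
    at_lead = meta_stats[meta_stats["variant_id"] == lead_variant_id]
    if at_lead.empty:
        raise ValueError(f"no statistics at lead variant {lead_variant_id!r}")
    at_lead = at_lead[is_trans_table(at_lead, annotation, th)]
    if at_lead.empty:
        raise ValueError(
            f"empty testing universe at {lead_variant_id!r} after removing "
            "cis-window genes"
        )
    out = at_lead[["gene_id", p_column]].rename(columns={p_column: "pvalue"})
    out = out.sort_values("pvalue", kind="stable", ignore_index=True)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["qvalue"] <= th.fdr_level
    return out


def locus_report(loci: list[TransLocus]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten loci into (summary, per-target) tables for writing."""
    summary_rows, member_rows = [], []
    for i, locus in enumerate(loci, start=1):
        locus_id = f"locus{i:02d}"
        summary_rows.append(
            {
                "locus_id": locus_id,
                "lead_variant_id": locus.lead_variant_id,
                "chrom": locus.chrom,
                "pos": locus.pos,
                "lead_gene": locus.lead_gene,
                "lead_p": locus.lead_p,
                "lead_beta": (
                    float(locus.members.iloc[0]["beta"])
                    if not locus.members.empty
                    else float("nan")
                ),
                "n_members": len(locus.members),
                "n_targets_sig": locus.n_targets_sig,
                "is_candidate": locus.is_candidate,
                "nearest_cis_gene": locus.nearest_cis_gene,
            }
        )
        m = locus.members.copy()
        m.insert(0, "locus_id", locus_id)
        m.insert(1, "lead_variant_id", locus.lead_variant_id)
        member_rows.append(m)
    summary = pd.DataFrame(summary_rows)
    members = (
        pd.concat(member_rows, ignore_index=True)
        if member_rows
        else pd.DataFrame(
            columns=["locus_id", "lead_variant_id", "gene_id", "pvalue",
                     "beta", "crossmap_pass", "crossmap_reason"]
        )
    )
    return summary, members
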