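"""End-to-end orchestration: QC -> scan -> meta -> loci -> replication ->
colocalisation, with deterministic seeds and reproducible artifacts.

Every written artifact is accompanied by a manifest (config hash, seed,
package version, row counts) so a rerun with the same configuration is
byte-identical.  The per-stage functions are importable on in-memory
objects; the file-driven entry points wrap them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    CrossmapTable,
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    write_summary_stats,
)
from .association import ols_scan
from .coloc import ColocConfig, ColocResult, coloc_abf, poemcoloc_impute
from .loci import (
    LocusThresholds,
    TransLocus,
    aggregate_loci,
    call_candidate_loci,
    clump_per_gene,
    is_trans_table,
    locus_report,
    per_locus_fdr,
)
from .meta import meta_analyse
from .preprocess import (
    QcThresholds,
    build_covariates,
    filter_genotypes,
    filter_low_expression,
    int_transform_matrix,
)
from .replication import replicate_loci

__all__ = [
    "CohortData",
    "PipelineConfig",
    "DiscoveryResult",
    "prepare_cohort",
    "run_discovery",
    "run_replication",
    "run_coloc",
    "load_pipeline_config",
]


@dataclass
class CohortData:
    """One cohort's aligned genotype, expression and covariate inputs."""

    cohort_id: str
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    sex: np.ndarray | None = None

    def aligned(self) -> "CohortData":
        """Restrict to the genotype/expression sample intersection,
        preserving expression order."""
        shared = [s for s in self.expression.sample_ids
                  if s in set(self.genotypes.sample_ids)]
        if not shared:
            raise ValueError(
                f"cohort {self.cohort_id}: zero overlapping samples between "
                "genotypes and expression"
            )
        sex = self.sex
        if sex is not None:
            index = {s: i for i, s in enumerate(self.expression.sample_ids)}
            sex = np.asarray(sex, dtype=float)[[index[s] for s in shared]]
        return CohortData(
            self.cohort_id,
            self.genotypes.subset_samples(shared),
            self.expression.subset_samples(shared),
            sex,
        )


@dataclass
class PipelineConfig:
    seed: int
    cohorts: dict[str, dict[str, str]] = field(default_factory=dict)
    annotation: str | None = None
    crossmap: str | None = None
    replication: dict[str, str] | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    loci: LocusThresholds = field(default_factory=LocusThresholds)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    out_dir: str | None = None


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "seed" not in doc:
        raise ValueError(f"{path}: pipeline config must state a seed")
    return PipelineConfig(
        seed=int(doc["seed"]),
        cohorts=doc.get("cohorts", {}),
        annotation=doc.get("annotation"),
        crossmap=doc.get("crossmap"),
        replication=doc.get("replication"),
        qc=QcThresholds(**doc.get("qc", {})),
        loci=LocusThresholds(**doc.get("loci", {})),
        coloc=ColocConfig(**doc.get("coloc", {})),
        out_dir=doc.get("out_dir"),
    )


@dataclass
class DiscoveryResult:
    meta_stats: pd.DataFrame
    loci: list[TransLocus]
    locus_summary: pd.DataFrame
    locus_members: pd.DataFrame
    fdr_targets: dict[str, pd.DataFrame]
    exclusions: dict[str, pd.DataFrame]
    scans: dict[str, pd.DataFrame]
    funnel: dict[str, int]

    @property
    def candidates(self) -> pd.DataFrame:
        if self.locus_summary.empty:
            return self.locus_summary
        return self.locus_summary[self.locus_summary["is_candidate"]]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def prepare_cohort(
    cohort: CohortData, qc: QcThresholds = QcThresholds()
) -> tuple[CohortData, pd.DataFrame, pd.DataFrame]:
    """QC one cohort: align samples, filter variants, filter low-expressed
    genes (TPM input only), inverse-normal transform, build covariates.

    Returns the prepared cohort (expression retagged INT), the variant
    exclusion report, and the covariate table.
    """
    cohort = cohort.aligned()
    gm, exclusions = filter_genotypes(cohort.genotypes, qc)
    if not gm.variants:
        raise ValueError(
            f"cohort {cohort.cohort_id}: no variants survive genotype QC"
        )
    em = cohort.expression
    if em.unit == "TPM":
        em = filter_low_expression(em, qc)
    if em.unit != "INT":
        em = int_transform_matrix(em)
    covariates = build_covariates(gm, em, cohort.sex, qc)
    return CohortData(cohort.cohort_id, gm, em, cohort.sex), exclusions, covariates


def scan_cohort(cohort: CohortData, covariates: pd.DataFrame) -> pd.DataFrame:
    return ols_scan(cohort.genotypes, cohort.expression, covariates,
                    cohort_id=cohort.cohort_id)


def run_discovery(
    cohorts: list[CohortData],
    annotation: dict[str, GeneRecord],
    crossmap: CrossmapTable | None = None,
    qc: QcThresholds = QcThresholds(),
    loci_th: LocusThresholds = LocusThresholds(),
    out_dir: str | Path | None = None,
    config_label: str = "",
    seed: int | None = None,
) -> DiscoveryResult:
    """The discovery pipeline: per-cohort QC and scan, inverse-variance and
    random-effects meta-analysis, cis/trans assignment, clumping, locus
    aggregation, cross-mappability filtering, candidacy calls and per-locus
    FDR target sets.

    When ``out_dir`` is given, writes stage artifacts plus a manifest;
    reruns with identical inputs produce byte-identical files.
    """
    if not cohorts:
        raise ValueError("at least one cohort is required")

    exclusions: dict[str, pd.DataFrame] = {}
    scans: dict[str, pd.DataFrame] = {}
    for cohort in cohorts:
        prepared, excl, covariates = prepare_cohort(cohort, qc)
        exclusions[cohort.cohort_id] = excl
        scans[cohort.cohort_id] = scan_cohort(prepared, covariates)

    meta_stats = meta_analyse(list(scans.values()), random_effects=True)

    trans_mask = is_trans_table(meta_stats, annotation, loci_th)
    trans_stats = meta_stats[trans_mask]
    leads = []
    for gid, grp in trans_stats.groupby("gene_id", sort=True):
        leads.append(clump_per_gene(grp, loci_th))
    lead_table = (
        pd.concat(leads, ignore_index=True) if leads else trans_stats.head(0)
    )

    loci = aggregate_loci(lead_table, trans_stats, annotation, loci_th)
    loci = call_candidate_loci(loci, annotation, crossmap, loci_th)
    locus_summary, locus_members = locus_report(loci)

    fdr_targets: dict[str, pd.DataFrame] = {}
    if not locus_summary.empty:
        for row in locus_summary.itertuples():
            if row.is_candidate:
                fdr_targets[row.locus_id] = per_locus_fdr(
                    row.lead_variant_id, meta_stats, annotation, loci_th
                )

    funnel = {
        "cohorts": len(cohorts),
        "pairs_meta": len(meta_stats),
        "pairs_trans": int(trans_mask.sum()),
        "gene_leads": len(lead_table),
        "loci": len(loci),
        "candidate_loci": int(locus_summary["is_candidate"].sum())
        if not locus_summary.empty else 0,
    }

    result = DiscoveryResult(
        meta_stats, loci, locus_summary, locus_members,
        fdr_targets, exclusions, scans, funnel,
    )
    if out_dir is not None:
        _write_discovery(result, Path(out_dir), config_label, seed)
    return result


def _write_discovery(result: DiscoveryResult, out_dir: Path,
                     config_label: str, seed: int | None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_summary_stats(result.meta_stats, out_dir / "meta_stats.tsv")
    write_summary_stats(result.locus_summary, out_dir / "locus_summary.tsv")
    write_summary_stats(result.locus_members, out_dir / "locus_members.tsv")
    excl = (
        pd.concat(
            [df.assign(cohort_id=c) for c, df in result.exclusions.items()],
            ignore_index=True,
        )
        if result.exclusions
        else pd.DataFrame(columns=["variant_id", "reason", "value", "cohort_id"])
    )
    write_summary_stats(excl, out_dir / "exclusions.tsv")
    for locus_id, table in result.fdr_targets.items():
        write_summary_stats(table, out_dir / f"fdr_targets_{locus_id}.tsv")
    manifest = {
        "stage": "discovery",
        "config_hash": hashlib.sha256(config_label.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "funnel": result.funnel,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def run_replication(
    discovery: DiscoveryResult,
    replication_cohort: CohortData,
    qc: QcThresholds = QcThresholds(),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Evaluate every candidate locus in an independent cohort.

    The replication cohort is QC'd and scanned only at the candidate lead
    variants; both replication criteria (lead-pair nominal significance
    with concordant sign, and Storey pi1 over discovery FDR targets) are
    reported per locus.
    """
    candidates = discovery.candidates
    if candidates.empty:
        return pd.DataFrame(
            columns=["locus_id", "lead_variant_id", "lead_gene",
                     "lead_pair_p_rep", "lead_beta_rep", "lead_sign_concordant",
                     "criterion1_pass", "pi1", "pi0", "n_target_p_used",
                     "criterion2_pass", "replicated", "verdict"]
        )
    prepared, _, covariates = prepare_cohort(replication_cohort, qc)
    lead_ids = set(candidates["lead_variant_id"])
    keep = [v in lead_ids for v in prepared.genotypes.variant_ids]
    if not any(keep):
        raise ValueError(
            "replication cohort shares no variants with the candidate leads"
        )
    gm = prepared.genotypes.subset_variants(np.array(keep))
    rep_stats = ols_scan(gm, prepared.expression, covariates,
                         cohort_id=replication_cohort.cohort_id)
    table = replicate_loci(candidates, discovery.fdr_targets, rep_stats)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_summary_stats(table, out_dir / "replication.tsv")
    return table


def run_coloc(
    discovery: DiscoveryResult,
    locus_id: str,
    gwas_stats: pd.DataFrame,
    config: ColocConfig = ColocConfig(),
    trait2: str = "case-control",
    ld_panel: GenotypeMatrix | None = None,
    loci_th: LocusThresholds = LocusThresholds(),
) -> ColocResult:
    """Colocalise one candidate locus's lead-gene signal with a GWAS signal.

    The eQTL side is the meta-analysis profile of the locus's lead gene in
    the +/-``clump_radius`` region around the lead variant.  ``gwas_stats``
    is either a full regional table (variant_id / beta / se) or a single
    lead-variant row, in which case an LD panel is required and the profile
    is imputed.
    """
    summary = discovery.locus_summary
    row = summary[summary["locus_id"] == locus_id]
    if row.empty:
        raise ValueError(f"unknown locus {locus_id!r}")
    row = row.iloc[0]
    ms = discovery.meta_stats
    region = ms[
        (ms["gene_id"] == row["lead_gene"])
        & (ms["chrom"] == row["chrom"])
        & ((ms["pos"] - row["pos"]).abs() <= loci_th.clump_radius)
    ][["variant_id", "beta_fixed", "se_fixed"]].rename(
        columns={"beta_fixed": "beta", "se_fixed": "se"}
    )
    if len(gwas_stats) == 1 and ld_panel is not None:
        lead = gwas_stats.iloc[0]
        z = float(lead["beta"] / lead["se"]) if "se" in gwas_stats else float(lead["z"])
        gwas_stats = poemcoloc_impute(
            str(lead["variant_id"]), z, ld_panel, int(lead.get("n", 10000))
        )
    return coloc_abf(region, gwas_stats, config, "quantitative", trait2)
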