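"""Multi-cohort synthetic data with planted cis-mediated trans networks.

The generator emulates the statistical structure a multi-cohort trans-eQTL
analysis assumes: several cohorts of unequal size genotyped on a shared
variant panel (binomial dosages with per-variant MAF and imputation-quality
scores), and expression built from covariate structure (sex, cohort batch
offsets, latent technical factors), cis effects, regulator-mediated trans
networks, read-leakage contamination, and Gaussian noise.

Trans effects are mediated: the regulator gene R receives a cis effect
``y_R = beta_cis * g_v + ...`` and each target k receives
``y_k = gamma_k * y_R + ...``, so the marginal per-allele slope of target k
on the variant is ``beta_cis * gamma_k``.  Each gene's within-cohort
variance is normalised to 1, so planted marginal slopes are in phenotype-SD
units per alt allele and survive the rank-based inverse normal transform
essentially unchanged.

Every planted (variant, gene) pair is recorded in a :class:`TrueModel`
ledger so recovery can be tested without re-deriving ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import (
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    CrossmapTable,
    VariantRecord,
    format_variant_id,
)

__all__ = [
    "CisEffect",
    "TransNetwork",
    "Contamination",
    "SimulationConfig",
    "TrueModel",
    "build_panel",
    "simulate_genotypes",
    "simulate_expression",
    "plant_crossmap_artifact",
    "simulate_gwas_region",
    "default_config",
    "null_config",
]


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-stage generator fanned out from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CisEffect:
    """A planted cis effect: per-allele slope of a local gene on a variant."""

    variant_id: str
    gene_id: str
    beta: float


@dataclass
class TransNetwork:
    """A cis-mediated trans regulatory network.

    The regulator gene sits in cis of ``variant_id`` with slope ``beta_cis``;
    each target's marginal slope on the variant is ``marginal_slopes[k]``
    (so the regulator-to-target slope is ``marginal_slopes[k] / beta_cis``).
    """

    variant_id: str
    regulator_gene: str
    beta_cis: float
    targets: list[str]
    marginal_slopes: list[float]

    def __post_init__(self):
        if len(self.targets) != len(self.marginal_slopes):
            raise ValueError("one marginal slope per target required")
        if abs(self.beta_cis) < 1e-12:
            raise ValueError("beta_cis must be non-zero for a mediated network")


@dataclass
class Contamination:
    """Read-leakage artifact: a fraction of a strong cis gene's signal leaks
    into unrelated target genes, faking a trans association at the cis
    variant."""

    variant_id: str
    source_gene: str
    source_cis_beta: float
    targets: list[str]
    leakage: float
    crossmap_score: float = 5.0

    def __post_init__(self):
        if not (0.0 <= self.leakage < 1.0):
            raise ValueError(f"leakage must lie in [0, 1), got {self.leakage}")
        if self.source_gene in self.targets:
            raise ValueError("contamination target equals its source gene")


@dataclass
class SimulationConfig:
    """Full description of a synthetic multi-cohort study.

    Defaults are the desk-scale study conditions used throughout the test
    suite: three cohorts of 200 samples on a shared panel of independent
    variants spread over four chromosomes.
    """

    seed: int
    n_samples: tuple[int, ...] = (200, 200, 200)
    n_variants: int = 480
    n_genes: int = 400
    n_chromosomes: int = 4
    variant_spacing: int = 400_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf_overrides: dict[str, float] = field(default_factory=dict)
    ld_rho: float = 0.0  # haplotype copying prob between adjacent variants
    cis_effects: list[CisEffect] = field(default_factory=list)
    networks: list[TransNetwork] = field(default_factory=list)
    contaminations: list[Contamination] = field(default_factory=list)
    n_latent: int = 6
    latent_var: float = 0.3  # per-gene variance from latent technical factors
    sex_effect: float = 0.5
    sex_gene_frac: float = 0.1
    batch_sd: float = 0.3  # per-cohort per-gene constant offsets
    noise_floor: float = 0.05  # minimum residual variance per gene

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if any(n < 1 for n in self.n_samples):
            raise ValueError("cohort sizes must be >= 1")
        if min(self.n_variants, self.n_genes, self.n_chromosomes) < 1:
            raise ValueError("panel sizes must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")

    @property
    def n_cohorts(self) -> int:
        return len(self.n_samples)

    @property
    def cohort_ids(self) -> list[str]:
        return [f"cohort{i + 1}" for i in range(self.n_cohorts)]

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["n_samples"] = list(self.n_samples)
        doc["maf_range"] = list(self.maf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError(f"{path}: simulation config must state a seed")
        doc["n_samples"] = tuple(doc["n_samples"])
        doc["maf_range"] = tuple(doc["maf_range"])
        doc["cis_effects"] = [CisEffect(**d) for d in doc.get("cis_effects", [])]
        doc["networks"] = [TransNetwork(**d) for d in doc.get("networks", [])]
        doc["contaminations"] = [
            Contamination(**d) for d in doc.get("contaminations", [])
        ]
        return cls(**doc)


@dataclass
class TrueModel:
    """Ground-truth ledger: every planted (variant, gene) pair with its
    marginal slope; anything not listed is null."""

    cis_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    trans_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    artifact_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        keys = [(v, g) for v, g, _ in
                self.cis_pairs + self.trans_pairs + self.artifact_pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("planted pair categories must be disjoint")

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {
            (v, g)
            for v, g, _ in self.cis_pairs + self.trans_pairs + self.artifact_pairs
        }

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("cis", v, g, s) for v, g, s in self.cis_pairs]
            + [("trans", v, g, s) for v, g, s in self.trans_pairs]
            + [("artifact", v, g, s) for v, g, s in self.artifact_pairs]
        )
        return pd.DataFrame(
            rows, columns=["kind", "variant_id", "gene_id", "marginal_slope"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# panel layout
# ---------------------------------------------------------------------------

def build_panel(config: SimulationConfig) -> tuple[list[VariantRecord], list[GeneRecord]]:
    """Deterministic variant/gene placement plus MAF and imputation-R2 draws.

    Variants are laid out in contiguous per-chromosome blocks at fixed
    spacing; gene ``j`` sits 50 kb downstream of variant ``j`` (its local
    cis variant).  MAFs are uniform on ``maf_range`` except for explicit
    overrides; imputation R2 is Beta(8, 1) (median ~0.92, rare low-quality
    variants that the QC screen removes).
    """
    rng = child_rng(config.seed, 0)
    per_chrom = -(-config.n_variants // config.n_chromosomes)  # ceil
    mafs = rng.uniform(*config.maf_range, size=config.n_variants)
    r2 = rng.beta(8.0, 1.0, size=config.n_variants)

    variants: list[VariantRecord] = []
    for j in range(config.n_variants):
        chrom = f"chr{j // per_chrom + 1}"
        pos = 1_000_000 + (j % per_chrom) * config.variant_spacing
        vid = format_variant_id(chrom, pos, "A", "G")
        maf = config.maf_overrides.get(vid, float(mafs[j]))
        variants.append(
            VariantRecord(chrom, pos, "A", "G", maf=maf,
                          imputation_r2=float(r2[j]))
        )

    if config.n_genes > config.n_variants:
        raise ValueError("panel layout requires n_genes <= n_variants")
    genes: list[GeneRecord] = []
    for g in range(config.n_genes):
        v = variants[local_variant_of(config, g)]
        start = v.pos + 50_000
        genes.append(
            GeneRecord(f"GENE{g + 1:04d}", v.chrom, start, start + 20_000)
        )
    return variants, genes


def local_variant_of(config: SimulationConfig, gene_index: int) -> int:
    """Index of the cis variant paired with gene ``gene_index``.

    Genes are spread evenly over chromosomes: gene blocks mirror the
    variant blocks, so each chromosome carries ~n_genes/n_chromosomes genes
    regardless of rounding in the variant layout.
    """
    per_chrom_var = -(-config.n_variants // config.n_chromosomes)
    per_chrom_gene = -(-config.n_genes // config.n_chromosomes)
    c, j = divmod(gene_index, per_chrom_gene)
    stride = max(1, per_chrom_var // per_chrom_gene)
    idx = c * per_chrom_var + j * stride
    if idx >= config.n_variants or j * stride >= per_chrom_var:
        raise ValueError(
            f"gene {gene_index} does not fit the panel layout; increase "
            "n_variants or n_chromosomes"
        )
    return idx


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> dict[str, GenotypeMatrix]:
    """Per-cohort hard-call dosages on the shared panel.

    With ``ld_rho = 0`` variants are independent Binomial(2, MAF) draws.
    With ``ld_rho > 0`` haplotypes follow a Markov copying scheme along each
    chromosome: each haplotype allele copies its left neighbour with
    probability ``ld_rho``, giving block LD that decays with distance.
    """
    variants, _ = build_panel(config)
    mafs = np.array([v.maf for v in variants])
    chroms = np.array([v.chrom for v in variants])
    out: dict[str, GenotypeMatrix] = {}
    for c, (cohort, n) in enumerate(zip(config.cohort_ids, config.n_samples)):
        rng = child_rng(config.seed, 1, c)
        if config.ld_rho == 0.0:
            dosages = rng.binomial(2, mafs, size=(n, len(variants))).astype(float)
        else:
            dosages = _markov_haplotypes(rng, n, mafs, chroms, config.ld_rho)
        sample_ids = [f"{cohort}_s{i + 1:04d}" for i in range(n)]
        out[cohort] = GenotypeMatrix(sample_ids, variants, dosages)
    return out


def _markov_haplotypes(rng, n, mafs, chroms, rho) -> np.ndarray:
    haps = np.empty((2, n, len(mafs)))
    for h in range(2):
        col = rng.random(n) < mafs[0]
        haps[h, :, 0] = col
        for j in range(1, len(mafs)):
            fresh = rng.random(n) < mafs[j]
            if chroms[j] != chroms[j - 1]:
                col = fresh
            else:
                copy = rng.random(n) < rho
                col = np.where(copy, haps[h, :, j - 1], fresh)
            haps[h, :, j] = col
    return haps.sum(axis=0)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _variance_budget(config, gene_ids, latent_contrib, sex_genes, var_genetic):
    """Residual noise variance per gene so total within-cohort variance is 1."""
    var = np.ones(len(gene_ids)) - latent_contrib - var_genetic
    var[[g in sex_genes for g in gene_ids]] -= config.sex_effect**2 * 0.25
    low = var < config.noise_floor
    if low.any():
        warnings.warn(
            "planted effects leave less residual variance than the noise "
            f"floor for {int(low.sum())} gene(s); clamping",
            stacklevel=3,
        )
        var[low] = config.noise_floor
    return var


def simulate_expression(
    genotypes: dict[str, GenotypeMatrix], config: SimulationConfig
) -> tuple[dict[str, ExpressionMatrix], TrueModel]:
    """Per-cohort expression with planted cis and mediated trans effects.

    Returns the cohort expression matrices (unit ``normalized``) and the
    :class:`TrueModel` ledger of every planted pair.  Contamination is *not*
    applied here; see :func:`plant_crossmap_artifact`.
    """
    variants, genes = build_panel(config)
    vid_index = {v.variant_id: i for i, v in enumerate(variants)}
    gid_index = {g.gene_id: i for i, g in enumerate(genes)}
    gene_ids = [g.gene_id for g in genes]
    gene_by_id = {g.gene_id: g for g in genes}

    for net in config.networks:
        chrom, pos, _, _ = (variants[vid_index[net.variant_id]].chrom,
                            variants[vid_index[net.variant_id]].pos, None, None)
        for t in net.targets:
            if gene_by_id[t].distance_to(chrom, pos) <= 5_000_000:
                warnings.warn(
                    f"network regulator variant {net.variant_id} lies within "
                    f"the cis window of target {t}; cis/trans labels are "
                    "confounded for this pair",
                    stacklevel=2,
                )

    # per-gene slopes planted directly on a variant (cis + contamination source)
    direct: dict[str, list[tuple[str, float]]] = {}
    for eff in config.cis_effects:
        direct.setdefault(eff.gene_id, []).append((eff.variant_id, eff.beta))
    for net in config.networks:
        direct.setdefault(net.regulator_gene, []).append(
            (net.variant_id, net.beta_cis)
        )
    for cont in config.contaminations:
        direct.setdefault(cont.source_gene, []).append(
            (cont.variant_id, cont.source_cis_beta)
        )

    # global (cross-cohort) structure drawn from the panel stream
    rng_global = child_rng(config.seed, 2)
    n_sex = int(round(config.sex_gene_frac * len(gene_ids)))
    sex_genes = set(
        rng_global.choice(gene_ids, size=n_sex, replace=False)
    ) if n_sex else set()
    loadings = rng_global.normal(size=(len(gene_ids), config.n_latent))
    if config.n_latent:
        norms = np.linalg.norm(loadings, axis=1, keepdims=True)
        loadings = loadings / norms * np.sqrt(config.latent_var)
    # contamination sources emulate highly expressed genes whose variance is
    # dominated by a strong cis effect: no latent or sex share
    source_genes = {c_.source_gene for c_ in config.contaminations}
    for gid in source_genes:
        loadings[gid_index[gid], :] = 0.0
    # keep the sex effect off genes with strong planted cis variance so the
    # unit-variance budget always closes
    sex_genes -= source_genes | {n_.regulator_gene for n_ in config.networks}
    latent_contrib = (loadings**2).sum(axis=1)

    var_genetic = np.zeros(len(gene_ids))
    for gid, effs in direct.items():
        gi = gid_index[gid]
        for vid, beta in effs:
            maf = variants[vid_index[vid]].maf
            var_genetic[gi] += beta**2 * 2 * maf * (1 - maf)
    for net in config.networks:
        for t, s in zip(net.targets, net.marginal_slopes):
            gamma = s / net.beta_cis
            # gamma^2 * var(y_R) with var(y_R) = 1 by the variance budget
            var_genetic[gid_index[t]] += gamma**2
    noise_var = _variance_budget(
        config, gene_ids, latent_contrib, sex_genes, var_genetic
    )

    out: dict[str, ExpressionMatrix] = {}
    for c, cohort in enumerate(config.cohort_ids):
        gm = genotypes[cohort]
        n = gm.n_samples
        rng = child_rng(config.seed, 3, c)
        sex = (np.arange(n) % 2).astype(float)  # balanced binary covariate
        factors = rng.normal(size=(n, config.n_latent))
        batch = rng.normal(0.0, config.batch_sd, size=len(gene_ids))

        y = rng.normal(size=(n, len(gene_ids))) * np.sqrt(noise_var)
        y += factors @ loadings.T
        y += batch
        sex_mask = np.array([g in sex_genes for g in gene_ids])
        y[:, sex_mask] += np.outer(sex, np.full(sex_mask.sum(), config.sex_effect))

        for gid, effs in direct.items():
            gi = gid_index[gid]
            for vid, beta in effs:
                y[:, gi] += beta * gm.dosages[:, vid_index[vid]]
        for net in config.networks:
            y_reg = y[:, gid_index[net.regulator_gene]]
            for t, s in zip(net.targets, net.marginal_slopes):
                y[:, gid_index[t]] += (s / net.beta_cis) * y_reg

        out[cohort] = ExpressionMatrix(gm.sample_ids, gene_ids, y, "normalized")

    truth = TrueModel(
        cis_pairs=[(e.variant_id, e.gene_id, e.beta) for e in config.cis_effects]
        + [(n_.variant_id, n_.regulator_gene, n_.beta_cis) for n_ in config.networks]
        + [(c_.variant_id, c_.source_gene, c_.source_cis_beta)
           for c_ in config.contaminations],
        trans_pairs=[
            (net.variant_id, t, s)
            for net in config.networks
            for t, s in zip(net.targets, net.marginal_slopes)
        ],
        artifact_pairs=[
            (cont.variant_id, t, cont.leakage * cont.source_cis_beta)
            for cont in config.contaminations
            for t in cont.targets
        ],
    )
    return out, truth


def plant_crossmap_artifact(
    expression: dict[str, ExpressionMatrix], config: SimulationConfig
) -> tuple[dict[str, ExpressionMatrix], CrossmapTable]:
    """Leak each contamination source into its targets on the normalized
    scale (``y_target += leakage * y_source``) and emit the corresponding
    cross-mappability entries (score > 1, so the downstream filter can act).

    Entries are written even at ``leakage = 0``, in which case expression is
    returned unchanged.  Deterministic given its inputs: no randomness here.
    """
    table = CrossmapTable()
    out: dict[str, ExpressionMatrix] = {}
    for cohort, em in expression.items():
        values = em.values.copy()
        gi = {g: i for i, g in enumerate(em.gene_ids)}
        for cont in config.contaminations:
            src = values[:, gi[cont.source_gene]].copy()
            for t in cont.targets:
                values[:, gi[t]] += cont.leakage * src
        out[cohort] = ExpressionMatrix(em.sample_ids, em.gene_ids, values, em.unit)
    for cont in config.contaminations:
        for t in cont.targets:
            table.set(t, cont.source_gene, cont.crossmap_score)
    return out, table


# ---------------------------------------------------------------------------
# GWAS regions
# ---------------------------------------------------------------------------

def simulate_gwas_region(
    gm: GenotypeMatrix,
    causal_variant: str,
    effect: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Single-variant association statistics for a simulated quantitative
    trait with one causal variant in the panel.

    The trait is ``effect * dosage + N(0, 1)``; each panel variant is then
    regressed on the trait marginally (no covariates), giving the regional
    beta/se/p profile a colocalisation analysis consumes.
    """
    from scipy import stats

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = gm.n_samples
    if n < 10:
        raise ValueError(f"need at least 10 samples for a GWAS region, got {n}")
    vids = gm.variant_ids
    if vids.count(causal_variant) > 1:
        raise ValueError(f"duplicate causal variant id {causal_variant!r}")
    if causal_variant not in vids:
        raise ValueError(f"causal variant {causal_variant!r} not in panel")

    g_causal = gm.dosages[:, vids.index(causal_variant)]
    trait = effect * g_causal + rng.normal(size=n)

    G = gm.dosages - gm.dosages.mean(axis=0)
    y = trait - trait.mean()
    gg = (G**2).sum(axis=0)
    ok = gg > 1e-12
    beta = np.full(len(vids), np.nan)
    se = np.full(len(vids), np.nan)
    beta[ok] = (G[:, ok] * y[:, None]).sum(axis=0) / gg[ok]
    resid_ss = (y**2).sum() - beta[ok] ** 2 * gg[ok]
    df = n - 2
    se[ok] = np.sqrt(np.maximum(resid_ss, 0.0) / df / gg[ok])
    z = beta / se
    pval = 2 * stats.t.sf(np.abs(z), df)
    return pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "n": n,
            "maf": gm.maf(),
        }
    )


# ---------------------------------------------------------------------------
# canned study conditions
# ---------------------------------------------------------------------------

def default_config(
    seed: int,
    n_samples: tuple[int, ...] = (200, 200, 200),
    include_network: bool = True,
    include_artifact: bool = True,
    n_network_targets: int = 20,
    slope_range: tuple[float, float] = (0.25, 0.40),
    leakage: float = 0.3,
) -> SimulationConfig:
    """The packaged desk-scale study: one 20-target trans network mediated by
    a cis regulator (marginal slopes 0.25-0.40 SD per allele), one read-
    leakage contamination locus with 6 apparent targets, and a handful of
    ordinary cis effects, across three cohorts totalling 600 samples."""
    config = SimulationConfig(seed=seed, n_samples=tuple(n_samples))
    variants, genes = build_panel(config)
    per_chrom_genes = {c: [g for g in genes if g.chrom == c]
                       for c in (f"chr{i+1}" for i in range(config.n_chromosomes))}

    # ordinary cis effects on a few genes spread over the genome
    cis: list[CisEffect] = []
    n_per_chrom = -(-config.n_genes // config.n_chromosomes)
    cis_indices = [5, n_per_chrom // 2, n_per_chrom + 10,
                   2 * n_per_chrom + n_per_chrom // 2 + 5,
                   3 * n_per_chrom + 20, 3 * n_per_chrom + n_per_chrom // 2]
    for gi in cis_indices:
        v = variants[local_variant_of(config, gi)]
        cis.append(CisEffect(v.variant_id, genes[gi].gene_id, 0.5))

    networks: list[TransNetwork] = []
    contaminations: list[Contamination] = []
    overrides: dict[str, float] = {}

    if include_network:
        reg_index = 2  # chr1 gene; its local variant is the network variant
        v = variants[local_variant_of(config, reg_index)]
        overrides[v.variant_id] = 0.5  # common variant: stable power
        targets = [g.gene_id for g in
                   per_chrom_genes["chr3"][:n_network_targets // 2]
                   + per_chrom_genes["chr4"][:(n_network_targets + 1) // 2]]
        slopes = [float(s) for s in np.linspace(slope_range[1], slope_range[0],
                                                n_network_targets)]
        networks.append(
            TransNetwork(v.variant_id, genes[reg_index].gene_id, 1.1,
                         targets, slopes)
        )

    if include_artifact:
        # chr2 gene; its local variant is the artifact variant
        src_index = n_per_chrom + n_per_chrom // 3
        v = variants[local_variant_of(config, src_index)]
        overrides[v.variant_id] = 0.4
        art_targets = [g.gene_id for g in
                       per_chrom_genes["chr3"][-3:] + per_chrom_genes["chr4"][-3:]]
        contaminations.append(
            Contamination(v.variant_id, genes[src_index].gene_id, 1.4,
                          art_targets, leakage)
        )

    return SimulationConfig(
        seed=seed,
        n_samples=tuple(n_samples),
        maf_overrides=overrides,
        cis_effects=cis,
        networks=networks,
        contaminations=contaminations,
    )


def null_config(
    seed: int,
    n_samples: tuple[int, ...] = (200, 200, 200),
    n_variants: int = 120,
    n_genes: int = 60,
    n_chromosomes: int = 6,
) -> SimulationConfig:
    """No planted effects at all: every pair is null.

    Spread over six chromosomes so most variant-gene pairs fall outside the
    5 Mb cis window (>= 6,000 trans pairs at the defaults)."""
    return SimulationConfig(
        seed=seed,
        n_samples=tuple(n_samples),
        n_variants=n_variants,
        n_genes=n_genes,
        n_chromosomes=n_chromosomes,
    )
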