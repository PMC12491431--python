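"""Domain types and readers/writers for the on-disk formats of the pipeline.

Coordinates are 1-based inclusive throughout (VCF convention).  All tabular
formats are tab-separated text with a header row; gzip is handled
transparently by extension.  Summary statistics round-trip losslessly at 12
significant digits.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GeneRecord",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "CrossmapTable",
    "parse_variant_id",
    "format_variant_id",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_expression",
    "write_expression",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_crossmap",
    "write_crossmap",
    "read_summary_stats",
    "write_summary_stats",
    "SUMMARY_COLUMNS",
]

#: canonical column order for per-cohort and meta summary statistics
SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt",
    "gene_id", "beta", "se", "pvalue", "n", "maf",
]

_BIOTYPES = {"protein_coding", "lincRNA", "pseudogene", "miRNA", "other"}


class ParseError(ValueError):
    """Raised when an on-disk record violates its format contract."""


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# variant / gene records
# ---------------------------------------------------------------------------

def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    """Split a ``chr_pos_ref_alt`` identifier into its four fields.

    >>> parse_variant_id("chr22_18166589_T_C")
    ('chr22', 18166589, 'T', 'C')
    """
    parts = variant_id.split("_")
    if len(parts) != 4:
        raise ParseError(
            f"variant id {variant_id!r}: expected 4 underscore-separated "
            f"fields (chrom, pos, ref, alt), got {len(parts)}"
        )
    chrom, pos_str, ref, alt = parts
    try:
        pos = int(pos_str)
    except ValueError:
        raise ParseError(
            f"variant id {variant_id!r}: position field {pos_str!r} is not an integer"
        ) from None
    if pos < 1:
        raise ParseError(f"variant id {variant_id!r}: position must be >= 1")
    return chrom, pos, ref, alt


def format_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}_{pos}_{ref}_{alt}"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant keyed by ``chrom_pos_ref_alt``.

    ``maf`` is the minor-allele frequency in [0, 0.5]; ``imputation_r2`` the
    imputation quality score in [0, 1], NaN when genotyped directly.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float = float("nan")
    imputation_r2: float = float("nan")

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")

    @property
    def variant_id(self) -> str:
        return format_variant_id(self.chrom, self.pos, self.ref, self.alt)

    @classmethod
    def from_id(cls, variant_id: str, maf=float("nan"), imputation_r2=float("nan")):
        chrom, pos, ref, alt = parse_variant_id(variant_id)
        return cls(chrom, pos, ref, alt, maf=maf, imputation_r2=imputation_r2)

    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
        return {self.ref, self.alt} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class GeneRecord:
    """A gene body interval with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.biotype not in _BIOTYPES:
            raise ValueError(
                f"gene {self.gene_id}: unknown biotype {self.biotype!r}"
            )

    def distance_to(self, chrom: str, pos: int) -> float:
        """Distance in bp from a position to the gene body (0 if inside,
        inf if on another chromosome)."""
        if chrom != self.chrom:
            return float("inf")
        if self.start <= pos <= self.end:
            return 0.0
        return float(min(abs(pos - self.start), abs(pos - self.end)))


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix; dosages in [0, 2], NaN = missing."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, v = self.dosages.shape
        if n != len(self.sample_ids) or v != len(self.variants):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        ids = [v_.variant_id for v_ in self.variants]
        if len(set(ids)) != v:
            raise ValueError("duplicate variant ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency from non-missing dosages
        (NaN for all-missing columns)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def imputation_r2(self) -> np.ndarray:
        return np.array([v.imputation_r2 for v in self.variants])

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.sample_ids,
            [self.variants[i] for i in keep],
            self.dosages[:, keep],
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variants, self.dosages[rows])

    def with_refreshed_maf(self) -> "GenotypeMatrix":
        """Return a copy whose VariantRecord mafs match the dosage columns."""
        mafs = self.maf()
        variants = [replace(v, maf=m) for v, m in zip(self.variants, mafs)]
        return GenotypeMatrix(self.sample_ids, variants, self.dosages)


EXPRESSION_UNITS = ("TPM", "normalized", "INT")


@dataclass
class ExpressionMatrix:
    """Samples x genes expression matrix tagged with its unit.

    The unit tag gates stage-appropriate use: the low-expression filter
    requires ``TPM``, the association scan requires ``INT``.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    unit: str = "normalized"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, g = self.values.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"expression matrix {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if self.unit not in EXPRESSION_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            self.sample_ids,
            [self.gene_ids[i] for i in keep],
            self.values[:, keep],
            self.unit,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            list(sample_ids), self.gene_ids, self.values[rows], self.unit
        )


@dataclass
class CrossmapTable:
    """Sparse gene-pair cross-mappability scores; absent pair means 0.

    Lookup is symmetrized, ``score(a, b) = max(stored(a, b), stored(b, a))``:
    read leakage in either direction can fabricate a trans signal, so the
    filter treats the score as undirected.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def set(self, gene_a: str, gene_b: str, score: float) -> None:
        if score < 0:
            raise ValueError("cross-mappability scores must be >= 0")
        self.scores[(gene_a, gene_b)] = float(score)

    def score(self, gene_a: str, gene_b: str) -> float:
        return max(
            self.scores.get((gene_a, gene_b), 0.0),
            self.scores.get((gene_b, gene_a), 0.0),
        )

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from a VCF (``DS`` dosage or ``GT`` hard calls) or a
    wide dosage TSV.

    Hard genotypes map to dosages {0, 1, 2}; missing calls to NaN.  Variant
    MAF is recomputed from non-missing dosages.
    """
    path = Path(path)
    if format == "auto":
        name = path.name
        format = "vcf" if (".vcf" in name or name.endswith(".bcf")) else "dosage-tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{path}: variant at {rec.CHROM}:{rec.POS} is not biallelic"
            )
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col[col < -0.5] = np.nan  # cyvcf2 encodes missing as negative
        else:
            gts = rec.genotype.array()  # (n, ploidy+1); -1 = missing allele
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            col = alleles.sum(axis=1)
        r2 = rec.INFO.get("R2", rec.INFO.get("DR2", float("nan")))
        columns.append(col)
        variants.append(
            VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                          imputation_r2=float(r2) if r2 is not None else float("nan"))
        )
    dosages = (np.column_stack(columns) if columns
               else np.empty((len(sample_ids), 0)))
    return GenotypeMatrix(sample_ids, variants, dosages).with_refreshed_maf()


_DOSAGE_META = ["variant_id", "chrom", "pos", "ref", "alt", "maf", "imputation_r2"]


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    """Wide dosage TSV: one row per variant, metadata then sample columns."""
    meta = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "ref": [v.ref for v in gm.variants],
            "alt": [v.alt for v in gm.variants],
            "maf": [v.maf for v in gm.variants],
            "imputation_r2": [v.imputation_r2 for v in gm.variants],
        }
    )
    body = pd.DataFrame(gm.dosages.T, columns=gm.sample_ids)
    out = pd.concat([meta, body], axis=1)
    with _open(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def _read_dosage_tsv(path) -> GenotypeMatrix:
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: dosage TSV lacks columns {missing}")
    sample_ids = [c for c in df.columns if c not in _DOSAGE_META]
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ParseError(f"{path}: duplicate variant id {dup!r}")
    variants = [
        VariantRecord(r.chrom, int(r.pos), r.ref, r.alt,
                      maf=float(r.maf), imputation_r2=float(r.imputation_r2))
        for r in df.itertuples()
    ]
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(sample_ids, variants, dosages)


# ---------------------------------------------------------------------------
# expression / annotation / crossmap / summary-stat I/O
# ---------------------------------------------------------------------------

def write_expression(em: ExpressionMatrix, path) -> None:
    """Genes x samples TSV with a leading ``#unit=`` comment line."""
    df = pd.DataFrame(em.values.T, index=em.gene_ids, columns=em.sample_ids)
    df.index.name = "gene_id"
    with _open(path, "wt") as fh:
        fh.write(f"#unit={em.unit}\n")
        df.to_csv(fh, sep="\t", float_format="%.12g")


def read_expression(path, unit: str | None = None) -> ExpressionMatrix:
    with _open(path) as fh:
        first = fh.readline()
        if first.startswith("#unit="):
            file_unit = first.strip().split("=", 1)[1]
        else:
            file_unit = "normalized"
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids")
    return ExpressionMatrix(
        list(df.columns), list(df.index), df.to_numpy(dtype=float).T,
        unit or file_unit,
    )


def write_gene_annotation(genes: Iterable[GeneRecord], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
    )
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_gene_annotation(path) -> dict[str, GeneRecord]:
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    out: dict[str, GeneRecord] = {}
    for i, r in enumerate(df.itertuples(), start=2):
        if r.gene_id in out:
            raise ParseError(f"{path}:{i}: duplicate gene id {r.gene_id!r}")
        try:
            out[r.gene_id] = GeneRecord(
                r.gene_id, str(r.chrom), int(r.start), int(r.end),
                r.strand, r.biotype,
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
    return out


def write_crossmap(table: CrossmapTable, path) -> None:
    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(table.scores.items())],
        columns=["gene_a", "gene_b", "score"],
    )
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_crossmap(path) -> CrossmapTable:
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    table = CrossmapTable()
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            table.set(r.gene_a, r.gene_b, float(r.score))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
    return table


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write an association or meta summary table at 12 significant digits."""
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_summary_stats(path) -> pd.DataFrame:
    with _open(path) as fh:
        return pd.read_csv(fh, sep="\t")
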