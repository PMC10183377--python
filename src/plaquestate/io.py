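"""Readers and writers for every external format the pipeline touches.

Coordinate conventions are fixed package-wide: region intervals (BED) are
0-based half-open, variant positions are 1-based. Effect sizes are stored on
the additive log-odds scale; odds ratios are converted to ``beta = ln(OR)``
at read time so downstream arithmetic never branches on the effect scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Sentinel for a missing dosage in TSV files (never silently 0).
MISSING_DOSAGE = "NA"


class FormatError(ValueError):
    """A file does not conform to its expected layout (missing columns etc.)."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

CELL_TABLE_COLUMNS = ("cell_id", "library_id", "condition", "x", "y", "cell_type")


@dataclass
class CellTable:
    """Per-cell records driving cell-state discovery.

    ``condition_order`` fixes the ordering of the condition category (e.g.
    control < prelesion < early < late); by default it is the order of first
    appearance in the table.
    """

    cells: pd.DataFrame
    condition_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.cells
        for col in CELL_TABLE_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"cell table is missing required column {col!r}")
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()[:5]
            raise ValidationError(f"duplicate cell_id values: {list(dupes)}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite embedding coordinates")
        lib2cond = df.groupby("library_id", sort=False)["condition"].nunique()
        if (lib2cond > 1).any():
            bad = lib2cond[lib2cond > 1].index.tolist()
            raise ValidationError(f"libraries mapped to multiple conditions: {bad}")
        if not self.condition_order:
            self.condition_order = tuple(pd.unique(df["condition"]))
        unknown = set(df["condition"]) - set(self.condition_order)
        if unknown:
            raise ValidationError(f"conditions outside condition_order: {sorted(unknown)}")

    @property
    def libraries(self) -> list[str]:
        return list(pd.unique(self.cells["library_id"]))

    def library_condition(self) -> dict[str, str]:
        return dict(
            self.cells.groupby("library_id", sort=False)["condition"].first()
        )

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class CountMatrix:
    """A genes x (cells or samples) expression matrix with a named layer."""

    genes: list[str]
    names: list[str]
    values: np.ndarray
    layer: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.names)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.names)} columns"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene names")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate column names")
        if (self.values < 0).any():
            raise ValidationError("negative expression values")
        if self.layer == "raw_counts" and not np.allclose(self.values, np.round(self.values)):
            raise ValidationError("raw_counts layer must contain integers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.names)

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        idx = [self.genes.index(g) for g in genes]
        return CountMatrix(genes, list(self.names), self.values[idx], self.layer)


SUMSTATS_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "p", "info", "eaf",
)


@dataclass
class SumStats:
    """GWAS summary statistics on the additive log-odds scale."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in SUMSTATS_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"summary statistics missing column {col!r}")
        if df["variant_id"].duplicated().any():
            raise ValidationError("duplicate variant_id in summary statistics")
        for col in ("effect_allele", "other_allele"):
            bad = ~df[col].isin(VALID_ALLELES)
            if bad.any():
                raise ValidationError(
                    f"unknown allele code(s) in {col}: "
                    f"{sorted(df.loc[bad, col].unique())}"
                )
        if (df["effect_allele"] == df["other_allele"]).any():
            raise ValidationError("effect and other allele identical for some variants")
        p = df["p"].to_numpy(dtype=float)
        if (p <= 0).any() or (p > 1).any():
            raise ValidationError("p values must lie in (0, 1]")
        info = df["info"].to_numpy(dtype=float)
        if ((info < 0) | (info > 1)).any():
            raise ValidationError("INFO must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeDataset:
    """Target-cohort dosages with phenotype and covariates.

    ``dosages`` is samples x variants with values in {0, 1, 2} or NaN for
    missing. ``variants`` carries SumStats-compatible records plus observed
    target-cohort QC statistics (maf, info, missingness, hwe_p).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        n, m = len(self.sample_ids), len(self.variants)
        if self.dosages.shape != (n, m):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} != ({n}, {m})"
            )
        if len(self.phenotype) != n:
            raise ValidationError("phenotype length does not match samples")
        if set(np.unique(self.phenotype)) - {0, 1}:
            raise ValidationError("phenotype must be binary 0/1")
        if len(set(np.unique(self.phenotype))) < 2:
            raise ValidationError("phenotype must contain both classes")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (np.min(vals) < 0 or np.max(vals) > 2):
            raise ValidationError("dosages must lie in [0, 2]")
        if "missingness" in self.variants.columns:
            obs = np.isnan(self.dosages).mean(axis=0)
            rec = self.variants["missingness"].to_numpy(dtype=float)
            if not np.allclose(obs, rec, atol=1e-9):
                raise ValidationError("recorded missingness does not match dosages")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def subset_variants(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        variants = self.variants.iloc[keep].reset_index(drop=True)
        return GenotypeDataset(
            self.sample_ids, variants, self.dosages[:, keep],
            self.phenotype, self.covariates,
        )


@dataclass(frozen=True)
class RegionSet:
    """Named collection of genomic intervals, 0-based half-open.

    Overlapping intervals are allowed and never merged.
    """

    name: str
    intervals: pd.DataFrame  # chrom, start, end, [strand], [label]

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise FormatError(f"region set missing column {col!r}")
        if (df["start"] < 0).any():
            raise ValidationError("negative interval start")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("interval with start >= end")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

def read_cell_table(path, condition_order: tuple[str, ...] = ()) -> CellTable:
    """Read a per-cell TSV with columns cell_id, library_id, condition, x, y,
    cell_type. Row order is preserved."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "library_id": str,
                                            "condition": str, "cell_type": str})
    return CellTable(df, tuple(condition_order))


def write_cell_table(cells: CellTable, path) -> None:
    cells.cells.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices: dense TSV and MTX triplet
# ---------------------------------------------------------------------------

def read_matrix_tsv(path, layer: str = "tpm") -> CountMatrix:
    """Dense gene x sample TSV, first column = gene names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       df.to_numpy(dtype=float), layer)


def write_matrix_tsv(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(mtx_path, features_path, barcodes_path,
                    layer: str = "raw_counts") -> CountMatrix:
    """Sparse counts in MatrixMarket form with one-per-line feature and
    barcode lists (the CellRanger-style triplet)."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = [ln.strip().split("\t")[0] for ln in open(features_path) if ln.strip()]
    cells = [ln.strip() for ln in open(barcodes_path) if ln.strip()]
    return CountMatrix(genes, cells, mat, layer)


def write_counts_mtx(matrix: CountMatrix, mtx_path, features_path, barcodes_path) -> None:
    from scipy import sparse
    from scipy.io import mmwrite

    mmwrite(str(mtx_path), sparse.coo_matrix(matrix.values))
    with open(features_path, "w") as fh:
        fh.write("\n".join(matrix.genes) + "\n")
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(matrix.names) + "\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

DEFAULT_SUMSTATS_MAP = {c: c for c in SUMSTATS_COLUMNS}


def read_sumstats(path, column_map: dict[str, str] | None = None) -> SumStats:
    """Read tab-delimited GWAS summary statistics.

    ``column_map`` maps internal names to file column names. An ``or``
    mapping may replace ``beta``; odds ratios are converted with
    ``beta = ln(OR)`` so every downstream consumer sees log-odds.
    """
    cmap = dict(DEFAULT_SUMSTATS_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame()
    for internal in ("variant_id", "chrom", "pos", "effect_allele",
                     "other_allele", "p", "info", "eaf"):
        src = cmap[internal]
        if src not in df.columns:
            raise FormatError(f"summary statistics missing column {src!r} "
                              f"(mapped from {internal!r})")
        out[internal] = df[src]
    or_col = cmap.get("or", "or")
    beta_col = cmap.get("beta", "beta")
    if beta_col in df.columns:
        out["beta"] = df[beta_col].astype(float)
    elif or_col in df.columns:
        orv = df[or_col].astype(float)
        if (orv <= 0).any():
            raise ValidationError("odds ratios must be positive")
        out["beta"] = np.log(orv)
    else:
        raise FormatError(f"summary statistics missing column {beta_col!r} (or OR column)")
    out["chrom"] = out["chrom"].astype(str)
    out["variant_id"] = out["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].astype(str).str.upper()
    out = out[list(SUMSTATS_COLUMNS)]
    return SumStats(out.reset_index(drop=True))


def write_sumstats(ss: SumStats, path) -> None:
    ss.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regions (BED) and gene sets (GMT)
# ---------------------------------------------------------------------------

def read_regions(path, name: str | None = None) -> RegionSet:
    """BED3+ reader; 0-based half-open; optional 4th column is a label and
    optional 6th column a strand. Intervals are preserved verbatim."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise ValidationError(f"line {lineno}: negative start")
            if start >= end:
                raise ValidationError(f"line {lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, label, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "strand"])
    return RegionSet(name or str(path), df)


def write_regions(regions: RegionSet, path) -> None:
    df = regions.intervals
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            label = getattr(row, "label", "") or "."
            strand = getattr(row, "strand", ".") or "."
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{label}\t0\t{strand}\n")


def read_gmt(path) -> list[GeneSet]:
    """Standard GMT: name, description, then genes. Duplicate genes within a
    line are dropped with a warning; an empty file yields an empty list."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: GMT line needs >= 3 fields")
            name, genes = parts[0], parts[2:]
            uniq = list(dict.fromkeys(g for g in genes if g))
            if len(uniq) < sum(1 for g in genes if g):
                warnings.warn(f"GMT line {lineno} ({name}): duplicate genes dropped")
            sets.append(GeneSet(name, tuple(uniq)))
    return sets


def write_gmt(sets: list[GeneSet], path, description: str = "plaquestate") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Genotype dosages
# ---------------------------------------------------------------------------

def read_genotypes(dosage_path, variants_path, phenotype_path,
                   covariates_path=None, long_format: bool = False) -> GenotypeDataset:
    """Assemble a GenotypeDataset from TSV parts.

    The canonical dosage layout is wide (rows = samples, columns = variants,
    first column ``sample_id``); a long (sample, variant, dosage) layout is
    also accepted. Missing dosages are the literal string ``NA``.
    """
    variants = pd.read_csv(variants_path, sep="\t",
                           dtype={"variant_id": str, "chrom": str})
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    if long_format:
        long = pd.read_csv(dosage_path, sep="\t", na_values=[MISSING_DOSAGE],
                           dtype={"sample_id": str, "variant_id": str})
        wide = long.pivot(index="sample_id", columns="variant_id", values="dosage")
        wide = wide.reindex(index=pheno["sample_id"],
                            columns=variants["variant_id"])
    else:
        wide = pd.read_csv(dosage_path, sep="\t", index_col=0,
                           na_values=[MISSING_DOSAGE])
        wide.index = wide.index.astype(str)
        wide = wide.reindex(index=pheno["sample_id"],
                            columns=variants["variant_id"])
    covariates = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep="\t", dtype={"sample_id": str})
        covariates = (cov.set_index("sample_id")
                         .reindex(pheno["sample_id"]).reset_index(drop=True))
    return GenotypeDataset(
        list(pheno["sample_id"]), variants, wide.to_numpy(dtype=float),
        pheno["phenotype"].to_numpy(dtype=int), covariates,
    )


def write_genotypes(geno: GenotypeDataset, dosage_path, variants_path,
                    phenotype_path, covariates_path=None) -> None:
    wide = pd.DataFrame(geno.dosages, index=pd.Index(geno.sample_ids, name="sample_id"),
                        columns=geno.variant_ids)
    wide.to_csv(dosage_path, sep="\t", na_rep=MISSING_DOSAGE)
    geno.variants.to_csv(variants_path, sep="\t", index=False)
    pd.DataFrame({"sample_id": geno.sample_ids,
                  "phenotype": geno.phenotype}).to_csv(phenotype_path, sep="\t",
                                                       index=False)
    if covariates_path is not None and geno.covariates is not None:
        out = geno.covariates.copy()
        out.insert(0, "sample_id", geno.sample_ids)
        out.to_csv(covariates_path, sep="\t", index=False)
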