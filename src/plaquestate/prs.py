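"""Region-set-aware clumping-and-thresholding polygenic risk scores.

The pipeline follows the PRSet-style construction: QC of base summary
statistics (INFO >= 0.8, drop strand-ambiguous variants) and of the target
cohort (autosomes, MAF >= 0.01, INFO >= 0.8, HWE p >= 1e-25, missingness
<= 0.1); regions of interest built from gene bodies (-35 kb / +10 kb
flanks) or from chromatin accessibility peaks near gene TSSs (+/- 500 kb);
greedy LD clumping (500 kb window, r^2 0.2) that preferentially retains
in-region SNPs as clump indices; additive scoring (sum of beta x dosage);
covariate-adjusted evaluation as the full-minus-null Nagelkerke pseudo-R^2;
a competitive permutation p value against size-matched background SNP sets;
p-value-threshold scanning; and the hybrid score that keeps every strong-p
SNP genome-wide while admitting weak-p SNPs only inside regulatory regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree

from .io import GeneSet, GenotypeDataset, RegionSet, SumStats, ValidationError

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
AUTOSOMES = {str(c) for c in range(1, 23)} | {f"chr{c}" for c in range(1, 23)}


@dataclass(frozen=True)
class QCReport:
    n_in: int
    removed: dict[str, int]
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in - sum(self.removed.values()) != self.n_out:
            raise ValidationError("QC report does not balance")


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def qc_base(sumstats: SumStats, info_min: float = 0.8) -> tuple[SumStats, QCReport]:
    """Base-data QC: keep INFO >= ``info_min``, drop strand-ambiguous
    (A/T, C/G) variants. INFO boundary is inclusive."""
    df = sumstats.table
    low_info = df["info"].to_numpy(dtype=float) < info_min
    ambiguous = np.array([
        (ea, oa) in AMBIGUOUS_PAIRS
        for ea, oa in zip(df["effect_allele"], df["other_allele"])
    ])
    removed = {"info": int(low_info.sum()),
               "strand_ambiguous": int((~low_info & ambiguous).sum())}
    keep = ~(low_info | ambiguous)
    if not keep.any():
        raise ValidationError("base QC removed all variants")
    out = SumStats(df[keep].reset_index(drop=True))
    return out, QCReport(len(df), removed, len(out))


def qc_target(geno: GenotypeDataset, maf_min: float = 0.01,
              info_min: float = 0.8, hwe_p_min: float = 1e-25,
              miss_max: float = 0.1) -> tuple[GenotypeDataset, QCReport]:
    """Target-cohort QC in the stated order (non-autosomal, MAF, INFO, HWE,
    missingness), attributing each removed variant to its first failing
    filter."""
    v = geno.variants
    filters = [
        ("non_autosomal", ~v["chrom"].astype(str).isin(AUTOSOMES)),
        ("maf", v["maf"].to_numpy(dtype=float) < maf_min),
        ("info", v["info"].to_numpy(dtype=float) < info_min),
        ("hwe", v["hwe_p"].to_numpy(dtype=float) < hwe_p_min),
        ("missingness", v["missingness"].to_numpy(dtype=float) > miss_max),
    ]
    removed = {}
    already = np.zeros(len(v), dtype=bool)
    for name, fail in filters:
        fail = np.asarray(fail, dtype=bool)
        removed[name] = int((fail & ~already).sum())
        already |= fail
    if already.all():
        raise ValidationError("target QC removed all variants")
    out = geno.subset_variants(np.flatnonzero(~already))
    return out, QCReport(len(v), removed, len(out.variants))


# ---------------------------------------------------------------------------
# Region construction
# ---------------------------------------------------------------------------

def regions_from_genes(genes: RegionSet, gene_set: GeneSet,
                       up: int = 35_000, down: int = 10_000,
                       strand_aware: bool = True) -> RegionSet:
    """Extend the transcript region of every set gene by ``up`` bp before
    its 5' end and ``down`` bp after its 3' end (strand-aware when enabled),
    truncating at zero. ``genes`` is a BED-like annotation whose labels are
    gene names."""
    ann = genes.intervals.set_index("label")
    missing = [g for g in gene_set.genes if g not in ann.index]
    if missing:
        warnings.warn(f"{len(missing)} set gene(s) missing from annotation: "
                      f"{missing[:5]}")
    rows = []
    for g in gene_set.genes:
        if g not in ann.index:
            continue
        for _, rec in ann.loc[[g]].iterrows():
            strand = rec.get("strand", "+")
            if strand_aware and strand == "-":
                start, end = rec["start"] - down, rec["end"] + up
            else:
                start, end = rec["start"] - up, rec["end"] + down
            rows.append((rec["chrom"], max(0, int(start)), int(end), g, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "strand"])
    return RegionSet(f"{gene_set.name}_flanked", df)


def _tss(rec) -> int:
    """0-based TSS coordinate of an annotation record."""
    return int(rec["start"]) if rec.get("strand", "+") != "-" else int(rec["end"]) - 1


def regions_from_peaks(peaks: RegionSet, genes: RegionSet, gene_set: GeneSet,
                       window: int = 500_000) -> RegionSet:
    """Keep peaks overlapping the TSS +/- ``window`` interval of any set
    gene (any shared base counts); each peak is retained at most once."""
    ann = genes.intervals.set_index("label")
    trees: dict[str, IntervalTree] = {}
    for g in gene_set.genes:
        if g not in ann.index:
            continue
        for _, rec in ann.loc[[g]].iterrows():
            tss = _tss(rec)
            lo, hi = max(0, tss - window), tss + window + 1  # inclusive window
            trees.setdefault(str(rec["chrom"]), IntervalTree()).addi(lo, hi)
    keep = []
    for i, row in peaks.intervals.iterrows():
        tree = trees.get(str(row["chrom"]))
        if tree is not None and tree.overlaps(int(row["start"]), int(row["end"])):
            keep.append(i)
    df = peaks.intervals.loc[keep].reset_index(drop=True)
    return RegionSet(f"{peaks.name}_near_{gene_set.name}", df)


def resize_peaks(peaks: RegionSet, width: int) -> RegionSet:
    """Resize each peak to ``width`` bp centred on its summit, clipping at
    zero. The summit is an absolute coordinate in the ``summit`` column."""
    if width <= 0:
        raise ValidationError("peak width must be positive")
    if "summit" not in peaks.intervals.columns:
        raise ValidationError("peaks lack a 'summit' column")
    df = peaks.intervals.copy()
    if df["summit"].isna().any():
        raise ValidationError("missing summit coordinate")
    summit = df["summit"].astype(int)
    df["start"] = np.maximum(0, summit - width // 2)
    df["end"] = summit + (width - width // 2)
    return RegionSet(f"{peaks.name}_w{width}", df)


def _region_trees(regions: RegionSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in regions.intervals.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(row.start, row.end)
    return trees


def positions_in_regions(chrom: pd.Series, pos: pd.Series,
                         regions: RegionSet) -> np.ndarray:
    """Flag 1-based variant positions inside 0-based half-open intervals."""
    trees = _region_trees(regions)
    out = np.zeros(len(pos), dtype=bool)
    for i, (c, p) in enumerate(zip(chrom.astype(str), pos.astype(int))):
        tree = trees.get(c)
        if tree is not None and tree.overlaps(p - 1):
            out[i] = True
    return out


# ---------------------------------------------------------------------------
# Preferential clumping
# ---------------------------------------------------------------------------

@dataclass
class ClumpedPanel:
    """Post-clumping SNP panel: retained index variants (ordered as swept)
    with in-set flags and, for each, the clump members it removed."""

    retained: pd.DataFrame  # variant_id, chrom, pos, p, beta, in_set, n_clumped
    clumps: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.retained)


def _imputed_dosages(geno: GenotypeDataset, cols: np.ndarray) -> np.ndarray:
    dose = geno.dosages[:, cols]
    if np.isnan(dose).any():
        means = np.nanmean(dose, axis=0)
        idx = np.where(np.isnan(dose))
        dose = dose.copy()
        dose[idx] = np.take(means, idx[1])
    return dose


def preferential_clump(sumstats: SumStats, geno: GenotypeDataset,
                       region_set: RegionSet | None, window: int = 500_000,
                       r2_max: float = 0.2) -> ClumpedPanel:
    """Greedy LD clumping with in-region priority.

    Variants shared by the summary statistics and the target cohort are
    swept in (in_set descending, p ascending, position, id) order; each
    unclaimed variant becomes a clump index and claims unclaimed variants
    within ``window`` bp on its chromosome whose dosage r^2 with it exceeds
    ``r2_max``. r^2 is computed from target dosages with per-variant mean
    imputation of missing values.
    """
    if window < 0:
        raise ValidationError("window must be non-negative")
    if not 0.0 <= r2_max <= 1.0:
        raise ValidationError("r2_max must lie in [0, 1]")
    gv = geno.variants.reset_index().rename(columns={"index": "_col"})
    merged = sumstats.table.merge(gv[["variant_id", "_col"]], on="variant_id")
    if merged.empty:
        raise ValidationError("no variants shared between sumstats and genotypes")
    merged = merged.reset_index(drop=True)
    if region_set is not None:
        in_set = positions_in_regions(merged["chrom"], merged["pos"], region_set)
    else:
        in_set = np.zeros(len(merged), dtype=bool)

    dose = _imputed_dosages(geno, merged["_col"].to_numpy())
    centered = dose - dose.mean(axis=0, keepdims=True)
    ss = (centered ** 2).sum(axis=0)

    pos = merged["pos"].to_numpy(dtype=np.int64)
    chrom = merged["chrom"].to_numpy(dtype=object)
    p = merged["p"].to_numpy(dtype=float)
    vid = merged["variant_id"].to_numpy(dtype=object)
    order = np.lexsort((vid, pos, p, ~in_set))

    claimed = np.zeros(len(merged), dtype=bool)
    retained_idx: list[int] = []
    clumps: dict[str, list[str]] = {}
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        retained_idx.append(i)
        cand = np.flatnonzero(
            ~claimed & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window))
        members: list[str] = []
        if cand.size:
            num = centered[:, cand].T @ centered[:, i]
            denom = np.sqrt(ss[cand] * ss[i])
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(denom > 0, (num / denom) ** 2, 0.0)
            hit = cand[r2 > r2_max]
            claimed[hit] = True
            members = [str(v) for v in vid[hit]]
        clumps[str(vid[i])] = members

    retained = merged.iloc[retained_idx][
        ["variant_id", "chrom", "pos", "p", "beta", "effect_allele",
         "other_allele"]].copy()
    retained["in_set"] = in_set[retained_idx]
    retained["n_clumped"] = [len(clumps[v]) for v in retained["variant_id"]]
    return ClumpedPanel(retained.reset_index(drop=True), clumps)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class PRSResult:
    sample_ids: list[str]
    scores: np.ndarray
    n_snps: int
    threshold: float
    label: str = "prs"
    variant_ids: list[str] = field(default_factory=list)


def _harmonized_beta(panel_rows: pd.DataFrame, geno_variants: pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Align panel effect sizes with target-cohort dosage orientation.

    Returns genotype column indices and effect sizes; an effect/other swap
    negates beta, an allele mismatch drops the variant with a warning.
    """
    gv = geno_variants.reset_index().rename(columns={"index": "_col"})
    m = panel_rows.merge(gv[["variant_id", "_col", "effect_allele",
                             "other_allele"]],
                         on="variant_id", suffixes=("", "_geno"))
    same = (m["effect_allele"] == m["effect_allele_geno"]) & \
        (m["other_allele"] == m["other_allele_geno"])
    flipped = (m["effect_allele"] == m["other_allele_geno"]) & \
        (m["other_allele"] == m["effect_allele_geno"])
    mismatch = ~(same | flipped)
    if mismatch.any():
        warnings.warn(f"{int(mismatch.sum())} variant(s) dropped: allele mismatch")
        m = m[~mismatch]
        same, flipped = same[~mismatch], flipped[~mismatch]
    beta = m["beta"].to_numpy(dtype=float) * np.where(same, 1.0, -1.0)
    return m["_col"].to_numpy(), beta


def _score(geno: GenotypeDataset, rows: pd.DataFrame, threshold: float,
           label: str) -> PRSResult:
    if rows.empty:
        raise ValidationError(f"no variants included at threshold {threshold}")
    cols, beta = _harmonized_beta(rows, geno.variants)
    if cols.size == 0:
        raise ValidationError(f"no variants included at threshold {threshold}")
    dose = _imputed_dosages(geno, cols)
    scores = dose @ beta
    vids = list(geno.variants["variant_id"].iloc[cols])
    return PRSResult(list(geno.sample_ids), scores, int(cols.size),
                     float(threshold), label, vids)


def score_prs(geno: GenotypeDataset, panel: ClumpedPanel, sumstats: SumStats,
              p_threshold: float = 1.0, restrict_to_set: bool = False,
              label: str = "prs") -> PRSResult:
    """Additive C+T score over retained panel variants with p <= threshold
    (and inside the region set when ``restrict_to_set``). Missing dosages
    are mean-imputed per variant; effect-allele orientation is harmonized
    against the target cohort."""
    rows = panel.retained[panel.retained["p"] <= p_threshold]
    if restrict_to_set:
        rows = rows[rows["in_set"]]
    return _score(geno, rows, p_threshold, label)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class PRSEvaluation:
    prs_r2: float
    full_r2: float
    null_r2: float
    n_samples: int
    method: str = "nagelkerke"
    competitive_p: float | None = None
    n_perm: int = 0


def _design(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Numeric covariate design and a completeness mask."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0)), np.ones(n, dtype=bool)
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    mask = ~X.isna().any(axis=1).to_numpy()
    return X.to_numpy(dtype=float), mask


def _pseudo_r2(y: np.ndarray, X: np.ndarray, method: str) -> float:
    """Pseudo-R^2 of a logistic model against the intercept-only model."""
    n = len(y)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception:
        # collinear design or separation: Newton's Hessian is singular; BFGS
        # still converges to the (non-unique) maximum-likelihood fit
        try:
            fit = sm.Logit(y, Xc).fit(method="bfgs", disp=0, maxiter=500)
        except Exception as exc:
            raise ValidationError(f"logistic fit failed: {exc}") from exc
    if not np.isfinite(fit.llf):
        raise ValidationError("logistic fit did not converge (non-finite llf)")
    ll_model, ll_null = fit.llf, fit.llnull
    if method == "mcfadden":
        return float(1.0 - ll_model / ll_null)
    cs = 1.0 - np.exp(2.0 / n * (ll_null - ll_model))
    max_cs = 1.0 - np.exp(2.0 / n * ll_null)
    return float(cs / max_cs)


def evaluate_prs(prs: PRSResult, geno: GenotypeDataset,
                 method: str = "nagelkerke") -> PRSEvaluation:
    """PRS.R^2: pseudo-R^2 of the full logistic model (phenotype ~ PRS +
    covariates) minus the covariates-only null model, on the identical
    complete-covariate sample set."""
    if list(prs.sample_ids) != list(geno.sample_ids):
        raise ValidationError("PRS and genotype samples do not match")
    y = geno.phenotype.astype(float)
    cov, mask = _design(geno.covariates, len(y))
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropping %d rows with incomplete covariates", n_dropped)
    y, cov = y[mask], cov[mask]
    score = np.asarray(prs.scores)[mask]
    full = _pseudo_r2(y, np.column_stack([score, cov]), method)
    null = _pseudo_r2(y, cov, method) if cov.shape[1] else 0.0
    return PRSEvaluation(full - null, full, null, int(mask.sum()), method)


def competitive_p(observed: PRSEvaluation, background_panel: ClumpedPanel,
                  geno: GenotypeDataset, n_snps: int,
                  n_perm: int = 10_000, seed: int = 0,
                  method: str = "nagelkerke") -> PRSEvaluation:
    """Competitive permutation p value for a region-set PRS.

    Each permutation draws ``n_snps`` variants (the observed score's SNP
    count) from the post-clumping background pool, scores them identically
    and recomputes prs_r2; p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    pool = background_panel.retained
    if len(pool) < n_snps:
        raise ValidationError(
            f"background pool ({len(pool)}) smaller than panel ({n_snps})")
    rng = np.random.default_rng(seed)
    y = geno.phenotype.astype(float)
    cov, mask = _design(geno.covariates, len(y))
    y, cov = y[mask], cov[mask]
    null = _pseudo_r2(y, cov, method) if cov.shape[1] else 0.0

    cols_all, beta_all = _harmonized_beta(pool, geno.variants)
    dose_all = _imputed_dosages(geno, cols_all)[mask]
    n_ge = 0
    for _ in range(n_perm):
        pick = rng.choice(len(cols_all), size=n_snps, replace=False)
        score = dose_all[:, pick] @ beta_all[pick]
        r2 = _pseudo_r2(y, np.column_stack([score, cov]), method) - null
        if r2 >= observed.prs_r2:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return replace(observed, competitive_p=p, n_perm=n_perm)


def threshold_scan(panel: ClumpedPanel, geno: GenotypeDataset,
                   sumstats: SumStats, thresholds: list[float],
                   restrict_to_set: bool = False,
                   method: str = "nagelkerke") -> pd.DataFrame:
    """Evaluate the PRS at each p-value threshold; the best threshold is the
    prs_r2 argmax. Thresholds yielding an empty score are reported with
    n_snps 0 and NaN prs_r2."""
    if any(t <= 0 or t > 1 for t in thresholds):
        raise ValidationError("thresholds must lie in (0, 1]")
    rows = []
    for t in thresholds:
        try:
            prs = score_prs(geno, panel, sumstats, p_threshold=t,
                            restrict_to_set=restrict_to_set)
            ev = evaluate_prs(prs, geno, method=method)
            rows.append((t, prs.n_snps, ev.prs_r2, ev.full_r2, ev.null_r2))
        except ValidationError:
            rows.append((t, 0, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["threshold", "n_snps", "prs_r2",
                                      "full_r2", "null_r2"])
    out["best"] = False
    if out["prs_r2"].notna().any():
        out.loc[out["prs_r2"].idxmax(), "best"] = True
    return out


def hybrid_prs(panel_genomewide: ClumpedPanel, peak_regions: RegionSet,
               sumstats: SumStats, geno: GenotypeDataset,
               t_strong: float, t_weak: float = 1.0) -> PRSResult:
    """Hybrid score: every retained SNP with p <= ``t_strong`` regardless of
    regulatory annotation, plus retained SNPs with t_strong < p <= t_weak
    whose position falls inside ``peak_regions``."""
    if t_strong > t_weak:
        raise ValidationError("t_strong must be <= t_weak")
    ret = panel_genomewide.retained
    in_peaks = positions_in_regions(ret["chrom"], ret["pos"], peak_regions)
    include = (ret["p"] <= t_strong) | \
        ((ret["p"] > t_strong) & (ret["p"] <= t_weak) & in_peaks)
    return _score(geno, ret[include], t_weak, "hybrid")
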