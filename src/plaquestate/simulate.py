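"""Seeded generators for single-cell, bulk and genetic inputs.

The generators emulate the statistical structure the downstream analyses
assume rather than the upstream measurement process:

* single-cell libraries are isotropic Gaussian cell-type clusters on a given
  2-D embedding, with a planted disease-expanded subpopulation of one cell
  type displaced to its own territory and over-expressing a marker program;
* bulk samples are proportion-weighted mixtures of expression profiles with
  multiplicative log-normal noise;
* genotypes follow a Gaussian-threshold model with block-constant latent
  correlation (contiguous LD blocks on a uniform physical grid), a liability
  threshold case/control phenotype, and an independent base cohort from
  which per-variant logistic score-test summary statistics are computed.

All generators are pure functions of their configuration: the same seed
yields byte-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import (CellTable, CountMatrix, GenotypeDataset, RegionSet, SumStats,
                 ValidationError)

_P_FLOOR = 1e-300  # SumStats requires p > 0


# ---------------------------------------------------------------------------
# Configurations and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SCSimConfig:
    """Single-cell scenario: cell-type clusters plus one planted state.

    ``state_fraction_by_condition`` gives the fraction of cells of the
    designated cell type (type 0) that belong to the planted state in each
    condition; one library is emitted per condition. ``state_offset``
    displaces state cells in the embedding relative to their parent cluster
    centre. Cluster centres are laid on a coarse grid (``center_spacing``)
    so that a 50 x 50 selection grid resolves each cluster into sectors of
    roughly one cluster standard deviation.
    """

    n_cell_types: int = 3
    cells_per_library: int = 2000
    state_fraction_by_condition: dict[str, float] = field(
        default_factory=lambda: {"control": 0.05, "late": 0.30})
    state_offset: tuple[float, float] = (40.0, 40.0)
    n_genes: int = 600
    n_marker_genes: int = 50
    marker_log2_fc: float = 1.5
    nb_dispersion: float = 0.5
    cluster_sd: float = 1.0
    state_sd_scale: float = 0.5  # state cells form a compact sub-cluster
    center_spacing: float = 40.0
    n_type_genes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, frac in self.state_fraction_by_condition.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"state fraction for {cond!r} outside [0, 1]")
        if self.n_marker_genes > self.n_genes:
            raise ValidationError("more marker genes than genes")
        if self.marker_log2_fc < 0 or self.nb_dispersion <= 0:
            raise ValidationError("marker_log2_fc must be >= 0 and nb_dispersion > 0")


@dataclass
class GWASSimConfig:
    """Case/control GWAS scenario under the liability threshold model."""

    n_variants: int = 1000
    n_blocks: int = 200
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 20
    causal_region_set: RegionSet | None = None  # None = whole genome
    h2_liability: float = 0.3
    prevalence: float = 0.2
    n_base: int = 5000
    n_target: int = 4000
    variant_spacing: int = 5000  # bp between adjacent variants
    chrom: str = "1"
    target_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_variants:
            raise ValidationError("n_causal > n_variants")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValidationError("within_block_r must be in [0, 1)")
        if not 0.0 <= self.h2_liability < 1.0:
            raise ValidationError("h2_liability must be in [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must be in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each synthetic dataset."""

    state_cell_ids: list[str] = field(default_factory=list)
    marker_genes: list[str] = field(default_factory=list)
    state_cell_type: str = ""
    expected_state_fractions: dict[str, float] = field(default_factory=dict)
    causal_variant_ids: list[str] = field(default_factory=list)
    causal_effects: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Single-cell scenario
# ---------------------------------------------------------------------------

def _cluster_centers(n_types: int, spacing: float) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_types)))
    centers = [(spacing * (i % side), spacing * (i // side)) for i in range(n_types)]
    return np.asarray(centers, dtype=float)


def simulate_single_cell(config: SCSimConfig) -> tuple[CellTable, CountMatrix, TruthRecord]:
    """Generate one library per condition with a planted cell state.

    State cells of cell type 0 are displaced by ``state_offset`` in the
    embedding and have the negative-binomial means of the planted marker
    genes multiplied by ``2 ** marker_log2_fc``.
    """
    if any(f > 0 for f in config.state_fraction_by_condition.values()) and \
            config.state_offset == (0.0, 0.0):
        warnings.warn("state_offset is zero with nonzero state fraction: "
                      "the planted state is undetectable in the embedding")
    rng = np.random.default_rng(config.seed)
    centers = _cluster_centers(config.n_cell_types, config.center_spacing)

    # gene model: lognormal baseline, elevated baseline for planted markers,
    # per-type identity genes upregulated 4x
    base_mu = rng.lognormal(mean=-1.0, sigma=1.0, size=config.n_genes)
    genes = [f"gene{g}" for g in range(config.n_genes)]
    marker_idx = rng.choice(config.n_genes, size=config.n_marker_genes, replace=False)
    base_mu[marker_idx] = rng.uniform(0.5, 2.0, size=config.n_marker_genes)
    type_gene_idx = {}
    pool = np.setdiff1d(np.arange(config.n_genes), marker_idx)
    pool = rng.permutation(pool)
    for t in range(config.n_cell_types):
        type_gene_idx[t] = pool[t * config.n_type_genes:(t + 1) * config.n_type_genes]

    conditions = list(config.state_fraction_by_condition)
    rows, count_cols, state_ids = [], [], []
    r_size = 1.0 / config.nb_dispersion
    for cond in conditions:
        lib = f"lib_{cond}"
        frac = config.state_fraction_by_condition[cond]
        cell_types = rng.integers(0, config.n_cell_types,
                                  size=config.cells_per_library)
        is_state = (cell_types == 0) & (rng.random(config.cells_per_library) < frac)
        xy = centers[cell_types] + rng.normal(0.0, config.cluster_sd,
                                              size=(config.cells_per_library, 2))
        # state cells: compact sub-cluster displaced to its own territory
        xy[is_state] = (centers[0] + np.asarray(config.state_offset)
                        + (xy[is_state] - centers[0]) * config.state_sd_scale)
        for i in range(config.cells_per_library):
            cid = f"{lib}:cell{i}"
            t = int(cell_types[i])
            mu = base_mu.copy()
            mu[type_gene_idx[t]] *= 4.0
            if is_state[i]:
                mu[marker_idx] *= 2.0 ** config.marker_log2_fc
                state_ids.append(cid)
            counts = rng.negative_binomial(r_size, r_size / (r_size + mu))
            count_cols.append(counts)
            rows.append((cid, lib, cond, xy[i, 0], xy[i, 1], f"type{t}"))

    cells = CellTable(
        pd.DataFrame(rows, columns=["cell_id", "library_id", "condition",
                                    "x", "y", "cell_type"]),
        tuple(conditions),
    )
    counts = CountMatrix(genes, [r[0] for r in rows],
                         np.column_stack(count_cols), layer="raw_counts")
    truth = TruthRecord(
        state_cell_ids=state_ids,
        marker_genes=[genes[g] for g in sorted(marker_idx)],
        state_cell_type="type0",
        expected_state_fractions={c: f / config.n_cell_types for c, f in
                                  config.state_fraction_by_condition.items()},
    )
    return cells, counts, truth


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """Library-size normalize to ``scale`` counts per cell and log1p."""
    totals = counts.values.sum(axis=0, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    vals = np.log1p(counts.values / totals * scale)
    return CountMatrix(list(counts.genes), list(counts.names), vals, layer="lognorm")


# ---------------------------------------------------------------------------
# Bulk mixtures
# ---------------------------------------------------------------------------

def simulate_bulk(cell_profiles: CountMatrix, proportions: pd.DataFrame,
                  noise_sd: float, seed: int) -> CountMatrix:
    """Mix expression profiles into bulk samples.

    ``proportions`` is samples x profiles and every row must sum to 1;
    sample expression is the proportion-weighted mean of the profiles with
    multiplicative log-normal noise of scale ``noise_sd``.
    """
    props = proportions.to_numpy(dtype=float)
    if (props < 0).any():
        raise ValidationError("negative mixing proportion")
    if not np.allclose(props.sum(axis=1), 1.0):
        raise ValidationError("mixing proportions must sum to 1 per sample")
    missing = [c for c in proportions.columns if c not in cell_profiles.names]
    if missing:
        raise ValidationError(f"profiles absent from matrix: {missing}")
    rng = np.random.default_rng(seed)
    prof = cell_profiles.to_frame()[list(proportions.columns)].to_numpy(dtype=float)
    mix = prof @ props.T  # genes x samples
    if noise_sd > 0:
        mix = mix * rng.lognormal(0.0, noise_sd, size=mix.shape)
    return CountMatrix(list(cell_profiles.genes), list(proportions.index.astype(str)),
                       mix, layer="tpm")


# ---------------------------------------------------------------------------
# GWAS scenario
# ---------------------------------------------------------------------------

def _threshold_genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray,
                         blocks: np.ndarray, r: float) -> np.ndarray:
    """Two latent Gaussian haplotype draws per sample, block-constant latent
    correlation ``r``, thresholded at the per-variant MAF quantile."""
    m = len(mafs)
    thresh = stats.norm.ppf(mafs)
    dosage = np.zeros((n, m), dtype=float)
    for hap in range(2):
        shared = rng.normal(size=(n, blocks.max() + 1))
        indiv = rng.normal(size=(n, m))
        latent = np.sqrt(r) * shared[:, blocks] + np.sqrt(1.0 - r) * indiv
        dosage += (latent < thresh[None, :]).astype(float)
    return dosage


def _in_regions(chrom: str, pos: np.ndarray, regions: RegionSet | None) -> np.ndarray:
    """1-based positions against 0-based half-open intervals."""
    if regions is None:
        return np.ones(len(pos), dtype=bool)
    mask = np.zeros(len(pos), dtype=bool)
    sub = regions.intervals[regions.intervals["chrom"] == chrom]
    for row in sub.itertuples(index=False):
        mask |= (pos >= row.start + 1) & (pos <= row.end)
    return mask


def logistic_score_test(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-variant logistic score test (intercept-only null).

    Returns the one-step effect estimate ``U / V`` (on the log-odds scale)
    and the two-sided p value of the score statistic.
    """
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    g = dosages - dosages.mean(axis=0, keepdims=True)
    u = g.T @ (y - ybar)
    v = ybar * (1.0 - ybar) * (g ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(v > 0, u / v, 0.0)
        z = np.where(v > 0, u / np.sqrt(v), 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    return beta, p


def _hwe_p(dosages: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) Hardy-Weinberg test per variant on hard genotypes."""
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        g = dosages[:, j]
        g = g[~np.isnan(g)]
        n = len(g)
        if n == 0:
            continue
        n_aa = np.sum(g == 0)
        n_ab = np.sum(g == 1)
        n_bb = np.sum(g == 2)
        p_allele = (2 * n_bb + n_ab) / (2.0 * n)
        exp = np.array([(1 - p_allele) ** 2, 2 * p_allele * (1 - p_allele),
                        p_allele ** 2]) * n
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        nz = exp > 0
        chi2 = ((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum()
        out[j] = stats.chi2.sf(chi2, df=1)
    return out


def simulate_gwas(config: GWASSimConfig) -> tuple[SumStats, GenotypeDataset, TruthRecord]:
    """Generate an independent base cohort (summary statistics) and target
    cohort (dosages, phenotype, covariates) with planted causal structure.

    Causal variants are sampled only inside ``causal_region_set`` and their
    standardized effects are scaled so the realized liability variance
    explained equals ``h2_liability``; case status thresholds the liability
    at the standard-normal ``1 - prevalence`` quantile.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    pos = (np.arange(m, dtype=int) * config.variant_spacing) + 1
    blocks = (np.arange(m) * config.n_blocks) // m
    mafs = rng.uniform(*config.maf_range, size=m)
    alleles = rng.permuted(
        np.tile(np.array([["A", "G"], ["C", "T"], ["A", "C"], ["G", "T"]]),
                (m // 4 + 1, 1))[:m], axis=1)
    vids = [f"rs{i}" for i in range(m)]

    eligible = np.flatnonzero(_in_regions(config.chrom, pos, config.causal_region_set))
    if config.n_causal > 0 and len(eligible) == 0:
        raise ValidationError("causal_region_set contains no variants")
    causal = rng.choice(eligible, size=min(config.n_causal, len(eligible)),
                        replace=False) if config.n_causal else np.array([], dtype=int)
    raw_effects = rng.normal(size=len(causal))

    def liability_and_pheno(dose: np.ndarray) -> np.ndarray:
        n = dose.shape[0]
        if config.h2_liability > 0 and len(causal):
            x = dose[:, causal]
            x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
            g = x @ raw_effects
            sd = g.std()
            g = g / (sd if sd > 0 else 1.0) * np.sqrt(config.h2_liability)
        else:
            g = np.zeros(n)
        liab = g + rng.normal(0.0, np.sqrt(1.0 - config.h2_liability), size=n)
        return (liab > stats.norm.ppf(1.0 - config.prevalence)).astype(int)

    # base cohort -> summary statistics
    base_dose = _threshold_genotypes(rng, config.n_base, mafs, blocks,
                                     config.within_block_r)
    y_base = liability_and_pheno(base_dose)
    beta, p = logistic_score_test(base_dose, y_base)
    ss = SumStats(pd.DataFrame({
        "variant_id": vids,
        "chrom": config.chrom,
        "pos": pos,
        "effect_allele": alleles[:, 0],
        "other_allele": alleles[:, 1],
        "beta": beta,
        "p": p,
        "info": 1.0,
        "eaf": base_dose.mean(axis=0) / 2.0,
    }))

    # independent target cohort
    targ_dose = _threshold_genotypes(rng, config.n_target, mafs, blocks,
                                     config.within_block_r)
    y_targ = liability_and_pheno(targ_dose)
    if config.target_missing_rate > 0:
        mask = rng.random(targ_dose.shape) < config.target_missing_rate
        targ_dose = np.where(mask, np.nan, targ_dose)
    freq = np.nanmean(targ_dose, axis=0) / 2.0
    variants = pd.DataFrame({
        "variant_id": vids,
        "chrom": config.chrom,
        "pos": pos,
        "effect_allele": alleles[:, 0],
        "other_allele": alleles[:, 1],
        "maf": np.minimum(freq, 1.0 - freq),
        "info": 1.0,
        "missingness": np.isnan(targ_dose).mean(axis=0),
        "hwe_p": _hwe_p(targ_dose),
    })
    covariates = pd.DataFrame({
        "sex": rng.integers(0, 2, size=config.n_target),
        "age": rng.normal(60.0, 8.0, size=config.n_target),
    })
    geno = GenotypeDataset(
        [f"s{i}" for i in range(config.n_target)], variants, targ_dose,
        y_targ, covariates,
    )
    truth = TruthRecord(
        causal_variant_ids=[vids[i] for i in sorted(causal)],
        causal_effects={vids[i]: float(e) for i, e in zip(causal, raw_effects)},
    )
    return ss, geno, truth
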