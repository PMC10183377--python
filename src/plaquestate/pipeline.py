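"""End-to-end orchestration: simulate -> states -> markers -> score -> prs.

A single YAML-able configuration drives every stage; per-stage seeds are
derived deterministically from the global seed by hashing the stage name, so
an individual stage rerun reproduces its output bit for bit. Every
intermediate is a file in one of the package's text formats and the run
manifest records a checksum for each.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (GeneSet, RegionSet, ValidationError, read_cell_table,
                 read_counts_mtx, write_cell_table, write_counts_mtx,
                 write_genotypes, write_gmt, write_matrix_tsv, write_regions,
                 write_sumstats, read_genotypes, read_sumstats, read_regions)
from .markers import find_markers, truncate_signature
from .prs import (competitive_p, evaluate_prs, preferential_clump, qc_base,
                  qc_target, score_prs, threshold_scan)
from .scoring import module_score, quantile_normalize
from .simulate import (GWASSimConfig, SCSimConfig, TruthRecord, lognormalize,
                       simulate_bulk, simulate_gwas, simulate_single_cell)
from .states import (GridSpec, assemble_states, build_occupancy, sector_of,
                     sector_fold_change, state_fractions)

STAGES = ("simulate", "states", "markers", "score", "prs")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    out_dir: str = "plaquestate_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    # state discovery
    grid_bins: int = 50
    threshold_log2: float = 1.0
    min_cells: int = 5
    min_state_cells: int = 20
    # markers
    min_pct: float = 0.10
    min_logfc: float = 0.25
    alpha: float = 0.05
    # scoring
    n_bins: int = 25
    n_ctrl: int = 100
    n_bulk_per_group: int = 12
    bulk_noise_sd: float = 0.2
    # prs
    p_thresholds: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.5, 1.0)
    clump_window: int = 500_000
    clump_r2: float = 0.2
    n_perm: int = 199
    # simulators (None = module defaults)
    sc: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if not self.stages.get("simulate", False):
            for s in STAGES[1:]:
                if self.stages.get(s, False):
                    raise ValidationError(
                        f"stage {s!r} requires the simulate stage (or existing inputs)")
        if self.grid_bins < 1 or self.n_perm < 1:
            raise ValidationError("grid_bins and n_perm must be positive")
        if any(t <= 0 or t > 1 for t in self.p_thresholds):
            raise ValidationError("p_thresholds must lie in (0, 1]")


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    checksums: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order, writing all
    intermediates under ``config.out_dir`` and a manifest at the end."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = yaml.safe_dump(asdict(config), sort_keys=True)
    manifest = RunManifest(hashlib.sha256(cfg_yaml.encode()).hexdigest(),
                           __version__)

    def record(stage: str, *paths: Path) -> None:
        manifest.timestamps[stage] = time.time()
        for p in paths:
            manifest.checksums[str(p.relative_to(out))] = _checksum(p)

    enabled = {s for s in STAGES if config.stages.get(s, False)}

    cells = counts = truth_sc = None
    sumstats = geno = truth_gwas = None
    if "simulate" in enabled:
        sc_cfg = SCSimConfig(**{**config.sc, "seed": stage_seed(config.seed, "simulate_sc")})
        cells, counts, truth_sc = simulate_single_cell(sc_cfg)
        write_cell_table(cells, out / "cells.tsv")
        write_counts_mtx(counts, out / "counts.mtx", out / "features.tsv",
                         out / "barcodes.tsv")
        truth_sc.to_json(out / "truth_sc.json")
        gw_kwargs = dict(config.gwas)
        regions = gw_kwargs.pop("causal_region_set", None)
        if regions is None:
            # default planted region set: 10 windows of 100 kb
            iv = pd.DataFrame({"chrom": "1",
                               "start": np.arange(10) * 450_000,
                               "end": np.arange(10) * 450_000 + 100_000})
            regions = RegionSet("causal", iv)
        gwas_cfg = GWASSimConfig(causal_region_set=regions,
                                 **{**gw_kwargs,
                                    "seed": stage_seed(config.seed, "simulate_gwas")})
        sumstats, geno, truth_gwas = simulate_gwas(gwas_cfg)
        write_sumstats(sumstats, out / "sumstats.tsv")
        write_genotypes(geno, out / "dosages.tsv", out / "variants.tsv",
                        out / "phenotype.tsv", out / "covariates.tsv")
        write_regions(regions, out / "causal_regions.bed")
        truth_gwas.to_json(out / "truth_gwas.json")
        record("simulate", out / "cells.tsv", out / "counts.mtx",
               out / "sumstats.tsv", out / "dosages.tsv")

    states = []
    grid = GridSpec(config.grid_bins, config.grid_bins)
    if "states" in enabled:
        occ = build_occupancy(cells, grid)
        conds = cells.condition_order
        lib_by_cond = {c: [l for l, cc in cells.library_condition().items() if cc == c]
                       for c in conds}
        calls = sector_fold_change(occ, lib_by_cond[conds[-1]], lib_by_cond[conds[0]],
                                   config.threshold_log2, config.min_cells)
        states = assemble_states(cells, calls, grid, config.min_state_cells)
        pd.DataFrame([(c.sector[0], c.sector[1], c.log2_fc, c.flagged,
                       c.n_cells_pooled) for c in calls],
                     columns=["i", "j", "log2_fc", "flagged", "n_cells"]
                     ).to_csv(out / "sector_calls.tsv", sep="\t", index=False)
        pd.DataFrame([(s.state_id, cid, s.cell_type) for s in states
                      for cid in s.cell_ids],
                     columns=["state_id", "cell_id", "cell_type"]
                     ).to_csv(out / "state_assignments.tsv", sep="\t", index=False)
        state_fractions(cells, states).to_csv(out / "state_fractions.tsv",
                                              sep="\t", index=False)
        record("states", out / "sector_calls.tsv", out / "state_assignments.tsv",
               out / "state_fractions.tsv")

    signatures: list[GeneSet] = []
    lognorm = None
    if "markers" in enabled:
        lognorm = lognormalize(counts)
        bounds = grid.resolve_bounds(cells)
        ix, iy = sector_of(cells.cells["x"].to_numpy(float),
                           cells.cells["y"].to_numpy(float), grid, bounds)
        flagged_sectors = {s for st in states for s in st.sectors}
        in_flagged = np.array([(i, j) in flagged_sectors for i, j in zip(ix, iy)])
        tables = []
        for st in states:
            same_type = (cells.cells["cell_type"] == st.cell_type).to_numpy()
            ref = cells.cells.loc[same_type & ~in_flagged, "cell_id"].tolist()
            if len(ref) < 3 or len(st.cell_ids) < 3:
                continue
            tab = find_markers(lognorm, st.cell_ids, ref, state_id=st.state_id,
                               min_pct=config.min_pct, min_logfc=config.min_logfc,
                               alpha=config.alpha)
            tables.append(tab)
            sig = tab[tab["significant"]]
            if len(sig):
                signatures.append(truncate_signature(tab, top_n=len(sig),
                                                     name=st.state_id))
        all_tab = pd.concat(tables) if tables else pd.DataFrame()
        all_tab.to_csv(out / "markers.tsv", sep="\t", index=False)
        write_gmt(signatures, out / "signatures.gmt")
        record("markers", out / "markers.tsv", out / "signatures.gmt")

    if "score" in enabled:
        # bulk mixtures: per-cell-type mean profiles plus the dominant state,
        # lesion samples enriched for state content
        seed = stage_seed(config.seed, "score")
        prof_frames, prof_names = [], []
        df = cells.cells
        for t in sorted(df["cell_type"].unique()):
            sel = (df["cell_type"] == t).to_numpy()
            prof_frames.append(counts.values[:, sel].mean(axis=1))
            prof_names.append(t)
        state_ids = set(truth_sc.state_cell_ids) if truth_sc else set()
        in_state = df["cell_id"].isin(state_ids).to_numpy()
        if in_state.any():
            prof_frames.append(counts.values[:, in_state].mean(axis=1))
            prof_names.append("planted_state")
        from .io import CountMatrix
        profiles = CountMatrix(list(counts.genes), prof_names,
                               np.column_stack(prof_frames), layer="tpm")
        n = config.n_bulk_per_group
        base = np.full(len(prof_names), 1.0 / max(1, len(prof_names) - 1))
        rows, labels = [], []
        for grp, state_frac in (("control", 0.02), ("lesion", 0.25)):
            for k in range(n):
                w = base.copy()
                if "planted_state" in prof_names:
                    w[prof_names.index("planted_state")] = 0.0
                    w = w / w.sum() * (1 - state_frac)
                    w[prof_names.index("planted_state")] = state_frac
                rows.append(w)
                labels.append((f"{grp}{k}", grp))
        props = pd.DataFrame(rows, columns=prof_names,
                             index=[l[0] for l in labels])
        bulk = simulate_bulk(profiles, props, config.bulk_noise_sd, seed)
        logged = bulk
        logged.values = np.log1p(logged.values)
        qn = quantile_normalize(logged)
        if signatures:
            scores = module_score(qn, signatures, config.n_bins, config.n_ctrl, seed)
            scores.insert(0, "group", [l[1] for l in labels])
            scores.to_csv(out / "module_scores.tsv", sep="\t",
                          index_label="sample")
            record("score", out / "module_scores.tsv")

    if "prs" in enabled:
        seed = stage_seed(config.seed, "prs")
        ss_qc, base_report = qc_base(sumstats)
        geno_qc, targ_report = qc_target(geno)
        regions = read_regions(out / "causal_regions.bed", name="causal")
        panel = preferential_clump(ss_qc, geno_qc, regions,
                                   config.clump_window, config.clump_r2)
        scan = threshold_scan(panel, geno_qc, ss_qc, list(config.p_thresholds),
                              restrict_to_set=True)
        scan.to_csv(out / "prs_scan.tsv", sep="\t", index=False)
        best_t = float(scan.loc[scan["best"], "threshold"].iloc[0])
        prs = score_prs(geno_qc, panel, ss_qc, best_t, restrict_to_set=True,
                        label="region_set")
        ev = evaluate_prs(prs, geno_qc)
        bg_panel = preferential_clump(ss_qc, geno_qc, None,
                                      config.clump_window, config.clump_r2)
        ev = competitive_p(ev, bg_panel, geno_qc, prs.n_snps,
                           n_perm=config.n_perm, seed=seed)
        pd.DataFrame({"sample_id": prs.sample_ids, "score": prs.scores}
                     ).to_csv(out / "prs_scores.tsv", sep="\t", index=False)
        with open(out / "prs_evaluation.json", "w") as fh:
            json.dump({
                "base_qc": asdict(base_report), "target_qc": asdict(targ_report),
                "n_snps": prs.n_snps, "threshold": best_t,
                "prs_r2": ev.prs_r2, "full_r2": ev.full_r2, "null_r2": ev.null_r2,
                "competitive_p": ev.competitive_p, "n_perm": ev.n_perm,
                "seed": seed,
            }, fh, indent=1)
        record("prs", out / "prs_scores.tsv", out / "prs_evaluation.json",
               out / "prs_scan.tsv")

    manifest.to_json(out / "manifest.json")
    return manifest


def demo_config(out_dir: str = "plaquestate_demo", seed: int = 7) -> PipelineConfig:
    """The bundled synthetic scenario: two libraries with a planted 6x
    disease-expanded state, and a 1,000-variant GWAS with causal effects
    confined to a region set."""
    return PipelineConfig(
        out_dir=out_dir, seed=seed,
        gwas={"n_base": 3000, "n_target": 2000, "n_variants": 800},
        n_perm=199,
    )
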