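"""Cell-state marker signatures and gene-list enrichment.

Markers of a disease-increased state are genes upregulated in state cells
relative to unchanged cells of the same cell type (two-sided Wilcoxon
rank-sum, min.pct 0.1, log fold change 0.25, BH FDR < 0.05). Enrichment of
external candidate lists against a signature uses the upper-tail
hypergeometric test with the expressed-gene universe as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneSet, ValidationError

MARKER_COLUMNS = ("state_id", "gene", "log_fc", "pct_state", "pct_ref",
                  "p", "p_adj", "significant")


def _wilcoxon_p(x_state: np.ndarray, x_ref: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (rows).

    Exact for small untied groups, normal approximation with tie correction
    otherwise (the behaviour of R's wilcox.test, which backs the ecosystem
    convention for marker detection).
    """
    n1, n2 = x_state.shape[1], x_ref.shape[1]
    if min(n1, n2) <= 8:
        out = np.empty(x_state.shape[0])
        for g in range(x_state.shape[0]):
            with np.errstate(invalid="ignore"):
                res = stats.mannwhitneyu(x_state[g], x_ref[g],
                                         alternative="two-sided", method="auto")
            out[g] = res.pvalue
    else:
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(x_state, x_ref, alternative="two-sided",
                                     method="asymptotic", axis=1)
        out = np.atleast_1d(res.pvalue)
    return np.nan_to_num(out, nan=1.0)


def find_markers(counts: CountMatrix, state_cells: list[str],
                 reference_cells: list[str], state_id: str = "state",
                 min_pct: float = 0.10, min_logfc: float = 0.25,
                 alpha: float = 0.05, logfc_base: float = np.e) -> pd.DataFrame:
    """Differential expression of state cells against reference cells.

    ``counts`` must be log-normalized. Genes enter the test only if expressed
    (value > 0) in at least ``min_pct`` of one group and their log fold
    change of mean de-logged expression reaches ``min_logfc`` in magnitude.
    BH adjustment runs over the tested genes; retained markers
    (``significant``) have ``p_adj < alpha`` and positive fold change.
    Sub-threshold tested genes stay in the table with ``significant=False``
    so ranked truncation can extend past the threshold.
    """
    if counts.layer != "lognorm":
        raise ValidationError("find_markers expects a lognorm matrix")
    state_cells, reference_cells = list(state_cells), list(reference_cells)
    if set(state_cells) & set(reference_cells):
        raise ValidationError("state and reference cell groups overlap")
    if len(state_cells) < 3 or len(reference_cells) < 3:
        raise ValidationError("each comparison group needs at least 3 cells")
    name_idx = {n: i for i, n in enumerate(counts.names)}
    xs = counts.values[:, [name_idx[c] for c in state_cells]]
    xr = counts.values[:, [name_idx[c] for c in reference_cells]]

    pct_state = (xs > 0).mean(axis=1)
    pct_ref = (xr > 0).mean(axis=1)
    # fold change of means on the de-logged scale, re-logged (configurable base)
    mean_s = np.expm1(xs).mean(axis=1)
    mean_r = np.expm1(xr).mean(axis=1)
    log_fc = (np.log(mean_s + 1.0) - np.log(mean_r + 1.0)) / np.log(logfc_base)

    tested = ((pct_state >= min_pct) | (pct_ref >= min_pct)) & \
        (np.abs(log_fc) >= min_logfc)
    if not tested.any():
        warnings.warn("no genes pass the expression/fold-change filters")
        return pd.DataFrame(columns=MARKER_COLUMNS)

    idx = np.flatnonzero(tested)
    p = _wilcoxon_p(xs[idx], xr[idx])
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame({
        "state_id": state_id,
        "gene": [counts.genes[i] for i in idx],
        "log_fc": log_fc[idx],
        "pct_state": pct_state[idx],
        "pct_ref": pct_ref[idx],
        "p": p,
        "p_adj": p_adj,
    })
    table["significant"] = (table["p_adj"] < alpha) & (table["log_fc"] > 0)
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Signature sharing and truncation
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    gene_state_counts: pd.Series      # gene -> number of signatures containing it
    unique_per_state: dict[str, int]  # signature -> genes unique to it
    sharing_histogram: pd.Series      # k -> number of genes in exactly k signatures

    @property
    def uniqueness_fraction(self) -> float:
        total = len(self.gene_state_counts)
        return float((self.gene_state_counts == 1).sum()) / total if total else 1.0


def overlap_summary(signatures: list[GeneSet]) -> OverlapSummary:
    """Exact marker-sharing summary across signatures."""
    if not signatures:
        raise ValidationError("need at least one signature")
    counts: dict[str, int] = {}
    for sig in signatures:
        for g in sig.genes:
            counts[g] = counts.get(g, 0) + 1
    gene_counts = pd.Series(counts, dtype=int).sort_index()
    unique = {sig.name: sum(1 for g in sig.genes if counts[g] == 1)
              for sig in signatures}
    hist = gene_counts.value_counts().sort_index()
    hist.index.name = "k"
    return OverlapSummary(gene_counts, unique, hist)


def _rank_markers(markers: pd.DataFrame) -> pd.DataFrame:
    order = markers.assign(_abs_fc=markers["log_fc"].abs()).sort_values(
        ["p_adj", "_abs_fc", "gene"], ascending=[True, False, True],
        kind="mergesort")
    return order.drop(columns="_abs_fc")


def truncate_signature(markers: pd.DataFrame, top_n: int,
                       extend: bool = False, name: str | None = None) -> GeneSet:
    """Top-``top_n`` genes ranked by p_adj ascending, then |log_fc|
    descending, then gene name. With ``extend=True`` sub-threshold tested
    genes are appended by the same ranking when the significant signature is
    shorter than ``top_n``."""
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    sig = markers if "significant" not in markers.columns else \
        markers[markers["significant"]]
    ranked = _rank_markers(sig)
    genes = list(ranked["gene"].head(top_n))
    if extend and len(genes) < top_n and "significant" in markers.columns:
        extra = _rank_markers(markers[~markers["significant"]])
        genes.extend(list(extra["gene"].head(top_n - len(genes))))
    state = name or (str(markers["state_id"].iloc[0]) if len(markers) else "signature")
    return GeneSet(state, tuple(genes))


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    state_id: str
    candidate_list: str
    k: int          # overlap
    n: int          # signature size (within background)
    K: int          # candidate list size (within background)
    N: int          # background size
    p: float        # upper-tail hypergeometric
    overlap_ratio: float


def hypergeom_enrichment(signature: GeneSet, candidates: GeneSet,
                         background: GeneSet) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``candidates`` in
    ``signature`` against the expressed-gene ``background`` universe.

    Genes outside the background are dropped with a warning.
    """
    bg = set(background.genes)
    if not bg:
        raise ValidationError("empty background")
    sig = set(signature.genes)
    cand = set(candidates.genes)
    dropped = (sig - bg) | (cand - bg)
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) outside background dropped")
    sig &= bg
    cand &= bg
    k, n, K, N = len(sig & cand), len(sig), len(cand), len(bg)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(signature.name, candidates.name, k, n, K, N, p,
                            k / n if n else 0.0)
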