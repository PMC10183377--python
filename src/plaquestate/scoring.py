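"""Quantile normalization and bin-background gene-program activity scores.

Both operations are transform-shaped and exposed as scikit-learn
transformers (samples are rows, genes are columns); :func:`quantile_normalize`
and :func:`module_score` wrap them for the package's gene x sample
``CountMatrix`` containers.

The module score follows the bin-background construction: genes are binned
by average log expression across samples, and each sample's score for a gene
set is the mean expression of the set genes minus the mean of random
expression-matched control genes drawn from the same bins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix, GeneSet, ValidationError


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Force every sample onto the shared distribution of mean order
    statistics (the preprocessCore construction).

    ``fit`` stores the reference distribution (the across-sample mean of the
    per-sample sorted value vectors); ``transform`` replaces each sample's
    order statistics with the reference, giving ties the mean of the
    reference values they would jointly occupy.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D samples x genes array")
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("feature count changed between fit and transform")
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = _map_to_reference(X[i], self.reference_)
        return out


def _map_to_reference(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    assigned = np.empty_like(ref)
    assigned[order] = ref
    # ties receive the mean of the reference values they would occupy
    if len(np.unique(x)) != len(x):
        assigned = pd.Series(assigned).groupby(x).transform("mean").to_numpy()
    return assigned


def quantile_normalize(matrix: CountMatrix) -> CountMatrix:
    """Quantile-normalize a gene x sample matrix across samples."""
    if len(matrix.names) < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returned unchanged")
        return matrix
    qn = QuantileNormalizer().fit(matrix.values.T)
    return CountMatrix(list(matrix.genes), list(matrix.names),
                       qn.transform(matrix.values.T).T, matrix.layer)


# ---------------------------------------------------------------------------
# Bin-background module score
# ---------------------------------------------------------------------------

def assign_bins(mean_expression: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bins (1..n_bins) by rank of average log expression;
    bin sizes differ by at most one."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    order = np.argsort(np.argsort(mean_expression, kind="stable"), kind="stable")
    # order = rank 0..G-1; np.array_split semantics on contiguous rank ranges
    g = len(mean_expression)
    edges = np.linspace(0, g, n_bins + 1).astype(int)
    bins = np.empty(g, dtype=int)
    for b in range(n_bins):
        bins[(order >= edges[b]) & (order < edges[b + 1])] = b + 1
    return bins


def _score_against_controls(X: pd.DataFrame, set_genes: list[str],
                            ctrl_genes: list[str]) -> pd.Series:
    """Per-sample mean of set genes minus mean of control genes (controls
    may repeat; multiplicity is respected)."""
    return X[set_genes].mean(axis=1) - X[ctrl_genes].mean(axis=1)


class ModuleScorer(BaseEstimator, TransformerMixin):
    """Bin-background activity scorer for one or more gene programs.

    Parameters
    ----------
    gene_sets : list of GeneSet
        Programs to score.
    n_bins : int
        Number of equal-frequency expression bins (default 25).
    n_ctrl : int
        Control genes drawn per set gene from its bin (default 100), with
        replacement when the bin is smaller. Set genes are excluded from the
        control pool whenever the bin holds other genes.
    random_state : int
        Seed for the control draws.
    """

    def __init__(self, gene_sets: list[GeneSet], n_bins: int = 25,
                 n_ctrl: int = 100, random_state: int = 0):
        self.gene_sets = gene_sets
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("ModuleScorer expects a samples x genes DataFrame")
        genes = np.asarray(X.columns)
        bins = assign_bins(X.to_numpy(dtype=float).mean(axis=0), self.n_bins)
        self.bins_ = pd.Series(bins, index=genes)
        rng = np.random.default_rng(self.random_state)
        self.controls_: dict[str, list[str]] = {}
        self.present_: dict[str, list[str]] = {}
        for gs in self.gene_sets:
            present = [g for g in gs.genes if g in self.bins_.index]
            if not present:
                raise ValidationError(f"no genes of set {gs.name!r} present in matrix")
            ctrl: list[str] = []
            in_set = set(gs.genes)
            for g in present:
                pool = genes[(bins == self.bins_[g])]
                non_set = [c for c in pool if c not in in_set]
                pool = non_set if non_set else list(pool)
                replace = len(pool) < self.n_ctrl
                ctrl.extend(rng.choice(pool, size=self.n_ctrl, replace=replace))
            self.controls_[gs.name] = ctrl
            self.present_[gs.name] = present
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "controls_")
        scores = {name: _score_against_controls(X, self.present_[name],
                                                self.controls_[name])
                  for name in self.controls_}
        return pd.DataFrame(scores, index=X.index)


def module_score(matrix: CountMatrix, gene_set: GeneSet | list[GeneSet],
                 n_bins: int = 25, n_ctrl: int = 100, seed: int = 0) -> pd.DataFrame:
    """Score gene programs in a log-scale gene x sample matrix.

    Returns a samples x sets table of background-subtracted scores.
    """
    sets = [gene_set] if isinstance(gene_set, GeneSet) else list(gene_set)
    X = pd.DataFrame(matrix.values.T, index=matrix.names, columns=matrix.genes)
    scorer = ModuleScorer(sets, n_bins=n_bins, n_ctrl=n_ctrl, random_state=seed)
    return scorer.fit(X).transform(X)
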