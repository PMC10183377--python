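import numpy as np
import pandas as pd
import pytest

from plaquestate.io import CellTable, CountMatrix, GeneSet, RegionSet, SumStats


@pytest.fixture
def small_cells() -> CellTable:
    rows = []
    for lib, cond in (("L1", "control"), ("L2", "late")):
        for i in range(10):
            rows.append((f"{lib}c{i}", lib, cond, 0.1 * i, 0.2 * i, "typeA"))
    return CellTable(pd.DataFrame(
        rows, columns=["cell_id", "library_id", "condition", "x", "y", "cell_type"]))


@pytest.fixture
def small_sumstats() -> SumStats:
    return SumStats(pd.DataFrame({
        "variant_id": ["v1", "v2", "v3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 5100, 100],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "beta": [0.1, -0.2, 0.05],
        "p": [1e-4, 0.02, 0.5],
        "info": [1.0, 0.95, 0.9],
        "eaf": [0.3, 0.4, 0.5],
    }))


def make_regions(name, triples):
    rows = [(c, s, e) for c, s, e in triples]
    return RegionSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture
def lognorm_matrix():
    """Deterministic lognorm matrix: 6 state cells clearly above 6 reference
    cells for the first 2 genes."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    cells = [f"s{i}" for i in range(6)] + [f"r{i}" for i in range(6)]
    vals = rng.uniform(0.5, 1.5, size=(5, 12))
    vals[0, :6] += 2.0
    vals[1, :6] += 2.0
    return CountMatrix(genes, cells, vals, layer="lognorm")
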