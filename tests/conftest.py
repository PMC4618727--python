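import numpy as np
import pandas as pd
import pytest

from permseq import GenomeGrid
from permseq.covariates import AggregatedPriorTable

from helpers import build_aln


@pytest.fixture
def fixed_point_instance():
    """Two positions with uni-read counts (3, 1) and one shared multi-read:
    the uniform-prior fixed point is z = (0.75, 0.25) in closed form."""
    aln = build_aln([[0], [0], [0], [1], [0, 1]])
    grid = GenomeGrid(("chr1",), (2,))
    return aln, grid


@pytest.fixture
def small_grid():
    return GenomeGrid(("chr1", "chr2"), (1000, 500))


def make_lasso_table(seed: int) -> AggregatedPriorTable:
    """Aggregated table with two histones: histone 0 is independent noise,
    histone 1 doubles the mean count in its enriched (code 2) rows."""
    rng = np.random.default_rng(seed)
    rows = []
    for x in range(3, 60, 4):
        for h1 in range(3):
            for h2 in range(3):
                mult = 2.0 if h2 == 2 else 1.0
                s = np.exp(0.5 + 0.03 * x + rng.normal(0, 0.05)) * mult
                size = {0: 200, 1: 30, 2: 10}[h1] * {0: 200, 1: 30, 2: 10}[h2]
                rows.append((str(x), f"{h1}|{h2}", s, size, float(x)))
    df = pd.DataFrame(rows, columns=["x_key", "histone_pattern", "S_bar",
                                     "size", "x_rep"])
    return AggregatedPriorTable(df, M=int(df["size"].sum()), n_histones=2)


def make_recovery_table(seed: int) -> AggregatedPriorTable:
    """Rows following S_bar = exp(0.5 + 0.02 x) on x = 3..200 with Gaussian
    noise (sd 0.01) on the log scale."""
    rng = np.random.default_rng(seed)
    x = np.arange(3, 201)
    sbar = np.exp(0.5 + 0.02 * x + rng.normal(0, 0.01, len(x)))
    df = pd.DataFrame({"x_key": x.astype(str), "histone_pattern": "",
                       "S_bar": sbar, "size": 100, "x_rep": x.astype(float)})
    return AggregatedPriorTable(df, M=int(df["size"].sum()))
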