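"""Shared fixtures: a session-wide synthetic genome and small helpers.

Building the genome model (bin grid + GC landscape) once per session keeps
the cohort-level tests fast; it is read-only for all consumers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from niptcall import BinTable, GenomeModel, SimulationConfig


@pytest.fixture(scope="session")
def default_genome() -> GenomeModel:
    """Genome model with default geometry, shared by all simulation tests."""
    return GenomeModel(SimulationConfig())


@pytest.fixture()
def toy_bins() -> BinTable:
    """A tiny two-chromosome bin table with hand-set counts and GC."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chrY"] * 3,
            "start": [1, 101, 201, 301, 1, 101, 201],
            "end": [100, 200, 300, 400, 100, 200, 300],
            "gc": [0.4, 0.5, 0.45, 0.35, 0.4, 0.5, 0.45],
            "raw_count": [10, 20, 30, 40, 1, 2, 3],
            "corrected_count": [0.0] * 7,
        }
    )
    return BinTable(df)


def random_bin_table(rng: np.random.Generator, n_y_bins: int = 20) -> BinTable:
    """A random chrY-plus-one-autosome table for property checks."""
    width = 100
    n_auto = 30
    counts_auto = rng.integers(0, 500, n_auto)
    counts_y = rng.integers(0, 50, n_y_bins)
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_auto + ["chrY"] * n_y_bins,
            "start": list(range(1, n_auto * width, width))
            + list(range(1, n_y_bins * width, width)),
            "end": list(range(width, n_auto * width + 1, width))
            + list(range(width, n_y_bins * width + 1, width)),
            "gc": rng.uniform(0.3, 0.6, n_auto + n_y_bins),
            "raw_count": np.concatenate([counts_auto, counts_y]),
            "corrected_count": 0.0,
        }
    )
    return BinTable(df)
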