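"""Shared fixtures: a small two-chromosome synthetic dataset for module
tests and one full-scale four-stage run for the acceptance suite."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from polytopo.genome_io import BinnedMatrix, GenomeModel
from polytopo.synthetic import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_hic,
)

SMALL_CHROMS = (("A01", 8_000_000, "At"), ("D01", 5_000_000, "Dt"))


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=7, chromosomes=SMALL_CHROMS)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cfg, small_data):
    genome, truth = small_data
    return simulate_hic(genome, truth, "0DPA", small_cfg)


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_data):
    genome, truth = small_data
    return simulate_expression(genome, truth, small_cfg)


@pytest.fixture(scope="session")
def full_summary():
    """One full-scale (2 x 20 Mb At + 2 x 12 Mb Dt) four-stage pipeline run."""
    from polytopo.pipeline import PipelineConfig, run_all

    return run_all(PipelineConfig(seed=1))


def toy_matrix(dense: np.ndarray, resolution: int = 10_000, chrom: str = "chr1"):
    """Wrap a symmetric dense array as a single-chromosome BinnedMatrix."""
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    bins = pd.DataFrame({"chrom": chrom, "start": np.arange(n) * resolution})
    upper = np.triu(dense)
    return BinnedMatrix(resolution, bins, sp.coo_matrix(upper))


@pytest.fixture
def toy_matrix_factory():
    return toy_matrix
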