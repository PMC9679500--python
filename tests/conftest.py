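import numpy as np
import pandas as pd
import pytest

from specstarch.spectra_io import ReferenceTable, SpectraSet
from specstarch.synthetic import SimulationConfig, simulate_reference, simulate_spectra


def make_spectra(matrix, wavelengths=None, sample_ids=None, **meta_cols) -> SpectraSet:
    """Build a SpectraSet from a raw matrix for tests."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if wavelengths is None:
        wavelengths = np.arange(740, 740 + p)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame({"sample_id": sample_ids, **meta_cols})
    return SpectraSet(np.asarray(wavelengths), matrix, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(n_trials=1, genotypes_per_trial=30, n_reps=2, seed=9)


@pytest.fixture
def small_dataset(small_config):
    reference = simulate_reference(small_config)
    spectra = simulate_spectra(reference, small_config)
    return reference, spectra


@pytest.fixture
def multi_trial_reference():
    config = SimulationConfig(
        n_trials=4,
        genotypes_per_trial=30,
        shared_genotype_fraction=0.3,
        design=["RCBD", "ALPHA_LATTICE", "RCBD", "ALPHA_LATTICE"],
        n_reps=2,
        seed=11,
    )
    return simulate_reference(config)


@pytest.fixture
def tiny_reference():
    rows = []
    for g in range(6):
        for rep in (1, 2):
            rows.append(
                {
                    "sample_id": f"T:G{g}:r{rep}",
                    "trial_id": "T",
                    "genotype_id": f"G{g}",
                    "rep": rep,
                    "block": f"B{rep}",
                    "design": "RCBD",
                    "starch": 20.0 + g + 0.1 * rep,
                }
            )
    return ReferenceTable(pd.DataFrame(rows))
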