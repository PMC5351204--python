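import numpy as np
import pandas as pd
import pytest

from methylshift.preprocess import CountMatrix, MethylationMatrix, make_site_table
from methylshift.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def null_dataset():
    """Null case-control dataset: no planted effects, no confounders."""
    config = SimulationConfig(
        n_cases=29, n_controls=34, n_cpg_sites=300, n_cph_sites=700,
        effect_fraction=0.0, n_confounders=0, seed=101,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def effect_dataset():
    """Dataset with case hypermethylation planted on 30% of CpH sites."""
    config = SimulationConfig(
        n_cases=29, n_controls=34, n_cpg_sites=200, n_cph_sites=1000,
        effect_fraction=0.3, effect_median_shift=1.8, seed=202,
    )
    return simulate_dataset(config)


@pytest.fixture
def toy_counts():
    """Tiny hand-checkable count matrix: 4 sites x 4 samples."""
    sites = make_site_table(
        ["chr1", "chr1", "chr1", "chr2"], [100, 200, 700, 150], "+", "CpG"
    )
    coverage = np.array(
        [[20, 30, 40, 50],
         [10, 10, 10, 10],
         [9, 50, 50, 50],
         [100, 100, 100, 100]]
    )
    methylated = np.array(
        [[5, 15, 10, 25],
         [0, 10, 5, 2],
         [9, 25, 0, 50],
         [50, 50, 50, 50]]
    )
    return CountMatrix(sites, ["A", "B", "C", "D"], coverage, methylated)


@pytest.fixture
def toy_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["A", "B", "C", "D"],
            "diagnosis": ["case", "case", "control", "control"],
            "age": [30.0, 40.0, 35.0, 50.0],
            "sex": ["M", "F", "M", "F"],
            "bank": ["bankA", "bankA", "bankB", "bankB"],
        }
    )


def meth_from_values(values, samples=None, coverage=30, positions=None):
    """Helper: MethylationMatrix from an explicit percent matrix."""
    values = np.asarray(values, dtype=float)
    s, n = values.shape
    if samples is None:
        samples = [f"S{j}" for j in range(n)]
    if positions is None:
        positions = 100 * (np.arange(s) + 1)
    sites = make_site_table(["chr1"] * s, positions, "+", "CpG")
    cov = np.full((s, n), coverage, dtype=np.int64)
    return MethylationMatrix(sites, list(samples), values, cov, np.ones((s, n), bool))
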