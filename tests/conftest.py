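import numpy as np
import pandas as pd
import pytest

from ovisclock import MethylomeDataset, SimConfig, simulate_dataset
from ovisclock.data import validate_sample_sheet


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort shared by read-only tests."""
    return simulate_dataset(SimConfig(
        n_samples=80, n_probes=300, n_clock_probes=30, n_asdmp_probes=20,
        seed=11))


def make_dataset(beta_values, ages, sex=None, castrated=None, tissue="ear",
                 species="sheep", mass=None, probe_ids=None):
    """Hand-built MethylomeDataset for arithmetic-oracle tests."""
    beta_values = np.asarray(beta_values, dtype=float)
    n_probes, n_samples = beta_values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    ids = [f"s{i}" for i in range(n_samples)]
    sheet = validate_sample_sheet(pd.DataFrame({
        "sample_id": ids,
        "age": ages,
        "sex": sex if sex is not None else ["female"] * n_samples,
        "castrated": castrated if castrated is not None else [False] * n_samples,
        "tissue": tissue,
        "species": species,
        "mass": mass if mass is not None else np.nan,
    }))
    beta = pd.DataFrame(beta_values, index=probe_ids, columns=ids)
    return MethylomeDataset(beta, sheet)
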