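import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from washhook.synthetic_chip import ChipConfig, ChipSeries, generate_chip_series

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chip_powerlaw():
    """Noise-free per-mode power-law washing series (desk scale)."""
    cfg = ChipConfig(n_sets=3000, noise_cv=0.0, washing="powerlaw", seed=7)
    return cfg, generate_chip_series(cfg)


@pytest.fixture(scope="session")
def chip_sigmoid():
    """Noise-free sigmoid-kernel washing series (desk scale)."""
    cfg = ChipConfig(n_sets=3000, noise_cv=0.0, washing="sigmoid", seed=5)
    return cfg, generate_chip_series(cfg)


@pytest.fixture(scope="session")
def chip_sigmoid_noisy():
    cfg = ChipConfig(n_sets=3000, noise_cv=0.15, washing="sigmoid", seed=5)
    return cfg, generate_chip_series(cfg)


def make_series(pm, mm, timepoints=(0,), M=1e4, set_ids=None, sequences=None):
    """Tiny hand-built chip series for unit tests.

    ``pm``/``mm`` are (n_pairs, n_timepoints) arrays (or 1-d for a single
    timepoint) of net intensities.
    """
    pm = np.atleast_2d(np.asarray(pm, dtype=float))
    mm = np.atleast_2d(np.asarray(mm, dtype=float))
    if pm.shape[1] != len(timepoints):
        pm, mm = pm.T, mm.T
    n = pm.shape[0]
    if set_ids is None:
        set_ids = ["set1"] * n
    if sequences is None:
        sequences = ["ACGT" * 6 + "A"] * n
    rows = {
        "set_id": np.repeat(set_ids, 2),
        "pair_index": np.repeat(np.arange(1, n + 1), 2),
        "probe_type": np.tile(["PM", "MM"], n),
        "sequence": np.repeat(sequences, 2),
    }
    probes = pd.DataFrame(rows)
    for j, t in enumerate(timepoints):
        col = np.column_stack([pm[:, j], mm[:, j]]).ravel()
        probes[ChipSeries.intensity_column(t)] = col
    O = {t: 0.0 for t in timepoints}
    return ChipSeries(probes=probes, timepoints=tuple(timepoints), O=O, M=M)
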