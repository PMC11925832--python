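import numpy as np
import pandas as pd
import pytest

from sepclust.synth import CohortConfig, generate_cohort


def make_blobs(n=300, k=3, p=5, sep=5.0, n_outliers=0, seed=0):
    """Well-separated Gaussian blobs plus optional gross outliers.

    Returns (X, labels, outlier_index_array); outliers are appended rows.
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, sep, (k, p))
    y = rng.integers(0, k, n)
    X = rng.normal(0, 1, (n, p)) + mu[y]
    out_idx = np.arange(n, n + n_outliers)
    if n_outliers:
        Xo = rng.normal(0, 1, (n_outliers, p)) + rng.choice([-1, 1], (n_outliers, p)) * 40.0
        X = np.vstack([X, Xo])
        y = np.concatenate([y, np.full(n_outliers, -1)])
    return X, y, out_idx


@pytest.fixture(scope="session")
def blob_fixture():
    X, y, _ = make_blobs(n=300, k=3, p=5, sep=5.0, seed=1)
    return X, y


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=300, k_true=3, separation=5.0, contamination=0.0,
                       mix=(0.215, 0.3925, 0.3925), septic_clusters=(1,),
                       p_sev=1.0, p_mild=0.0, seed=11)
    return generate_cohort(cfg)


def toy_events(rows):
    """rows: tuples (day, event_type, name, value) for patient 'T1'."""
    return pd.DataFrame(
        [("T1", d, t, n, v) for d, t, n, v in rows],
        columns=["patient_id", "day", "event_type", "name", "value"])


def toy_encounter(**kwargs):
    enc = {"patient_id": "T1", "discharged_alive_day": None}
    enc.update(kwargs)
    return enc
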