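import numpy as np
import pandas as pd
import pytest

import mltc_clusters as m


@pytest.fixture
def toy_map() -> m.ClusterMap:
    """Three clusters mirroring the worked example: metabolic,
    respiratory-and-vascular, alcohol-and-liver; seven diseases."""
    rows = []
    clusters = [
        ("metabolic", 4),
        ("respiratory_vascular", 2),
        ("alcohol_liver", 1),
    ]
    i = 0
    for cid, size in clusters:
        for _ in range(size):
            i += 1
            rows.append((f"d{i}", f"Disease {i}", cid, cid.replace("_", " ")))
    return m.ClusterMap(
        pd.DataFrame(rows, columns=["disease_id", "disease_name", "cluster_id", "cluster_name"])
    )


@pytest.fixture
def fig1_counts(toy_map) -> pd.Series:
    """The worked-example patient: 4 metabolic, 2 respiratory-and-vascular,
    1 alcohol-and-liver disease."""
    return m.cluster_counts([f"d{i}" for i in range(1, 8)], toy_map)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated cohort shared across tests (n=2000)."""
    cfg = m.SimConfig(n_patients=2000, seed=7)
    catalog, cohort = m.simulate(cfg)
    return cfg, catalog, cohort


@pytest.fixture(scope="session")
def small_counts(small_sim) -> pd.DataFrame:
    _, catalog, cohort = small_sim
    return m.cohort_cluster_counts(cohort, catalog.map)


def random_counts(rng: np.random.Generator, n: int, k: int) -> pd.DataFrame:
    """Random per-patient cluster-count table with row sums >= 2."""
    raw = rng.poisson(0.8, size=(n, k))
    deficit = np.maximum(2 - raw.sum(axis=1), 0)
    raw[np.arange(n), rng.integers(0, k, n)] += deficit
    return pd.DataFrame(
        raw,
        index=pd.Index([f"p{i:04d}" for i in range(n)], name="patient_id"),
        columns=[f"c{j}" for j in range(k)],
    )
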