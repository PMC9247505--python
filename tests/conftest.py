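import numpy as np
import pandas as pd
import pytest

from lmewscore import CohortTable, default_discovery_config, generate_cohort


def make_toy_cohort(
    n_per_center,
    n_rois=2,
    seed=0,
    d=0.01,
    sigma=0.1,
    beta=None,
    center_offsets=None,
    diagnosis="CN",
):
    """Small hand-rolled cohort with known linear structure (no generator
    dependence) for oracle-level tests.  Returns (CohortTable, X, truth)."""
    rng = np.random.default_rng(seed)
    rois = [f"roi{k}" for k in range(n_rois)]
    frames = []
    truth_offsets = {}
    for j, n in enumerate(n_per_center):
        cid = f"C{j}"
        age = rng.uniform(55, 85, n)
        sex = rng.integers(0, 2, n).astype(float)
        edu = rng.uniform(8, 20, n)
        icv = rng.uniform(1.1e6, 1.7e6, n)
        X = np.column_stack([age, sex, edu, icv])
        if beta is None:
            b = np.array([-0.01, -0.05, 0.005, 1e-8])
        else:
            b = np.asarray(beta)
        off = (
            center_offsets[j]
            if center_offsets is not None
            else rng.normal(0, np.sqrt(d))
        )
        truth_offsets[cid] = off
        thick = (
            2.5
            + (X @ b)[:, None]
            + off
            + rng.normal(0, sigma, (n, n_rois))
        )
        df = pd.DataFrame(thick, columns=rois)
        df.insert(0, "icv", icv)
        df.insert(0, "education", edu)
        df.insert(0, "sex", sex)
        df.insert(0, "age", age)
        df.insert(0, "diagnosis", diagnosis)
        df.insert(0, "center_id", cid)
        df.insert(0, "subject_id", [f"{cid}_s{i}" for i in range(n)])
        frames.append(df)
    table = CohortTable(pd.concat(frames, ignore_index=True), tuple(rois))
    return table, truth_offsets


@pytest.fixture(scope="session")
def small_discovery():
    """Reduced-scale 10-center discovery cohort shared by slower tests."""
    cfg = default_discovery_config(scale=0.15, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_cohort():
    table, offsets = make_toy_cohort([20, 15, 25], n_rois=2, seed=42)
    return table
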