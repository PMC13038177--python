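import numpy as np
import pandas as pd
import pytest

import traitspace as ts


@pytest.fixture(scope="session")
def small_study2():
    """A small within-subjects study shared across tests (30 perceivers)."""
    cfg = ts.SimulationConfig.study2(seed=7, n_perceivers=30, slope_gamma=0.05)
    return ts.simulate_study2(cfg)


@pytest.fixture(scope="session")
def small_study2_dataset(small_study2):
    return ts.build_mlm_dataset(
        small_study2.face_ratings, small_study2.pairwise_ratings
    )


@pytest.fixture(scope="session")
def small_study1():
    """A small between-subjects study with 8 traits (fast spaces)."""
    cfg = ts.SimulationConfig.study1(
        seed=3,
        traits=ts.STUDY1_TRAITS[:8],
        n_perceivers=80,
        n_targets_per_group=40,
        targets_per_perceiver=15,
        kappa=0.8,
    )
    return ts.simulate_study1(cfg)


@pytest.fixture(scope="session")
def study1_spaces(small_study1):
    fs = ts.face_space(small_study1.face_ratings)
    ss = ts.stereotype_space(small_study1.abstract_ratings)
    return fs, ss


@pytest.fixture()
def face_csv(tmp_path):
    """Hand-written 6-row face-rating fixture: 2 perceivers x 3 traits."""
    df = pd.DataFrame(
        {
            "perceiver_id": ["a", "a", "a", "b", "b", "b"],
            "subject": ["t1", "t1", "t1", "t1", "t1", "t1"],
            "race": ["White"] * 6,
            "gender": ["male"] * 6,
            "trait": ["warm", "competent", "dominant"] * 2,
            "rating": [3, 5, 2, 4, 6, 1],
        }
    )
    path = tmp_path / "faces.csv"
    df.to_csv(path, index=False)
    return path
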