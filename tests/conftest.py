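"""Shared fixtures: compact phantoms and end-to-end study runs.

The study fixtures use deliberately small problem sizes (16x16x10 ribbon,
18 subjects, 150 training voxels per subject, a 2x2 hyperparameter grid)
so the whole suite runs in minutes; the generative structure is unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest

from rsfcbf.model import ModelConfig
from rsfcbf.pipeline import StudyConfig, run_synthetic_study
from rsfcbf.synthetic import GenerativeParams, PhantomSpec, make_phantom

SMALL_PHANTOM = PhantomSpec(shape=(16, 16, 10), ribbon_thickness_voxels=1.5,
                            n_parcels=6)
SMALL_MODEL = ModelConfig(C_grid=(1.0, 10.0), gamma_grid=(1.0 / 57.0, 0.1),
                          cv_folds=3, voxels_per_subject=150)
SMALL_PARAMS = GenerativeParams(n_timepoints=160)


def small_study_config(seed: int, modes=("original", "pva_corrected"),
                       **overrides) -> StudyConfig:
    kw = dict(n_case=0, n_control=18, phantom=SMALL_PHANTOM,
              params=SMALL_PARAMS, model=SMALL_MODEL, modes=modes, seed=seed)
    kw.update(overrides)
    return StudyConfig(**kw)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(SMALL_PHANTOM)


@pytest.fixture(scope="session")
def study_replicates():
    """Ten seeded end-to-end runs comparing original vs PVA-corrected modes."""
    results = []
    for seed in range(10):
        res = run_synthetic_study(small_study_config(seed))
        results.append(res)
    return results


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
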