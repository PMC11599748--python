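"""Shared fixtures: one small synthetic landscape reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from marshstock import (
    GenerativeOCDParams,
    GridSpec,
    ModelSpec,
    SamplingDesign,
    extract_covariates,
    fit,
    generate_covariate_grid,
    sample_cores,
)

TRUTH_EFFECTS = {"elevation": -0.008, "ndvi": 0.005, "tidal": 0.003}


@pytest.fixture(scope="session")
def grid():
    spec = GridSpec(0.0, 1.0, 50.0, 51.0, 0.02, seed=11)
    return generate_covariate_grid(
        spec,
        ["elevation", "ndvi", "tidal"],
        smoothness=0.12,
        categorical={"coastal_type": 3},
        mask_fraction=0.5,
    )


@pytest.fixture(scope="session")
def truth_params():
    return GenerativeOCDParams(
        intercept=0.03,
        covariate_effects=TRUTH_EFFECTS,
        depth_effect=-5e-5,
        noise_sd=0.004,
    )


@pytest.fixture(scope="session")
def cores(grid, truth_params):
    design = SamplingDesign(
        n_locations=150, n_clusters=3, cluster_fraction=0.85,
        cluster_sd=0.04, deep_retention=0.5, seed=11,
    )
    return sample_cores(grid, truth_params, design)


@pytest.fixture(scope="session")
def matrix(cores, grid):
    return extract_covariates(cores, grid)


@pytest.fixture(scope="session")
def fitted(matrix):
    return fit(matrix, ModelSpec(mtry=3, min_node=5, n_trees=100, seed=11))


def make_training_frame(values: np.ndarray, covariate: str = "x", depth: float = 10.0) -> pd.DataFrame:
    """Minimal training table around a single covariate column (for oracles)."""
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "location_id": [f"p{i}" for i in range(len(values))],
            "lon": 0.0,
            "lat": 0.0,
            "region": "r",
            "depth_cm": depth,
            covariate: values,
            "ocd_gcm3": 0.03,
        }
    )
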