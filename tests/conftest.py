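import numpy as np
import pandas as pd
import pytest

from adiffi import (
    CohortTable,
    RadiusModel,
    SpatialEffect,
    SyntheticCohortSpec,
)


def make_null_spec(
    seed: int,
    n_a: int = 5,
    n_b: int = 5,
    grid: int = 24,
    voxel_mm: float = 1.0,
    center_sd: float = 3.0,
    policy: str = "resample",
) -> SyntheticCohortSpec:
    """Small two-group null spec used across the suite."""
    return SyntheticCohortSpec(
        grid_shape=(grid,) * 3,
        voxel_size_mm=(voxel_mm,) * 3,
        groups=(("MES", n_a), ("RTK_I", n_b)),
        center_mean_mm=(0.0, 0.0, 0.0),
        center_cov_mm2=np.diag([center_sd**2] * 3).tolist(),
        radius_model=RadiusModel(2.0, 0.3, 3.5, 0.4, 5.0, 0.5),
        master_seed=seed,
        center_policy=policy,
    )


def make_effect_spec(seed: int, n_a: int = 60, n_b: int = 60) -> SyntheticCohortSpec:
    """Planted-boost spec: most of group A's lesions concentrate in a sphere."""
    return SyntheticCohortSpec(
        grid_shape=(32,) * 3,
        voxel_size_mm=(1.0,) * 3,
        groups=(("MES", n_a), ("RTK_I", n_b)),
        center_mean_mm=(0.0, 0.0, 0.0),
        center_cov_mm2=np.diag([36.0] * 3).tolist(),
        radius_model=RadiusModel(2.5, 0.4, 4.0, 0.5, 6.0, 0.7),
        effect=SpatialEffect(
            group="MES", boost_center_mm=(5.0, 3.0, 0.0), boost_radius_mm=3.0, boost_prob=0.9
        ),
        master_seed=seed,
        center_policy="resample",
    )


def make_table(subtypes, mgmt=None, sex=None) -> CohortTable:
    """Cohort table without real mask files (metadata-only tests)."""
    n = len(subtypes)
    return CohortTable(
        pd.DataFrame(
            {
                "id": [f"P{i:04d}" for i in range(n)],
                "subtype": list(subtypes),
                "mgmt": list(mgmt) if mgmt is not None else ["methylated"] * n,
                "sex": list(sex) if sex is not None else ["male"] * n,
                "mask_path": [f"P{i:04d}.nii" for i in range(n)],
            }
        )
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small generated null cohort shared by read-only tests."""
    from adiffi import generate_cohort

    return generate_cohort(make_null_spec(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
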