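import numpy as np
import pytest

import echolv as e


@pytest.fixture(scope="session")
def small_config() -> e.PhantomConfig:
    """Desk-scale phantom: 8 animals, 48 px, 16 frames."""
    return e.PhantomConfig(
        n_animals=8, image_size=48, pixel_spacing=0.16,
        frames_per_cycle=16, n_slices_stored=8, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return e.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return small_cohort[0][0]


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[0][1]


@pytest.fixture(scope="session")
def truth_mesh(small_dataset, small_truth):
    return e.build_lv_mesh(
        small_truth, small_dataset.apex_z, small_dataset.base_z,
        small_dataset.cycle_duration_s,
    )


def constant_mesh(radius_endo=2.0, radius_epi=3.0, length=6.0,
                  n_time=60, n_z=60, n_theta=60, cycle_duration_s=0.12):
    """Time-constant straight-walled (cylindrical) mesh built directly."""
    radii = np.empty((2, n_time, n_z, n_theta))
    radii[0] = radius_endo
    radii[1] = radius_epi
    return e.LVMesh(
        radii=radii,
        theta_deg=np.arange(n_theta) * 360.0 / n_theta,
        z_fracs=np.arange(1, n_z + 1) / n_z,
        phases=np.arange(n_time) / n_time,
        apex_z=np.zeros(n_time),
        base_z=np.full(n_time, length),
        cycle_duration_s=cycle_duration_s,
    )


@pytest.fixture
def cylinder_mesh():
    return constant_mesh()
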