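import numpy as np
import pytest

from hanet.synthetic import (
    Parcellation,
    SimulationSpec,
    hub_covariance,
    make_parcellation,
    simulate_subject,
)


@pytest.fixture(scope="session")
def small_parcellation() -> Parcellation:
    """6 connected regions on a small grid."""
    return make_parcellation((6, 6, 5), n_rois=6, seed=11)


@pytest.fixture(scope="session")
def small_spec(small_parcellation) -> SimulationSpec:
    cov = hub_covariance(6, base_r=0.3, hub_rois=(2,), hub_r=0.6)
    return SimulationSpec(
        n_subjects_per_group=2,
        groups=("patient", "control"),
        roi_covariance_per_group={"patient": cov, "control": cov},
        n_timepoints=40,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_volume(small_parcellation, small_spec) -> np.ndarray:
    return simulate_subject(small_parcellation, small_spec, "patient", 99)


@pytest.fixture(scope="session")
def noise_free_volume(small_parcellation) -> np.ndarray:
    """Every voxel in a region carries exactly the region's latent series."""
    cov = hub_covariance(6, base_r=0.2)
    spec = SimulationSpec(
        n_subjects_per_group=1,
        groups=("g",),
        roi_covariance_per_group={"g": cov},
        n_timepoints=40,
        voxel_noise_sd=0.0,
        within_roi_signal_fraction=1.0,
        seed=6,
    )
    return simulate_subject(small_parcellation, spec, "g", 123)


@pytest.fixture
def two_roi_parcellation() -> Parcellation:
    """Two regions of 3 voxels each on a 3x2x1 grid."""
    labels = np.array([[[1], [1]], [[1], [2]], [[2], [2]]], dtype=np.int16)
    return Parcellation(labels, roi_names=("A", "B"))
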