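import numpy as np
import pytest

import protoconn as pc


@pytest.fixture(scope="session")
def synth_atlas():
    return pc.make_synthetic_atlas()


@pytest.fixture(scope="session")
def final_atlas(synth_atlas):
    return pc.finalize_synthetic_atlas(synth_atlas)


@pytest.fixture(scope="session")
def small_model():
    return pc.default_ground_truth(n_timepoints=200)


@pytest.fixture(scope="session")
def small_cohort(small_model, synth_atlas):
    return pc.simulate_cohort(small_model, 3, synth_atlas, master_seed=11)


def two_system_model(coupling: float, n_timepoints: int, signal_gain=1.0,
                     physio_gain=0.0, noise_gain=0.0, **kwargs):
    """Minimal two-system ground truth for convergence checks."""
    c = np.array([[1.0, coupling], [coupling, 1.0]])
    return pc.GroundTruthModel(
        systems=("language", "VWFA"),
        coupling_by_group={"adult": c},
        signal_gain=signal_gain, physio_gain=physio_gain, noise_gain=noise_gain,
        n_timepoints=n_timepoints, **kwargs)


def two_block_atlas(grid=(8, 8, 8)):
    specs = [("langA", "language", (1, 1, 2), (2, 2, 2)),
             ("vwfaA", "VWFA", (4, 4, 2), (2, 2, 2))]
    return pc.make_synthetic_atlas(grid_shape=grid, parcel_specs=specs)
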