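import numpy as np
import pytest

import raftmap as rm


@pytest.fixture(scope="session")
def double_well_1d_traj():
    """Canonical 1D double-well record: 3 kBT barrier, minima 200 nm apart,
    D = 0.025 um^2/s, 2000 frames at 25 ms."""
    pot = rm.make_double_well(3.0, 0.1, dim=1)
    return rm.simulate(pot, 0.025, n_frames=2000, frame_dt=0.025,
                       substeps=20, seed=1, r0=-0.1)


@pytest.fixture(scope="session")
def harmonic_2d_traj():
    """Stationary 2D harmonic confinement, k = 200 kBT/um^2, D = 0.05."""
    pot = rm.HarmonicWell(k=200.0, ndim=2)
    return rm.simulate(pot, 0.05, n_frames=4000, frame_dt=0.025,
                       substeps=10, seed=2)


@pytest.fixture(scope="session")
def flat_1d_traj():
    """Free diffusion in 1D, D = 0.025, 5000 frames, no noise."""
    pot = rm.HarmonicWell(k=0.0, ndim=1)
    return rm.simulate(pot, 0.025, n_frames=5000, frame_dt=0.025,
                       substeps=10, seed=5)


def make_synthetic_result(potential_model, positions, cell_size=0.02):
    """Wrap an analytic PotentialModel in an InferenceResult so the
    extraction operations can be exercised against closed forms."""
    import math

    from raftmap.inference import DiffusivityField, InferenceResult, Mesh

    positions = np.asarray(positions, float)
    lo = positions.min(axis=0) - cell_size
    hi = positions.max(axis=0) + cell_size
    shape = tuple(int(math.ceil((hi[ax] - lo[ax]) / cell_size)) or 1
                  for ax in range(positions.shape[1]))
    mesh = Mesh(origin=lo, cell_size=cell_size, shape=shape,
                ndim=positions.shape[1])
    ci = mesh.cell_of(positions[:-1])
    cells, counts = np.unique(ci, return_counts=True)
    dfield = DiffusivityField(cells=cells,
                              values=np.full(cells.size, 0.025),
                              estimated=np.ones(cells.size, bool),
                              counts=counts)
    return InferenceResult(potential=potential_model, dfield=dfield,
                           sigma=0.0, mesh=mesh, log_posterior=0.0,
                           diagnostics={"converged": True},
                           positions=positions)
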