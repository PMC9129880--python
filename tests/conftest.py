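import numpy as np
import pytest

from crestchain.model import Arena, Identity, ModelParams, Trajectory


def make_trajectory(y, identities, x=None, radii=None, frame_interval=5.0):
    """Build a Trajectory from per-cell y positions.

    ``y`` is (n_frames, n_cells); ``x`` defaults to zero (collinear chain),
    ``identities`` is a string like "LF".
    """
    y = np.asarray(y, dtype=float)
    n_frames, n_cells = y.shape
    pos = np.zeros((n_frames, n_cells, 2))
    pos[:, :, 1] = y
    if x is not None:
        pos[:, :, 0] = np.asarray(x, dtype=float)
    idents = tuple(Identity.from_char(c) for c in identities)
    if radii is None:
        params = ModelParams()
        radii = np.array([params.cell_radius[i] for i in idents])
    return Trajectory(
        positions=pos,
        identities=idents,
        times=np.arange(n_frames) * frame_interval,
        radii=np.asarray(radii, dtype=float),
    )


@pytest.fixture
def default_arena():
    return Arena()


@pytest.fixture
def quick_params():
    """Short simulation for smoke tests."""
    return ModelParams(n_steps=100, sample_every=5)
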