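import numpy as np
import pytest

from kinoflex.synthetic import PanelSpec, TrajectorySpec, gen_fluctuation_panel, gen_trajectory


@pytest.fixture
def panel():
    """A default-regime panel (43 kinases, planted signal at column 150)."""
    return gen_fluctuation_panel(PanelSpec(seed=7))[0]


@pytest.fixture
def small_panel():
    """A small, fast panel with the signal at column 3 and no correlated block."""
    spec = PanelSpec(
        n_active=8,
        n_inactive=10,
        n_columns=8,
        signal_column=3,
        corr_block=(),
        seed=11,
    )
    return gen_fluctuation_panel(spec)[0]


@pytest.fixture
def gaussian_trajectory():
    """A 2-residue isotropic Gaussian trajectory for geometry tests."""
    spec = TrajectorySpec(
        n_frames=25,
        residues=[(1, 0.3, [0.0, 0.0, 0.0]), (2, 0.3, [3.8, 0.0, 0.0])],
        seed=5,
    )
    return gen_trajectory(spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR-based)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
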