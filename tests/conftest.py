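import numpy as np
import pytest

import cbctmotion as cm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    """8^3 grid, 32 mm voxels (256 mm cube)."""
    return cm.VolumeGrid.isotropic(8, 32.0)


@pytest.fixture(scope="session")
def small_geom():
    """16^2 detector, 20 frames over the half arc."""
    return cm.default_protocol(detector_rows=16, detector_cols=16, n_frames=20)


@pytest.fixture(scope="session")
def medium_grid():
    return cm.VolumeGrid.isotropic(16, 16.0)


def dense_sirt_reference(A, y_stack, n_iter, nonneg=True, floor_rel=1e-6):
    """Literal dense-matrix transcription of the SIRT update rule."""
    T, npx, nv = A.shape

    def floored_inv(arr):
        pos = arr[arr > 0]
        floor = floor_rel * np.median(pos) if pos.size else 1.0
        return 1.0 / np.maximum(arr, floor)

    R = np.stack([floored_inv(A[t] @ np.ones(nv)) for t in range(T)])
    C = floored_inv(sum(A[t].T @ np.ones(npx) for t in range(T)))
    x = np.zeros(nv)
    for _ in range(n_iter):
        update = np.zeros(nv)
        for t in range(T):
            update += A[t].T @ (R[t] * (y_stack[t].ravel() - A[t] @ x))
        x = x + C * update
        if nonneg:
            x = np.maximum(x, 0.0)
    return x


@pytest.fixture(scope="session")
def dense_system(small_grid, small_geom):
    """The per-frame system matrices materialized as dense arrays.

    On an 8^3 grid / 16^2 detector the operator is small enough to store
    explicitly, giving an independent oracle for adjointness and SIRT.
    """
    nv = int(np.prod(small_grid.shape))
    npx = small_geom.detector_rows * small_geom.detector_cols
    A = np.zeros((small_geom.n_frames, npx, nv))
    for j in range(nv):
        e = np.zeros(nv)
        e[j] = 1.0
        vol = cm.Volume(small_grid, e.reshape(small_grid.shape))
        for t in range(small_geom.n_frames):
            A[t, :, j] = cm.forward_project(vol, small_geom, t, check_finite=False).ravel()
    return A
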