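from __future__ import annotations

import numpy as np
import pytest

from fibrefab.fabric import sample_directions
from fibrefab.orientation_field import (
    OrientationField,
    OrientationSample,
    WindowSpec,
)


@pytest.fixture(scope="session")
def directions128():
    return sample_directions(128)


@pytest.fixture(scope="session")
def directions64():
    return sample_directions(64)


@pytest.fixture(scope="session")
def directions32():
    return sample_directions(32)


def _orthonormal_complement(v):
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    a = np.eye(3)[int(np.argmin(np.abs(v)))]
    e2 = np.cross(v, a)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(v, e2)
    return e2, e3


def make_field(e1s, magnitudes=None, anisotropies=None, spacing_um=1.0):
    """Build a minimal synthetic OrientationField for statistics tests."""
    e1s = [np.asarray(v, dtype=float) for v in e1s]
    n = len(e1s)
    magnitudes = [10.0] * n if magnitudes is None else list(magnitudes)
    anisotropies = [0.5] * n if anisotropies is None else list(anisotropies)
    samples = []
    for i, (v, mag, ani) in enumerate(zip(e1s, magnitudes, anisotropies)):
        v = v / np.linalg.norm(v)
        e2, e3 = _orthonormal_complement(v)
        lam1 = mag
        lam3 = (1.0 - ani) * lam1
        samples.append(OrientationSample(
            center_um=(float(i), 0.0, 0.0),
            e1=tuple(v), e2=tuple(e2), e3=tuple(e3),
            eigenvalues_um=(lam1, (lam1 + lam3) / 2, lam3),
            magnitude_um=float(mag), anisotropy=float(ani),
            material_fraction=0.5, grid_index=(i, 0, 0), start_vox=(i, 0, 0),
        ))
    return OrientationField(
        samples=samples, window=WindowSpec(8, 8, 0.0), source_shape=(8, 8, 8),
        spacing_um=spacing_um, axis_map=("X", "Y", "Z"),
        skipped={"low_material": 0, "degenerate_fit": 0}, n_windows=n,
    )
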