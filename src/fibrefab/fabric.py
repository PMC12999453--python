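"""Mean-intercept-length (MIL) stereology and fabric-tensor analysis.

The MIL of a binary microstructure along a test direction is the average
length of uninterrupted material runs ("intercepts") encountered by a family
of parallel lines traced through the volume.  Structures elongated along a
direction produce long intercepts along it and short ones across it.  The
directional MIL profile is summarised by a second-order fabric tensor: the
ellipsoid form ``1/MIL(n)^2 = n^T M n`` is fitted by least squares over the
sampled directions, and the eigenvectors of ``M`` give the principal
material directions.  Eigenvalues are reported on the length scale
(``lambda_i = 1/sqrt(m_i)``, in micrometres, sorted descending) so that the
primary eigenvalue is the longest characteristic intercept length.

The degree of anisotropy is mapped onto a 0–1 index,
``1 - lambda_3/lambda_1``: 0 for an isotropic structure (equal eigenvalues)
and approaching 1 for extreme uniaxial alignment.

Line-sampling geometry (shared contract, mirrored by test oracles)
------------------------------------------------------------------
For a mask of shape ``(s0, s1, s2)`` and a unit direction ``d``:

* centre ``c = (shape - 1) / 2`` (voxel-centre coordinates, voxel units);
* ``half_diag = ||shape|| / 2``;
* an orthonormal in-plane basis ``u = cross(d, a) / ||.||``,
  ``v = cross(d, u)`` where ``a`` is the coordinate axis with the smallest
  ``|d|`` component (first such axis on ties);
* line origins ``(c + oi * u) + oj * v`` for
  ``oi, oj in arange(-n_off, n_off + 1) * line_spacing_vox`` with
  ``n_off = ceil(half_diag / line_spacing_vox)``;
* sample points ``origin + t * d`` for
  ``t in arange(-m, m + 1) * 0.5`` with ``m = ceil(half_diag / 0.5)``
  (half-voxel steps);
* each sample is mapped to the nearest voxel (``np.rint``); samples outside
  the array are void.

An intercept is a maximal run of material samples along one line; runs
truncated by the volume boundary count as one intercept.  Each material
sample contributes half a voxel of material length.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DirectionSet",
    "MILProfile",
    "FabricTensor",
    "FabricFitError",
    "DegenerateFabricError",
    "sample_directions",
    "canonicalize_axial",
    "compute_mil",
    "fit_fabric_tensor",
    "anisotropy_index",
]

STEP_VOX = 0.5
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

# Line plans are cached per (shape, spacing, direction set) so that sliding
# windows of identical shape reuse the sampled geometry.  Large volumes are
# streamed per direction instead of cached.
_PLAN_CACHE: dict = {}
_PLAN_CACHE_MAX_VOXELS = 140_608  # 52^3
_PLAN_CACHE_MAX_ENTRIES = 4


class FabricFitError(ValueError):
    """Raised when a fabric tensor cannot be fitted to a MIL profile."""


class DegenerateFabricError(FabricFitError):
    """Fitted ellipsoid form is not positive definite (carries the tensor)."""

    def __init__(self, message: str, tensor: np.ndarray):
        super().__init__(message)
        self.tensor = np.asarray(tensor)


@dataclass(frozen=True)
class DirectionSet:
    """A set of axial unit directions on the upper hemisphere.

    Directions are axial (a fiber along ``v`` equals one along ``-v``), so
    every vector is kept on the hemisphere with positive Z component; on the
    equator ties resolve toward +Y, then +X.
    """

    directions: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if d.shape[0] < 6:
            raise ValueError("a fabric fit needs at least 6 directions")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("directions must be unit vectors (tol 1e-12)")
        upper = (d[:, 2] > 0) | (
            (d[:, 2] == 0) & ((d[:, 1] > 0) | ((d[:, 1] == 0) & (d[:, 0] > 0)))
        )
        if not np.all(upper):
            raise ValueError("directions must lie on the upper hemisphere")
        gram = d @ d.T
        np.fill_diagonal(gram, 0.0)
        if np.any(np.abs(gram) > 1.0 - 1e-12):
            raise ValueError("directions must be pairwise distinct (axially)")
        d.setflags(write=False)
        object.__setattr__(self, "directions", d)

    @property
    def n(self) -> int:
        return self.directions.shape[0]

    @property
    def token(self) -> str:
        """Stable content hash, used to key line-plan caches."""
        return hashlib.sha1(self.directions.tobytes()).hexdigest()


@dataclass(frozen=True)
class MILProfile:
    """Per-direction mean intercept lengths from line sampling.

    ``mil_um`` is NaN where ``intercept_count`` is zero (no material run was
    met along any line of that family); everywhere else
    ``mil_um = total_material_length_um / intercept_count``.
    """

    mil_um: np.ndarray
    intercept_count: np.ndarray
    total_material_length_um: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.intercept_count, dtype=np.int64)
        total = np.asarray(self.total_material_length_um, dtype=np.float64)
        mil = np.asarray(self.mil_um, dtype=np.float64)
        if not (counts.shape == total.shape == mil.shape):
            raise ValueError("profile arrays must share one shape")
        if np.any(counts < 0) or np.any(total < 0):
            raise ValueError("counts and lengths must be non-negative")
        defined = counts > 0
        if np.any(~np.isnan(mil[~defined])):
            raise ValueError("mil_um must be NaN where intercept_count is 0")
        if np.any(np.abs(mil[defined] * counts[defined] - total[defined]) > 1e-6):
            raise ValueError("mil_um inconsistent with totals and counts")
        for name, arr in (("mil_um", mil), ("intercept_count", counts),
                          ("total_material_length_um", total)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def defined(self) -> np.ndarray:
        return self.intercept_count > 0


@dataclass(frozen=True)
class FabricTensor:
    """Symmetric MIL fabric tensor with its eigendecomposition.

    ``tensor`` is the fitted ellipsoid form ``M`` (units um^-2).
    ``eigenvalues_um`` are the length-scale eigenvalues ``1/sqrt(m_i)``,
    sorted descending; column ``i`` of ``eigenvectors`` is the matching
    sign-canonicalized unit eigenvector (see :func:`canonicalize_axial`).
    """

    tensor: np.ndarray
    eigenvalues_um: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.tensor, dtype=np.float64)
        lam = np.asarray(self.eigenvalues_um, dtype=np.float64)
        vec = np.asarray(self.eigenvectors, dtype=np.float64)
        if m.shape != (3, 3) or vec.shape != (3, 3) or lam.shape != (3,):
            raise ValueError("tensor/eigenvectors must be 3x3, eigenvalues length 3")
        if np.any(lam <= 0):
            raise ValueError("eigenvalues must be strictly positive")
        if np.any(np.diff(lam) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        if np.max(np.abs(vec.T @ vec - np.eye(3))) > 1e-9:
            raise ValueError("eigenvectors must be orthonormal (tol 1e-9)")
        recon = vec @ np.diag(1.0 / lam**2) @ vec.T
        scale = max(np.max(np.abs(m)), 1e-300)
        if np.max(np.abs(recon - m)) > 1e-9 * scale:
            raise ValueError("eigenpairs do not reconstruct the tensor")
        for name, arr in (("tensor", m), ("eigenvalues_um", lam),
                          ("eigenvectors", vec)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def primary_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def magnitude_um(self) -> float:
        """Alignment magnitude: the primary (largest) eigenvalue in um."""
        return float(self.eigenvalues_um[0])


def sample_directions(n: int, seed: int | None = None) -> DirectionSet:
    """Near-uniform axial direction set on the upper hemisphere.

    Uses the deterministic spherical Fibonacci lattice restricted to the
    upper hemisphere: ``z_i = (i + 1/2)/n`` with golden-angle azimuths.
    ``seed`` is accepted for signature stability with randomized variants
    but unused by the default scheme.

    Parameters
    ----------
    n:
        Number of directions, at least 6 (a fabric fit has 6 unknowns).
    """
    if n < 6:
        raise ValueError("n must be >= 6: the fabric fit has 6 free parameters")
    i = np.arange(n, dtype=np.float64)
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    phi = i * _GOLDEN_ANGLE
    d = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    d /= np.linalg.norm(d, axis=1)[:, None]
    return DirectionSet(d)


def canonicalize_axial(v: np.ndarray) -> np.ndarray:
    """Resolve the sign ambiguity of an axial vector.

    Returns ``v`` or ``-v`` such that the component of largest magnitude is
    positive; ties among equal-magnitude components are broken by the first
    axis in X, Y, Z order.  Components are interpreted in the anatomical
    (X, Y, Z) frame, but the rule is frame-agnostic.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (3,):
        raise ValueError("expected a 3-vector")
    a = np.abs(v)
    if not np.any(a > 0):
        raise ValueError("cannot canonicalize the zero vector")
    idx = int(np.argmax(a))  # argmax takes the first maximum: X before Y before Z
    return v.copy() if v[idx] > 0 else -v


# ---------------------------------------------------------------------------
# Line sampling


def _direction_basis(d: np.ndarray):
    axes = np.eye(3)
    a = axes[int(np.argmin(np.abs(d)))]
    u = np.cross(d, a)
    u = u / np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _line_samples(shape, d: np.ndarray, line_spacing_vox: float):
    """All line-sample voxel indices for one direction.

    Returns ``(flat_idx, valid)`` of shape (n_lines, n_steps): nearest-voxel
    flat indices (0 where the sample falls outside the array) and validity.
    Implements exactly the geometry documented in the module docstring.
    """
    shape = np.asarray(shape, dtype=np.int64)
    c = (shape.astype(np.float64) - 1.0) / 2.0
    half_diag = 0.5 * float(np.linalg.norm(shape.astype(np.float64)))
    u, v = _direction_basis(d)
    n_off = int(math.ceil(half_diag / line_spacing_vox))
    offs = np.arange(-n_off, n_off + 1, dtype=np.float64) * float(line_spacing_vox)
    m = int(math.ceil(half_diag / STEP_VOX))
    t = np.arange(-m, m + 1, dtype=np.float64) * STEP_VOX

    a_grid = c + offs[:, None] * u                       # (ni, 3)
    origins = a_grid[:, None, :] + offs[None, :, None] * v  # (ni, nj, 3)
    origins = origins.reshape(-1, 3)

    # Conservative ray-box pruning: drop lines that cannot round into the
    # array and restrict the step range; retained samples are computed with
    # arithmetic identical to the unpruned definition, so results are
    # unchanged (pruned samples are all void).
    box_lo = np.full(3, -0.5 - 1e-6)
    box_hi = shape.astype(np.float64) - 0.5 + 1e-6
    tmin = np.full(origins.shape[0], -np.inf)
    tmax = np.full(origins.shape[0], np.inf)
    alive = np.ones(origins.shape[0], dtype=bool)
    for comp in range(3):
        oc = origins[:, comp]
        dc = float(d[comp])
        if abs(dc) < 1e-12:
            alive &= (oc > box_lo[comp]) & (oc < box_hi[comp])
        else:
            t1 = (box_lo[comp] - oc) / dc
            t2 = (box_hi[comp] - oc) / dc
            tmin = np.maximum(tmin, np.minimum(t1, t2))
            tmax = np.minimum(tmax, np.maximum(t1, t2))
    alive &= tmax >= tmin
    origins = origins[alive]
    if origins.shape[0] == 0:
        empty = np.zeros((0, 1), dtype=np.int64)
        return empty, np.zeros((0, 1), dtype=bool)
    kmin = max(0, int(math.floor((tmin[alive].min() - 1.0) / STEP_VOX)) + m)
    kmax = min(2 * m, int(math.ceil((tmax[alive].max() + 1.0) / STEP_VOX)) + m)
    tt = t[kmin:kmax + 1]

    valid = np.ones((origins.shape[0], tt.size), dtype=bool)
    flat = np.zeros((origins.shape[0], tt.size), dtype=np.int64)
    for comp in range(3):
        ic = np.rint(origins[:, comp][:, None] + tt[None, :] * d[comp])
        valid &= (ic >= 0) & (ic < shape[comp])
        flat = flat * shape[comp] + ic.astype(np.int64)  # Horner index build
    flat[~valid] = 0

    keep_lines = valid.any(axis=1)
    flat, valid = flat[keep_lines], valid[keep_lines]
    if flat.size:
        cols = np.flatnonzero(valid.any(axis=0))
        flat = flat[:, cols[0]:cols[-1] + 1]
        valid = valid[:, cols[0]:cols[-1] + 1]
    return flat, valid


def _get_plans(shape, directions: DirectionSet, line_spacing_vox: float):
    n_vox = int(np.prod(shape))
    key = (tuple(shape), float(line_spacing_vox), directions.token)
    if key in _PLAN_CACHE:
        return _PLAN_CACHE[key]
    plans = [
        _line_samples(shape, d, line_spacing_vox) for d in directions.directions
    ]
    if n_vox <= _PLAN_CACHE_MAX_VOXELS:
        if len(_PLAN_CACHE) >= _PLAN_CACHE_MAX_ENTRIES:
            _PLAN_CACHE.pop(next(iter(_PLAN_CACHE)))
        _PLAN_CACHE[key] = plans
    return plans


def _mil_one_direction(mask_flat: np.ndarray, plan) -> tuple[int, int]:
    flat, valid = plan
    if flat.size == 0:
        return 0, 0
    material = mask_flat[flat] & valid
    n_samples = int(np.count_nonzero(material))
    starts = int(np.count_nonzero(material[:, 0])) + int(
        np.count_nonzero(material[:, 1:] & ~material[:, :-1])
    )
    return starts, n_samples


def compute_mil(
    mask: np.ndarray,
    spacing_um: float,
    directions: DirectionSet,
    line_spacing_vox: float = 2.0,
) -> MILProfile:
    """Directional mean intercept lengths of a binary mask.

    For every direction a family of parallel lines with perpendicular
    spacing ``line_spacing_vox`` is traced through the mask bounding box,
    sampled at half-voxel steps with nearest-voxel lookup.  An all-void mask
    is legal and yields an entirely undefined profile.

    Parameters
    ----------
    mask:
        3D boolean (or 0/1) array; material is True.
    spacing_um:
        Isotropic voxel spacing in micrometres.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3 or mask.size == 0:
        raise ValueError("mask must be a non-empty 3D array")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    if line_spacing_vox < 1:
        raise ValueError("line_spacing_vox must be >= 1")
    mask_flat = np.ascontiguousarray(mask).reshape(-1).astype(bool)

    plans = _get_plans(mask.shape, directions, line_spacing_vox)
    counts = np.zeros(directions.n, dtype=np.int64)
    totals = np.zeros(directions.n, dtype=np.float64)
    step_um = STEP_VOX * float(spacing_um)
    for k, plan in enumerate(plans):
        starts, n_samples = _mil_one_direction(mask_flat, plan)
        counts[k] = starts
        totals[k] = n_samples * step_um
    mil = np.full(directions.n, np.nan)
    defined = counts > 0
    mil[defined] = totals[defined] / counts[defined]
    return MILProfile(mil_um=mil, intercept_count=counts,
                      total_material_length_um=totals)


# ---------------------------------------------------------------------------
# Fabric tensor


def fit_fabric_tensor(profile: MILProfile, directions: DirectionSet) -> FabricTensor:
    """Least-squares fabric-ellipsoid fit to a MIL profile.

    Fits ``1/MIL(n)^2 = n^T M n`` over all directions with a defined MIL
    (directions with zero intercepts are dropped, not imputed).  Length-scale
    eigenvalues are the inverse square roots of the eigenvalues of ``M``.

    Raises
    ------
    FabricFitError
        Fewer than 6 defined directions, or rank-deficient design.
    DegenerateFabricError
        The fitted ``M`` is not positive definite; the error carries ``M``.
    """
    defined = profile.defined
    if profile.mil_um.shape[0] != directions.n:
        raise ValueError("profile and direction set sizes differ")
    n_def = int(np.count_nonzero(defined))
    if n_def < 6:
        raise FabricFitError(
            f"fabric fit needs >= 6 directions with defined MIL, got {n_def}"
        )
    nd = directions.directions[defined]
    x, y, z = nd[:, 0], nd[:, 1], nd[:, 2]
    design = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )
    if np.linalg.matrix_rank(design) < 6:
        raise FabricFitError("direction design matrix is rank-deficient")
    rhs = 1.0 / profile.mil_um[defined] ** 2
    coef, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    m = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    w, vec = np.linalg.eigh(m)  # ascending eigenvalues of M
    if w[0] <= 0:
        raise DegenerateFabricError(
            "fitted ellipsoid form is not positive definite", m
        )
    lam = 1.0 / np.sqrt(w)  # descending length-scale eigenvalues
    vec = np.column_stack([canonicalize_axial(vec[:, i]) for i in range(3)])
    # Rebuild M from the eigenpairs so the stored tensor satisfies the
    # reconstruction invariant bit-for-bit regardless of solver round-off.
    m_canon = vec @ np.diag(w) @ vec.T
    m_canon = 0.5 * (m_canon + m_canon.T)
    return FabricTensor(tensor=m_canon, eigenvalues_um=lam, eigenvectors=vec)


def anisotropy_index(tensor: FabricTensor) -> float:
    """Degree of anisotropy on a 0–1 scale: ``1 - lambda_3 / lambda_1``.

    0 for an isotropic fabric (equal eigenvalues), approaching 1 as the
    smallest characteristic length vanishes relative to the largest.
    """
    lam = tensor.eigenvalues_um
    return float(1.0 - lam[2] / lam[0])
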