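"""Synthetic fiber-volume phantoms with known ground truth.

Stand-ins for segmented micro-CT volumes: bundles of roughly parallel
tubular fibers, block-segregated mixtures of two orthogonal fiber families,
isotropic Boolean sphere packings, trabecular-like thresholded random
fields, and a biconcave disc label map with a circumferentially aligned
peripheral rim and a controllably aligned center.  Every phantom records
the ground truth (dominant axis or isotropy, nominal volume fraction,
seed) needed to validate the fabric analysis against a known answer.

Determinism contract: identical spec + seed produce bit-identical volumes.
Random streams are derived per fiber from ``(seed, fiber_index)`` via
``numpy.random.default_rng`` seed sequences, so adding more fibers never
reshuffles earlier ones.

Fibers are rasterized as hard capsules: a voxel is material when its
center lies within the fiber radius of the centerline segment.  Overlap
within a family is allowed; generation stops once the realized volume
fraction reaches the target, which keeps the realized fraction within one
fiber's worth of the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage

from ._axes import axis_index

__all__ = [
    "PhantomSpecError",
    "PhantomSpec",
    "DiscPhantomSpec",
    "PhantomTruth",
    "PhantomVolume",
    "generate_phantom",
    "make_disc_phantom",
]

PHANTOM_KINDS = ("parallel_fibers", "crossed_fibers", "isotropic_blobs", "trabecular")

_MAX_ELEMENT_ITERATIONS = 200_000

# Disc geometry constants: superellipse footprint exponent and semi-axes as
# fractions of the in-plane extents, biconcave thickness profile along Z
# (thin center, thick rim), in-disc material fraction, fiber segment length,
# and the small angular jitter of rim fibers about the local tangent.
_DISC_SUPERELLIPSE_EXPONENT = 2.5
_DISC_SEMI_AXIS_FRACTIONS = (0.45, 0.42)
_DISC_THICKNESS_FRACTIONS = (0.35, 0.85)  # center, rim (of the Z extent)
_DISC_TARGET_FRACTION = 0.30
_DISC_FIBER_LENGTH_VOX = 30.0
_DISC_RIM_JITTER_DEG = 3.0

RIM_LABEL = 1
CENTER_LABEL = 2


class PhantomSpecError(ValueError):
    """A phantom spec field is out of its valid range (names the field)."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise PhantomSpecError(f"{field_name}: {message}")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic fiber/trabecular phantom.

    ``secondary_axis``, ``mixing_fraction`` and ``block_edge_vox`` apply to
    the crossed-fiber kind only; ``anisotropy_stretch`` elongates the
    trabecular random field along ``primary_axis`` (1 = isotropic).
    """

    kind: str
    shape: tuple[int, int, int]
    spacing_um: float = 1.0
    fiber_radius_vox: float = 4.0
    target_volume_fraction: float = 0.3
    primary_axis: str = "X"
    secondary_axis: Optional[str] = None
    mixing_fraction: float = 0.5
    block_edge_vox: int = 64
    orientation_jitter_deg: float = 0.0
    anisotropy_stretch: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _require(self.kind in PHANTOM_KINDS, "kind",
                 f"must be one of {PHANTOM_KINDS}, got {self.kind!r}")
        shape = tuple(int(s) for s in self.shape)
        _require(len(shape) == 3, "shape", "must have three components")
        _require(all(s >= 16 for s in shape), "shape",
                 "every component must be >= 16 so analysis windows fit")
        object.__setattr__(self, "shape", shape)
        _require(self.spacing_um > 0, "spacing_um", "must be positive")
        _require(self.fiber_radius_vox > 0, "fiber_radius_vox", "must be positive")
        _require(0 < self.target_volume_fraction <= 0.7, "target_volume_fraction",
                 "must be in (0, 0.7]; denser packings merge fibers and void "
                 "the orientation ground truth")
        _require(self.primary_axis in ("X", "Y", "Z"), "primary_axis",
                 "must be X, Y or Z")
        _require(self.orientation_jitter_deg >= 0, "orientation_jitter_deg",
                 "must be >= 0")
        _require(self.anisotropy_stretch >= 1, "anisotropy_stretch", "must be >= 1")
        _require(int(self.seed) >= 0, "seed", "must be a non-negative integer")
        object.__setattr__(self, "seed", int(self.seed))
        if self.kind == "crossed_fibers":
            _require(self.secondary_axis in ("X", "Y", "Z"), "secondary_axis",
                     "must be X, Y or Z for crossed_fibers")
            _require(self.secondary_axis != self.primary_axis, "secondary_axis",
                     "must differ from primary_axis")
            _require(0 <= self.mixing_fraction <= 1, "mixing_fraction",
                     "must be in [0, 1]")
            _require(int(self.block_edge_vox) >= 1, "block_edge_vox",
                     "must be a positive integer")
            object.__setattr__(self, "block_edge_vox", int(self.block_edge_vox))


@dataclass(frozen=True)
class DiscPhantomSpec:
    """Parameters of the biconcave disc phantom.

    ``center_alignment`` blends the central fiber orientations between
    uniformly random (0) and fully circumferential (1); the rim is always
    circumferential with a small fixed jitter.
    """

    shape: tuple[int, int, int]
    spacing_um: float = 1.0
    rim_width_fraction: float = 0.25
    rim_fiber_radius_vox: float = 2.5
    center_alignment: float = 0.0
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        _require(len(shape) == 3, "shape", "must have three components")
        _require(all(s >= 16 for s in shape), "shape",
                 "every component must be >= 16 so analysis windows fit")
        object.__setattr__(self, "shape", shape)
        _require(self.spacing_um > 0, "spacing_um", "must be positive")
        _require(0 < self.rim_width_fraction < 0.5, "rim_width_fraction",
                 "must be in (0, 0.5)")
        _require(self.rim_fiber_radius_vox > 0, "rim_fiber_radius_vox",
                 "must be positive")
        _require(0 <= self.center_alignment <= 1, "center_alignment",
                 "must be in [0, 1]")
        _require(int(self.seed) >= 0, "seed", "must be a non-negative integer")
        object.__setattr__(self, "seed", int(self.seed))


@dataclass
class PhantomTruth:
    """Ground-truth record sufficient to predict the fabric analysis."""

    kind: str
    seed: int
    nominal_volume_fraction: float
    realized_volume_fraction: float
    dominant_axis: Optional[str] = None  # "X"/"Y"/"Z" or "isotropic"
    secondary_axis: Optional[str] = None
    mixing_fraction: Optional[float] = None
    regions: dict = dc_field(default_factory=dict)
    fiber_directions: dict = dc_field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "kind": self.kind,
            "seed": self.seed,
            "nominal_volume_fraction": self.nominal_volume_fraction,
            "realized_volume_fraction": self.realized_volume_fraction,
            "dominant_axis": self.dominant_axis,
            "secondary_axis": self.secondary_axis,
            "mixing_fraction": self.mixing_fraction,
            "regions": self.regions,
        }
        out["fiber_directions"] = {
            k: np.asarray(v).tolist() for k, v in self.fiber_directions.items()
        }
        return out


@dataclass
class PhantomVolume:
    """A generated binary mask with optional region labels and ground truth."""

    mask: np.ndarray
    spacing_um: float
    truth: PhantomTruth
    labels: Optional[np.ndarray] = None
    legend: Optional[dict] = None
    axis_map: tuple[str, str, str] = ("X", "Y", "Z")

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.mask.shape:
                raise ValueError("labels and mask must have identical shape")

    @property
    def volume_fraction(self) -> float:
        return float(self.mask.mean())


# ---------------------------------------------------------------------------
# Rasterization helpers


def _paint_capsule(mask, p0, p1, radius, clip_lo=None, clip_hi=None,
                   inside=None) -> int:
    """Set voxels within ``radius`` of segment p0–p1; return newly set count.

    ``clip_lo``/``clip_hi`` bound the affected index box (half-open);
    ``inside`` optionally restricts painting to a support mask.
    """
    shape = np.asarray(mask.shape)
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    lo = np.floor(np.minimum(p0, p1) - radius).astype(np.int64)
    hi = np.ceil(np.maximum(p0, p1) + radius).astype(np.int64) + 1
    lo = np.maximum(lo, 0 if clip_lo is None else np.maximum(clip_lo, 0))
    hi = np.minimum(hi, shape if clip_hi is None else np.minimum(clip_hi, shape))
    if np.any(hi <= lo):
        return 0
    grids = np.meshgrid(*(np.arange(l, h, dtype=np.float64)
                          for l, h in zip(lo, hi)), indexing="ij", sparse=True)
    ab = p1 - p0
    denom = float(ab @ ab)
    if denom == 0.0:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, p0))
    else:
        tt = sum((g - c) * a for g, c, a in zip(grids, p0, ab)) / denom
        tt = np.clip(tt, 0.0, 1.0)
        d2 = sum((g - (c + tt * a)) ** 2 for g, c, a in zip(grids, p0, ab))
    sel = d2 <= radius * radius
    region = tuple(slice(l, h) for l, h in zip(lo, hi))
    if inside is not None:
        sel &= inside[region]
    new = int(np.count_nonzero(sel & ~mask[region]))
    mask[region] |= sel
    return new


def _unit_axis(name: str) -> np.ndarray:
    e = np.zeros(3)
    e[axis_index(name)] = 1.0
    return e


def _jittered_direction(axis_vec: np.ndarray, jitter_deg: float, rng) -> np.ndarray:
    """Unit vector within ``jitter_deg`` of ``axis_vec`` (uniform cone angle)."""
    theta = math.radians(jitter_deg) * rng.random()
    phi = 2.0 * math.pi * rng.random()
    # orthonormal frame around the axis
    a = np.eye(3)[int(np.argmin(np.abs(axis_vec)))]
    u = np.cross(axis_vec, a)
    u /= np.linalg.norm(u)
    v = np.cross(axis_vec, u)
    d = (math.cos(theta) * axis_vec
         + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v))
    return d / np.linalg.norm(d)


def _fiber_rng(seed: int, *counters: int):
    return np.random.default_rng([int(seed), *map(int, counters)])


# ---------------------------------------------------------------------------
# Generators


def _fill_with_fibers(mask, axis_name, jitter_deg, radius, target_fraction,
                      seed, max_elements, clip_lo=None, clip_hi=None,
                      counter_prefix=()):
    """Add capsules along (jittered) ``axis_name`` until the target fraction
    of the clip box is material.  Returns the number of fibers placed."""
    shape = np.asarray(mask.shape)
    lo = np.zeros(3, dtype=np.int64) if clip_lo is None else np.asarray(clip_lo)
    hi = shape if clip_hi is None else np.minimum(np.asarray(clip_hi), shape)
    box_vox = int(np.prod(hi - lo))
    region = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    material = int(np.count_nonzero(mask[region]))
    axis_vec = _unit_axis(axis_name)
    span = float(np.linalg.norm(hi - lo)) + radius
    i = 0
    while material / box_vox < target_fraction:
        if max_elements is not None and i >= max_elements:
            break
        if i >= _MAX_ELEMENT_ITERATIONS:
            raise RuntimeError(
                "fiber placement did not reach the target volume fraction"
            )
        rng = _fiber_rng(seed, *counter_prefix, i)
        p0 = rng.uniform(lo, hi)
        d = _jittered_direction(axis_vec, jitter_deg, rng)
        material += _paint_capsule(mask, p0 - span * d, p0 + span * d, radius,
                                   clip_lo=lo, clip_hi=hi)
        i += 1
    return i


def _generate_parallel(spec: PhantomSpec, max_elements):
    mask = np.zeros(spec.shape, dtype=bool)
    _fill_with_fibers(mask, spec.primary_axis, spec.orientation_jitter_deg,
                      spec.fiber_radius_vox, spec.target_volume_fraction,
                      spec.seed, max_elements)
    return mask, {"dominant_axis": spec.primary_axis}


def _generate_crossed(spec: PhantomSpec, max_elements):
    mask = np.zeros(spec.shape, dtype=bool)
    edge = spec.block_edge_vox
    starts = [range(0, s, edge) for s in spec.shape]
    blocks = [
        (np.array([i, j, k]), np.minimum(np.array([i + edge, j + edge, k + edge]),
                                         spec.shape))
        for i in starts[0] for j in starts[1] for k in starts[2]
    ]
    n_blocks = len(blocks)
    n_primary = int(round(spec.mixing_fraction * n_blocks))
    perm = _fiber_rng(spec.seed, 0xB10C).permutation(n_blocks)
    primary_blocks = set(int(b) for b in perm[:n_primary])
    for b, (lo, hi) in enumerate(blocks):
        axis = spec.primary_axis if b in primary_blocks else spec.secondary_axis
        _fill_with_fibers(mask, axis, spec.orientation_jitter_deg,
                          spec.fiber_radius_vox, spec.target_volume_fraction,
                          spec.seed, max_elements, clip_lo=lo, clip_hi=hi,
                          counter_prefix=(1, b))
    return mask, {
        "dominant_axis": spec.primary_axis,
        "secondary_axis": spec.secondary_axis,
        "mixing_fraction": n_primary / n_blocks,
    }


def _generate_blobs(spec: PhantomSpec, max_elements):
    mask = np.zeros(spec.shape, dtype=bool)
    r = spec.fiber_radius_vox
    pad = math.ceil(r)
    padded = np.asarray(spec.shape) + 2 * pad
    # Boolean model: 1 - exp(-n v / V) = target fraction; germs are sown in a
    # padded box so coverage is uniform up to the boundary.
    germ_density = -math.log(1.0 - spec.target_volume_fraction)
    ball_vol = 4.0 / 3.0 * math.pi * r**3
    n = int(round(germ_density * float(np.prod(padded)) / ball_vol))
    if max_elements is not None:
        n = min(n, max_elements)
    for i in range(n):
        rng = _fiber_rng(spec.seed, 2, i)
        c = rng.uniform(-pad, np.asarray(spec.shape, dtype=float) + pad)
        _paint_capsule(mask, c, c, r)
    return mask, {"dominant_axis": "isotropic"}


def _generate_trabecular(spec: PhantomSpec, max_elements):
    rng = _fiber_rng(spec.seed, 3)
    noise = rng.standard_normal(spec.shape)
    sigma = np.full(3, float(spec.fiber_radius_vox))
    sigma[axis_index(spec.primary_axis)] *= spec.anisotropy_stretch
    smooth = ndimage.gaussian_filter(noise, sigma=sigma)
    if max_elements == 0:
        return np.zeros(spec.shape, dtype=bool), {
            "dominant_axis": spec.primary_axis if spec.anisotropy_stretch > 1
            else "isotropic"
        }
    threshold = np.quantile(smooth, 1.0 - spec.target_volume_fraction)
    mask = smooth >= threshold
    return mask, {
        "dominant_axis": spec.primary_axis if spec.anisotropy_stretch > 1
        else "isotropic"
    }


def generate_phantom(spec: PhantomSpec, max_elements: int | None = None) -> PhantomVolume:
    """Generate a binary phantom volume from a validated spec.

    ``max_elements`` caps the number of fibers/blobs (0 emulates the
    vanishing-volume-fraction limit with an empty mask); by default
    elements are added until the realized volume fraction reaches the
    target, so the realized fraction lies within one element's volume of
    the target.
    """
    if not isinstance(spec, PhantomSpec):
        raise TypeError("spec must be a PhantomSpec")
    generator = {
        "parallel_fibers": _generate_parallel,
        "crossed_fibers": _generate_crossed,
        "isotropic_blobs": _generate_blobs,
        "trabecular": _generate_trabecular,
    }[spec.kind]
    mask, extra = generator(spec, max_elements)
    truth = PhantomTruth(
        kind=spec.kind,
        seed=spec.seed,
        nominal_volume_fraction=spec.target_volume_fraction,
        realized_volume_fraction=float(mask.mean()),
        **extra,
    )
    return PhantomVolume(mask=mask, spacing_um=spec.spacing_um, truth=truth)


# ---------------------------------------------------------------------------
# Disc phantom


def _superellipse_field(spec: DiscPhantomSpec):
    nx, ny, _ = spec.shape
    a = _DISC_SEMI_AXIS_FRACTIONS[0] * nx
    b = _DISC_SEMI_AXIS_FRACTIONS[1] * ny
    p = _DISC_SUPERELLIPSE_EXPONENT
    x = (np.arange(nx) - (nx - 1) / 2.0)
    y = (np.arange(ny) - (ny - 1) / 2.0)
    sx = np.abs(x / a) ** p
    sy = np.abs(y / b) ** p
    s = (sx[:, None] + sy[None, :]) ** (1.0 / p)
    return s, a, b, p


def _disc_support_and_labels(spec: DiscPhantomSpec):
    nx, ny, nz = spec.shape
    s, a, b, p = _superellipse_field(spec)
    t_center, t_rim = (f * nz for f in _DISC_THICKNESS_FRACTIONS)
    thickness = t_center + (t_rim - t_center) * np.clip(s, 0.0, 1.0) ** 2
    zc = (nz - 1) / 2.0
    z = np.arange(nz)
    inside_plane = s <= 1.0
    support = inside_plane[:, :, None] & (
        np.abs(z[None, None, :] - zc) <= thickness[:, :, None] / 2.0
    )
    labels = np.zeros(spec.shape, dtype=np.uint8)
    rim_plane = inside_plane & (s >= 1.0 - spec.rim_width_fraction)
    labels[support] = CENTER_LABEL
    labels[rim_plane[:, :, None] & support] = RIM_LABEL
    return support, labels, (s, a, b, p)


def _tangent_at(x: float, y: float, nx: int, ny: int, a: float, b: float,
                p: float, rng) -> np.ndarray:
    """In-plane unit tangent to the superellipse level set through (x, y)."""
    xr = (x - (nx - 1) / 2.0) / a
    yr = (y - (ny - 1) / 2.0) / b
    gx = p * np.abs(xr) ** (p - 1) * np.sign(xr) / a
    gy = p * np.abs(yr) ** (p - 1) * np.sign(yr) / b
    t = np.array([-gy, gx, 0.0])
    norm = np.linalg.norm(t)
    if norm < 1e-12:  # footprint center: no defined tangent
        phi = 2.0 * math.pi * rng.random()
        return np.array([math.cos(phi), math.sin(phi), 0.0])
    return t / norm


def make_disc_phantom(spec: DiscPhantomSpec,
                      max_elements: int | None = None) -> PhantomVolume:
    """Biconcave disc label map with circumferential rim fibers.

    The footprint is a superellipse in the XY plane with a biconcave
    thickness profile along Z (central thickness < rim thickness).  Rim
    fibers follow the local circumferential tangent with a small jitter;
    center fibers are drawn uniformly at random on the sphere and blended
    toward the local tangent by ``center_alignment``.  The drawn per-fiber
    directions are stored in the truth record per region.
    """
    if not isinstance(spec, DiscPhantomSpec):
        raise TypeError("spec must be a DiscPhantomSpec")
    support, labels, (s, a, b, p) = _disc_support_and_labels(spec)
    nx, ny, nz = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    support_count = int(np.count_nonzero(support))
    if support_count == 0:
        raise PhantomSpecError("shape: disc support is empty for this shape")
    material = 0
    half_len = _DISC_FIBER_LENGTH_VOX / 2.0
    ca = spec.center_alignment
    directions: dict[str, list] = {"rim": [], "center": []}
    i = 0
    while material / support_count < _DISC_TARGET_FRACTION:
        if max_elements is not None and i >= max_elements:
            break
        if i >= _MAX_ELEMENT_ITERATIONS:
            raise RuntimeError("disc fiber placement did not reach the target "
                               "volume fraction")
        rng = _fiber_rng(spec.seed, i)
        p0 = rng.uniform(0.0, np.asarray(spec.shape, dtype=float))
        idx = tuple(np.minimum(np.rint(p0).astype(int), np.asarray(spec.shape) - 1))
        i += 1
        if not support[idx]:
            continue
        tangent = _tangent_at(p0[0], p0[1], nx, ny, a, b, p, rng)
        if labels[idx] == RIM_LABEL:
            d = _jittered_direction(tangent, _DISC_RIM_JITTER_DEG, rng)
            directions["rim"].append(d)
        else:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            if ca == 0.0:
                d = u
            else:
                t_signed = tangent if float(u @ tangent) >= 0 else -tangent
                d = (1.0 - ca) * u + ca * t_signed
                norm = np.linalg.norm(d)
                d = u if norm < 1e-9 else d / norm
            directions["center"].append(d)
        material += _paint_capsule(mask, p0 - half_len * d, p0 + half_len * d,
                                   spec.rim_fiber_radius_vox, inside=support)
    truth = PhantomTruth(
        kind="disc",
        seed=spec.seed,
        nominal_volume_fraction=_DISC_TARGET_FRACTION,
        realized_volume_fraction=material / support_count,
        regions={
            "rim": {"orientation": "circumferential",
                    "jitter_deg": _DISC_RIM_JITTER_DEG, "label": RIM_LABEL},
            "center": {"alignment": ca, "label": CENTER_LABEL},
        },
        fiber_directions={k: np.asarray(v) for k, v in directions.items()},
    )
    return PhantomVolume(
        mask=mask, spacing_um=spec.spacing_um, truth=truth, labels=labels,
        legend={RIM_LABEL: "rim", CENTER_LABEL: "center"},
    )
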