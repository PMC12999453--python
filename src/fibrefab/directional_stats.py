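"""Reductions of an orientation field into directional statistics.

Implements the descriptive statistics reported for full-volume fiber
analyses: the total vector count, percentage distributions of dominant
directional components per anatomical axis, anisotropy summaries (mean,
median, sample SD), in-plane rose histograms for the three anatomical
planes in both a Fiber Frequency weighting (count per angular bin) and a
Sum Magnitude weighting (summed primary eigenvalues per bin), and
between-region anisotropy contrasts (e.g. disc rim vs. center).

Fiber orientations are axial (v and -v describe the same fiber), so
in-plane angles are folded into [0, 180); displayed rose diagrams mirror
the half-circle.  Every statistic is invariant under per-sample sign flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from ._axes import ANATOMICAL_AXES

__all__ = [
    "PLANES",
    "AxisSummary",
    "PlaneHistogram",
    "AnisotropySummary",
    "RegionContrast",
    "dominant_axis",
    "dominant_axis_fractions",
    "project_to_plane",
    "rose_histogram",
    "summarize_anisotropy",
    "region_contrast",
    "render_rose",
]

# plane name -> (first in-plane axis, second in-plane axis) as indices into
# the anatomical (X, Y, Z) component order; angles run from the first axis
# toward the second.
PLANES = {
    "sagittal_YZ": (1, 2),
    "frontal_XZ": (0, 2),
    "transverse_XY": (0, 1),
}

_IN_PLANE_EPS = 1e-6


@dataclass(frozen=True)
class AxisSummary:
    """Dominant-axis counts and fractions over a field."""

    counts: tuple  # (X, Y, Z)
    total: int

    def __post_init__(self):
        if sum(self.counts) != self.total:
            raise ValueError("axis counts must sum to the total")

    @property
    def fractions(self) -> tuple:
        return tuple(c / self.total for c in self.counts)

    def exact_fractions(self) -> tuple:
        """Rational fractions; these sum to exactly 1."""
        return tuple(Fraction(c, self.total) for c in self.counts)


@dataclass(frozen=True)
class PlaneHistogram:
    """Rose histogram of in-plane fiber angles for one anatomical plane.

    ``counts`` is the Fiber Frequency weighting; ``sum_magnitude_um`` the
    Sum Magnitude weighting (both always filled).  ``excluded`` counts
    samples with no in-plane component; counts + excluded conserve the
    field total.
    """

    plane: str
    bin_edges_deg: tuple
    counts: tuple
    sum_magnitude_um: tuple
    excluded: int

    def __post_init__(self):
        edges = np.asarray(self.bin_edges_deg, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != edges.size - 1:
            raise ValueError("counts length must match the number of bins")
        if len(self.sum_magnitude_um) != len(self.counts):
            raise ValueError("sum_magnitude length must match counts")


@dataclass(frozen=True)
class AnisotropySummary:
    """Mean, median, sample SD (n-1; 0 when n=1) of anisotropy indices."""

    mean: float
    median: float
    sd: float
    n: int


@dataclass(frozen=True)
class RegionContrast:
    """Per-region anisotropy summaries and the mean difference (a - b)."""

    region_a: str
    region_b: str
    summary_a: AnisotropySummary
    summary_b: AnisotropySummary
    mean_difference: float


def _e1_matrix(field) -> np.ndarray:
    if hasattr(field, "e1_array"):
        return field.e1_array()
    return np.asarray(field, dtype=np.float64).reshape(-1, 3)


def _require_nonempty(field) -> np.ndarray:
    e1 = _e1_matrix(field)
    if e1.shape[0] == 0:
        raise ValueError("the orientation field is empty")
    return e1


def dominant_axis(e1: Sequence[float]) -> int:
    """Anatomical axis index (0=X, 1=Y, 2=Z) of the largest |component|.

    Ties break toward X before Y before Z, matching the axial
    canonicalization rule.
    """
    return int(np.argmax(np.abs(np.asarray(e1, dtype=float))))


def dominant_axis_fractions(field) -> AxisSummary:
    """Proportion of vectors dominantly oriented along each anatomical axis."""
    e1 = _require_nonempty(field)
    dom = np.argmax(np.abs(e1), axis=1)
    counts = tuple(int(np.count_nonzero(dom == k)) for k in range(3))
    return AxisSummary(counts=counts, total=e1.shape[0])


def project_to_plane(sample, plane: str):
    """Project an axial orientation onto an anatomical plane.

    Returns ``(angle_deg, in_plane_weight)`` with the angle measured from
    the plane's first axis toward its second (sagittal: +Y toward +Z,
    frontal: +X toward +Z, transverse: +X toward +Y), folded into
    [0, 180) since fibers are axial; the weight is the norm of the
    in-plane component pair.  Returns ``None`` (excluded) when the vector
    has no in-plane component (weight below 1e-6).
    """
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(PLANES)}")
    v = np.asarray(getattr(sample, "e1", sample), dtype=float)
    i, j = PLANES[plane]
    a, b = float(v[i]), float(v[j])
    weight = math.hypot(a, b)
    if weight < _IN_PLANE_EPS:
        return None
    angle = math.degrees(math.atan2(b, a)) % 180.0
    return angle, weight


def rose_histogram(field, plane: str, n_bins: int = 18) -> PlaneHistogram:
    """Equal-width half-open angular bins over [0, 180) for one plane.

    Fills both weightings: per-bin sample counts (Fiber Frequency) and
    per-bin sums of sample magnitudes (Sum Magnitude).  Out-of-plane
    samples are excluded and counted, never silently dropped.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    samples = getattr(field, "samples", None)
    if samples is None or len(samples) == 0:
        raise ValueError("the orientation field is empty")
    width = 180.0 / n_bins
    edges = tuple(k * width for k in range(n_bins + 1))
    counts = np.zeros(n_bins, dtype=np.int64)
    sums = np.zeros(n_bins, dtype=np.float64)
    excluded = 0
    for s in samples:
        proj = project_to_plane(s, plane)
        if proj is None:
            excluded += 1
            continue
        angle, _ = proj
        k = min(int(angle // width), n_bins - 1)
        counts[k] += 1
        sums[k] += s.magnitude_um
    return PlaneHistogram(
        plane=plane, bin_edges_deg=edges, counts=tuple(int(c) for c in counts),
        sum_magnitude_um=tuple(float(x) for x in sums), excluded=excluded,
    )


def _summary(values: np.ndarray) -> AnisotropySummary:
    n = values.size
    sd = 0.0 if n == 1 else float(np.std(values, ddof=1))
    return AnisotropySummary(
        mean=float(np.mean(values)), median=float(np.median(values)),
        sd=sd, n=int(n),
    )


def summarize_anisotropy(field, by_axis: bool = False):
    """Anisotropy-index summaries over a field, optionally per dominant axis.

    With ``by_axis`` the samples are grouped by the anatomical axis of
    their dominant e1 component; groups are returned as a dict keyed by
    axis name, omitting empty axes.
    """
    e1 = _require_nonempty(field)
    aniso = field.anisotropy_array() if hasattr(field, "anisotropy_array") else None
    if aniso is None:
        raise ValueError("summarize_anisotropy needs an OrientationField")
    if not by_axis:
        return _summary(aniso)
    dom = np.argmax(np.abs(e1), axis=1)
    out = {}
    for k, name in enumerate(ANATOMICAL_AXES):
        sel = aniso[dom == k]
        if sel.size:
            out[name] = _summary(sel)
    if not out:
        raise ValueError("no non-empty dominant-axis group")
    return out


def region_contrast(field, region_of_sample: Sequence, region_a, region_b) -> RegionContrast:
    """Anisotropy contrast between two named regions of a field.

    ``region_of_sample`` assigns a region to each sample in field order
    (e.g. from :func:`fibrefab.orientation_field.window_region_labels`).
    """
    aniso = field.anisotropy_array()
    regions = list(region_of_sample)
    if len(regions) != aniso.size:
        raise ValueError("region_of_sample must align with the field samples")
    values = {}
    for name in (region_a, region_b):
        sel = aniso[[r == name for r in regions]]
        if sel.size == 0:
            raise ValueError(f"region {name!r} has no samples")
        values[name] = sel
    sa, sb = _summary(values[region_a]), _summary(values[region_b])
    return RegionContrast(
        region_a=str(region_a), region_b=str(region_b),
        summary_a=sa, summary_b=sb,
        mean_difference=sa.mean - sb.mean,
    )


def render_rose(hist: PlaneHistogram, weighting: str = "frequency",
                path=None, ax=None):
    """Render a rose diagram (mirrored half-circle) from a stored histogram.

    A thin display layer: the numbers in the histogram are the contract.
    ``weighting`` selects ``frequency`` (counts) or ``sum_magnitude``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if weighting == "frequency":
        values = np.asarray(hist.counts, dtype=float)
    elif weighting == "sum_magnitude":
        values = np.asarray(hist.sum_magnitude_um, dtype=float)
    else:
        raise ValueError("weighting must be 'frequency' or 'sum_magnitude'")
    edges = np.radians(np.asarray(hist.bin_edges_deg))
    centers = (edges[:-1] + edges[1:]) / 2
    width = np.diff(edges)
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.concatenate([centers, centers + np.pi])  # mirror: axial data
    ax.bar(theta, np.concatenate([values, values]),
           width=np.concatenate([width, width]), bottom=0.0, alpha=0.8)
    ax.set_title(f"{hist.plane} ({weighting})")
    if path is not None and own_fig:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
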