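"""Independent reference implementations used only by the tests.

These mirror the documented line-sampling and inscribed-sphere contracts
with deliberately naive code paths (per-line loops, exhaustive sphere
enumeration) so the optimized library implementations can be checked
against them exactly.
"""

from __future__ import annotations

import math
from itertools import groupby

import numpy as np
from scipy import ndimage


def naive_mil(mask, spacing_um, directions, line_spacing_vox):
    """Per-line run-length MIL: loops over every line of every family.

    Follows the documented sampling geometry (line grid over the volume
    half-diagonal, half-voxel steps, nearest-voxel lookup, boundary runs
    count as one intercept) with straightforward per-line bookkeeping.
    Returns (mil_um, intercept_count, total_material_length_um) arrays.
    """
    mask = np.asarray(mask).astype(bool)
    shape = np.asarray(mask.shape)
    c = (shape.astype(float) - 1.0) / 2.0
    half = 0.5 * float(np.linalg.norm(shape.astype(float)))
    step = 0.5
    n_off = int(math.ceil(half / line_spacing_vox))
    offs = np.arange(-n_off, n_off + 1, dtype=float) * float(line_spacing_vox)
    m = int(math.ceil(half / step))
    t = np.arange(-m, m + 1, dtype=float) * step
    mils, counts, totals = [], [], []
    for d in directions.directions:
        a = np.eye(3)[int(np.argmin(np.abs(d)))]
        u = np.cross(d, a)
        u = u / np.linalg.norm(u)
        v = np.cross(d, u)
        n_int = 0
        n_mat = 0
        for oi in offs:
            part = c + oi * u
            for oj in offs:
                origin = part + oj * v
                p = origin + t[:, None] * d
                idx = np.rint(p)
                ok = np.all((idx >= 0) & (idx < shape), axis=1)
                line = np.zeros(t.size, dtype=bool)
                ii = idx[ok].astype(int)
                if ii.size:
                    line[ok] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
                n_mat += int(line.sum())
                for value, _ in groupby(line):
                    if value:
                        n_int += 1
        counts.append(n_int)
        totals.append(n_mat * step * float(spacing_um))
        mils.append(np.nan if n_int == 0 else totals[-1] / n_int)
    return np.array(mils), np.array(counts), np.array(totals)


def brute_local_thickness(mask, spacing_um=1.0):
    """Exhaustive largest-inscribed-sphere thickness for tiny masks.

    thickness(p) = max over material centers c with |p - c| < dt(c) of
    (2 dt(c) - 1) voxels, evaluated by direct enumeration of all pairs.
    """
    mask = np.asarray(mask).astype(bool)
    dt = ndimage.distance_transform_edt(mask)
    pts = np.argwhere(mask)
    out = np.zeros(mask.shape)
    for cpt in pts:
        r = dt[tuple(cpt)]
        d2 = ((pts - cpt) ** 2).sum(axis=1)
        covered = d2 < r * r - 1e-9
        value = 2.0 * r - 1.0
        for p in pts[covered]:
            if out[tuple(p)] < value:
                out[tuple(p)] = value
    result = np.full(mask.shape, np.nan)
    result[mask] = out[mask] * float(spacing_um)
    return result
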