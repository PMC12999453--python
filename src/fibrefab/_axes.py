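"""Anatomical-axis bookkeeping.

The anatomical frame is fixed throughout the package:

* ``X`` — lateral–medial
* ``Y`` — ventral–dorsal
* ``Z`` — cranial–caudal

Array storage order carries no anatomical meaning; an ``axis_map`` (a
permutation of ``("X", "Y", "Z")``) states which anatomical axis each array
axis corresponds to.  ``axis_map[i]`` is the anatomical axis of array axis
``i``.
"""

from __future__ import annotations

from typing import Sequence, Tuple

ANATOMICAL_AXES: Tuple[str, str, str] = ("X", "Y", "Z")

AxisMap = Tuple[str, str, str]


def validate_axis_map(axis_map: Sequence[str]) -> AxisMap:
    am = tuple(str(a).upper() for a in axis_map)
    if sorted(am) != sorted(ANATOMICAL_AXES):
        raise ValueError(
            f"axis_map must be a permutation of {ANATOMICAL_AXES}, got {axis_map!r}"
        )
    return am  # type: ignore[return-value]


def anatomical_order(axis_map: Sequence[str]) -> Tuple[int, int, int]:
    """Array-axis indices in anatomical (X, Y, Z) order.

    ``perm = anatomical_order(axis_map)`` satisfies
    ``volume.transpose(perm)[ix, iy, iz]`` = voxel at anatomical index
    (ix, iy, iz), and for component vectors ``v_anat = v_array[list(perm)]``.
    """
    am = validate_axis_map(axis_map)
    return tuple(am.index(a) for a in ANATOMICAL_AXES)  # type: ignore[return-value]


def axis_index(axis: str) -> int:
    """Index of an anatomical axis name in the (X, Y, Z) frame."""
    try:
        return ANATOMICAL_AXES.index(axis.upper())
    except ValueError:
        raise ValueError(f"unknown anatomical axis {axis!r}") from None
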