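"""SWI minimum-intensity projection and the ordinal venous-contrast score.

On susceptibility-weighted imaging, deoxygenated venous blood is dark, so
vein conspicuity on minimum-intensity projections (minIP) tracks venous
deoxyhemoglobin content. Venous contrast is rated visually on a 4-point
ordinal scale combining the visibility of the deep venous vasculature and
of cortical veins:

====== ============== ===============
score  deep veins     cortical veins
====== ============== ===============
1      no             no
2      no             medium
3      medium         good
4      good           good
====== ============== ===============

The rating itself is a radiologist judgment and stays manual; this module
computes the projections and encodes/validates the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "Visibility",
    "SwiScore",
    "SCORE_TABLE",
    "score_from_visibility",
    "min_intensity_projection",
    "DEFAULT_SLAB_THICKNESS",
]

#: Legal visibility levels for either vein class.
VISIBILITY_LEVELS = ("no", "medium", "good")
Visibility = str

#: (deep, cortical) -> score, bijective over the four legal combinations.
SCORE_TABLE: dict[tuple[str, str], int] = {
    ("no", "no"): 1,
    ("no", "medium"): 2,
    ("medium", "good"): 3,
    ("good", "good"): 4,
}

#: Default minIP slab: 8 slices, axial — common SWI reading practice.
DEFAULT_SLAB_THICKNESS = 8

_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass(frozen=True)
class SwiScore:
    """Ordinal venous-contrast score with its defining visibility pair."""

    value: int
    deep_veins: Visibility
    cortical_veins: Visibility

    def __post_init__(self):
        if SCORE_TABLE.get((self.deep_veins, self.cortical_veins)) != self.value:
            raise ValidationError(
                f"({self.deep_veins}, {self.cortical_veins}) -> {self.value} "
                f"is not a row of the scoring table; legal rows: "
                + ", ".join(f"{pair} -> {s}" for pair, s in SCORE_TABLE.items())
            )


def score_from_visibility(deep: Visibility, cortical: Visibility) -> SwiScore:
    """Map a (deep, cortical) visibility pair to its score.

    Combinations outside the four-row scale (e.g. good deep veins with
    invisible cortical veins) are rejected.
    """
    for name, level in (("deep", deep), ("cortical", cortical)):
        if level not in VISIBILITY_LEVELS:
            raise ValidationError(
                f"{name} visibility must be one of {VISIBILITY_LEVELS}, "
                f"got {level!r}")
    try:
        value = SCORE_TABLE[(deep, cortical)]
    except KeyError:
        legal = ", ".join(f"(deep={d}, cortical={c})" for d, c in SCORE_TABLE)
        raise ValidationError(
            f"(deep={deep}, cortical={cortical}) is not on the venous-contrast "
            f"scale; legal pairs: {legal}") from None
    return SwiScore(value=value, deep_veins=deep, cortical_veins=cortical)


def min_intensity_projection(
    volume: np.ndarray,
    slab_thickness_slices: int = DEFAULT_SLAB_THICKNESS,
    axis: str = "axial",
) -> np.ndarray:
    """Slab-wise minimum-intensity projections of a 3D SWI magnitude volume.

    The projection axis is tiled into consecutive slabs of
    ``slab_thickness_slices`` slices (the last slab may be short); each
    output pixel is the minimum over its slab window. Returns an array of
    shape ``(n_slabs, ...)`` with the two in-plane dimensions preserved.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValidationError("min_intensity_projection expects a 3D volume")
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume must be finite")
    if slab_thickness_slices < 1:
        raise ValidationError("slab thickness must be >= 1")
    try:
        ax = _AXES[axis]
    except KeyError:
        raise ValidationError(
            f"axis must be one of {sorted(_AXES)}, got {axis!r}") from None
    if slab_thickness_slices > volume.shape[ax]:
        raise ValidationError(
            f"slab thickness {slab_thickness_slices} exceeds axis extent "
            f"{volume.shape[ax]}")
    moved = np.moveaxis(volume, ax, 0)
    n = moved.shape[0]
    slabs = [
        moved[start:start + slab_thickness_slices].min(axis=0)
        for start in range(0, n, slab_thickness_slices)
    ]
    return np.stack(slabs, axis=0)
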