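"""Temporal MIP, cerebrovascular segmentation and vessel-curve sampling.

The 4D series is first collapsed to a temporal maximum-intensity projection
(per-voxel maximum over frames), which is independent of bolus arrival time
and therefore a convenient support for segmenting the bright vasculature.
Segmentation here is a deliberately simple, deterministic pipeline —
intensity-percentile threshold, small-component removal (26-connectivity),
optional morphological closing — sufficient to provide a voxel support for
curve sampling on high-contrast MRA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, binary_closing

from .core import Series4D, SignalCurve, VesselMask
from .errors import ValidationError

__all__ = [
    "SegmentationParams",
    "temporal_mip",
    "segment_vessels",
    "sample_vessel_curves",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the percentile-threshold segmentation.

    intensity_percentile : percentile of the positive-intensity voxels used
        as threshold (strictly-greater); default 99.0 keeps the top 1%.
    min_component_voxels : connected components (26-connectivity) smaller
        than this are discarded; default 20 removes speckle.
    closing_radius_voxels : radius of an optional binary closing; 0 = off.
    """

    intensity_percentile: float = 99.0
    min_component_voxels: int = 20
    closing_radius_voxels: int = 0

    def __post_init__(self):
        if not (50.0 < self.intensity_percentile < 100.0):
            raise ValidationError("intensity_percentile must be in (50, 100)")
        if self.min_component_voxels < 1:
            raise ValidationError("min_component_voxels must be positive")
        if self.closing_radius_voxels < 0:
            raise ValidationError("closing_radius_voxels must be >= 0")


def temporal_mip(series: Series4D) -> np.ndarray:
    """Per-voxel maximum over the time dimension (3D volume)."""
    return series.data.max(axis=3)


def segment_vessels(
    mip: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> VesselMask:
    """Segment bright vasculature on a temporal MIP.

    Thresholds at the given percentile of the strictly positive voxels
    (padded zero background is ignored), removes 26-connected components
    smaller than ``min_component_voxels``, then applies an optional binary
    closing. A volume with zero dynamic range yields an empty mask and a
    warning.
    """
    mip = np.asarray(mip, dtype=float)
    if mip.ndim != 3:
        raise ValidationError("segment_vessels expects a 3D volume")
    if not np.all(np.isfinite(mip)) or np.any(mip < 0):
        raise ValidationError("MIP volume must be finite and nonnegative")
    if np.ptp(mip) == 0:
        warnings.warn("volume has zero dynamic range; returning empty mask",
                      RuntimeWarning, stacklevel=2)
        return VesselMask(np.zeros(mip.shape, dtype=bool))

    positive = mip[mip > 0]
    reference = positive if positive.size else mip.ravel()
    threshold = np.percentile(reference, params.intensity_percentile)
    mask = mip > threshold

    labels, n_labels = ndimage.label(mask, structure=_STRUCT_26)
    if n_labels:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= params.min_component_voxels
        keep[0] = False
        mask = keep[labels]

    if params.closing_radius_voxels > 0 and mask.any():
        mask = binary_closing(mask, ball(params.closing_radius_voxels))
    return VesselMask(mask)


def sample_vessel_curves(
    series: Series4D,
    mask: VesselMask,
    n_curves: int = 250,
    seed: int = 0,
) -> list[SignalCurve]:
    """Randomly select voxel time courses from within the vessel mask.

    Exactly ``min(n_curves, mask size)`` distinct voxels are drawn uniformly
    without replacement using the given seed; each returned curve carries its
    voxel coordinate. The study protocol draws 250 curves per series.
    """
    if n_curves < 1:
        raise ValidationError("n_curves must be positive")
    coords = mask.coordinates()
    if coords.shape[0] == 0:
        raise ValidationError("no vessel voxels: mask is empty")
    if mask.mask.shape != series.shape[:3]:
        raise ValidationError("mask extent does not match series")
    k = min(n_curves, coords.shape[0])
    rng = np.random.default_rng(seed)
    chosen = rng.choice(coords.shape[0], size=k, replace=False)
    return [series.curve_at(*coords[i]) for i in chosen]
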