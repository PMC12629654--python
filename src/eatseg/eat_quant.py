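"""Epicardial fat extraction and volumetry on the native CT grid.

Stage two of the pipeline: inside the pericardium mask, every voxel whose
HU falls in the adipose window (default −190 to −30 HU, inclusive — the
established fat range at 120 kV) is epicardial adipose tissue. Volume is
the voxel count times the voxel volume; a per-slice (inferior-first)
volume profile supports regional analyses such as the inferior-share
statistic.

Thresholding always happens on the original high-resolution image, never
on the downsampled network grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ct_io import CTVolume, SegmentationMask

__all__ = ["EATWindow", "EATResult", "extract_eat", "inferior_share"]


class UndefinedShareError(ValueError):
    """Inferior share is undefined when the total EAT volume is zero."""


@dataclass(frozen=True)
class EATWindow:
    """Inclusive HU window for adipose tissue."""

    lo: float = -190.0
    hi: float = -30.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"EAT window requires lo < hi, got [{self.lo}, {self.hi}]")


@dataclass
class EATResult:
    """EAT mask, volume and per-slice profile on the native grid.

    slice_profile is ordered inferior-first (canonical axis-2 order) and
    sums to volume_cm3 within float tolerance.
    """

    mask: SegmentationMask
    volume_cm3: float
    window: EATWindow
    slice_profile: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.data.sum())

    def to_dict(self) -> dict:
        return {
            "volume_cm3": self.volume_cm3,
            "n_voxels": self.n_voxels,
            "window_hu": [self.window.lo, self.window.hi],
            "spacing_mm": list(self.mask.spacing),
            "slice_profile_cm3": [float(v) for v in self.slice_profile],
        }


def extract_eat(
    vol: CTVolume, pericardium: SegmentationMask, window: EATWindow | None = None
) -> EATResult:
    """Threshold the adipose HU window inside the pericardium.

    mask = pericardium ∧ (window.lo ≤ HU ≤ window.hi), inclusive on both
    ends; volume_cm3 = voxel count · sx·sy·sz / 1000.
    """
    window = window or EATWindow()
    pericardium.check_same_grid(vol)
    eat = (
        (pericardium.data == 1)
        & (vol.data >= window.lo)
        & (vol.data <= window.hi)
    )
    sx, sy, sz = vol.spacing
    voxel_cm3 = sx * sy * sz / 1000.0
    counts = eat.sum(axis=(0, 1)).astype(np.int64)
    profile = counts * voxel_cm3
    volume = float(int(counts.sum()) * voxel_cm3)
    mask = SegmentationMask(eat.astype(np.uint8), vol.spacing, vol.origin, vol.axcodes)
    return EATResult(mask=mask, volume_cm3=volume, window=window, slice_profile=profile)


def inferior_share(result: EATResult, fraction: float = 0.2) -> float:
    """Fraction of total EAT volume held by the most-inferior EAT slices.

    The slice extent is taken over slices that contain any EAT; the
    inferior group is the ``ceil(fraction · n_eat_slices)`` most-inferior
    of those. Raises :class:`UndefinedShareError` for zero total volume.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    profile = np.asarray(result.slice_profile, dtype=float)
    total = profile.sum()
    if total <= 0:
        raise UndefinedShareError("no EAT voxels: inferior share is undefined")
    eat_slices = np.flatnonzero(profile > 0)  # inferior-first ordering
    k = math.ceil(fraction * eat_slices.size)
    return float(profile[eat_slices[:k]].sum() / total)
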