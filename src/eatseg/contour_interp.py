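"""Dense pericardium masks from sparse per-slice annotations.

Manual pericardium delineation is typically done on every 5th axial slice
(plus extra consecutive slices near the apex, where the boundary is faint).
This module completes the mask on the remaining slices by shape-based
interpolation: each annotated slice is converted to a signed Euclidean
distance field (positive inside), the fields of the two bracketing
annotated slices are blended linearly along z, and the blend is
thresholded at zero. Annotated slices are reproduced exactly; slices
outside the annotated heart extent stay empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .ct_io import SegmentationMask

__all__ = ["SparseAnnotation", "interpolate_dense", "signed_distance_2d"]


class InsufficientAnnotationError(ValueError):
    """Fewer than two annotated slices: nothing to interpolate between."""


@dataclass
class SparseAnnotation:
    """Per-slice binary annotations on a subset of axial slices.

    slices : mapping from axial slice index → 2D binary mask (all masks
        share one in-plane shape)
    shape : full 3D grid shape of the parent volume
    spacing : voxel spacing of the parent volume, mm
    bounds : (inferior_idx, superior_idx) inclusive annotated heart extent
    """

    slices: dict[int, np.ndarray]
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    bounds: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.slices:
            raise InsufficientAnnotationError("no annotated slices")
        plane = self.shape[:2]
        cleaned = {}
        for z, m in self.slices.items():
            m = np.asarray(m)
            if m.shape != tuple(plane):
                raise ValueError(
                    f"slice {z}: in-plane shape {m.shape} != volume plane {plane}"
                )
            cleaned[int(z)] = m.astype(bool)
        self.slices = cleaned
        lo, hi = self.bounds
        zs = sorted(self.slices)
        if not (lo <= zs[0] and zs[-1] <= hi):
            raise ValueError(
                f"bounds {self.bounds} do not contain annotated slices {zs[0]}..{zs[-1]}"
            )

    @property
    def annotated_indices(self) -> list[int]:
        return sorted(self.slices)


def signed_distance_2d(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance field of a 2D mask, positive inside."""
    mask = np.asarray(mask, dtype=bool)
    deep = float(sum(mask.shape))  # finite stand-in for "no boundary in plane"
    if not mask.any():
        return np.full(mask.shape, -deep, dtype=np.float32)
    if mask.all():
        return np.full(mask.shape, deep, dtype=np.float32)
    inside = distance_transform_edt(mask)
    outside = distance_transform_edt(~mask)
    return (inside - outside).astype(np.float32)


def interpolate_dense(ann: SparseAnnotation) -> SegmentationMask:
    """Reconstruct the dense mask from sparse slice annotations.

    Between two consecutive annotated slices z0 < z1 the mask at slice z is
    ``(1−w)·sdf(z0) + w·sdf(z1) ≥ 0`` with ``w = (z−z0)/(z1−z0)``. Slices
    outside ``ann.bounds`` (and outside the annotated index range) remain
    empty.
    """
    zs = ann.annotated_indices
    if len(zs) < 2:
        raise InsufficientAnnotationError(
            f"need at least 2 annotated slices, got {len(zs)}"
        )
    out = np.zeros(ann.shape, dtype=np.uint8)
    sdf_cache: dict[int, np.ndarray] = {}

    def sdf(z: int) -> np.ndarray:
        if z not in sdf_cache:
            sdf_cache[z] = signed_distance_2d(ann.slices[z])
        return sdf_cache[z]

    for z0, z1 in zip(zs[:-1], zs[1:]):
        for z in range(z0 + 1, z1):
            w = (z - z0) / (z1 - z0)
            d0, d1 = sdf(z0), sdf(z1)
            out[:, :, z] = (1.0 - w) * d0 + w * d1 >= 0
        sdf_cache.pop(z0, None)
    for z in zs:
        out[:, :, z] = ann.slices[z]
    return SegmentationMask(out, ann.spacing)
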