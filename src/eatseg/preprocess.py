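"""Deterministic preprocessing from native CT grids to fixed training cubes.

The forward pipeline is: isotropic resampling (trilinear for images,
nearest-neighbour for masks) → centred pad/crop to a fixed cube →
HU clipping and linear normalisation to [0, 1]. The auxiliary "redundant"
training class (fat-density voxels outside the pericardium in the inferior
20% of axial slices) is generated on the resampled HU grid, before
normalisation, so all supervision lives on one grid.

Every forward run is recorded in a :class:`GridTransform`, which
:func:`invert_to_native` uses to map a cube-grid prediction back to the
native voxel grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .ct_io import CTVolume, SegmentationMask, GridMismatchError

__all__ = [
    "PreprocessConfig",
    "GridTransform",
    "LabelVolume",
    "resample_isotropic",
    "pad_crop_center",
    "clip_normalize",
    "make_redundant_class",
    "apply_pipeline",
    "invert_to_native",
]

BACKGROUND, PERICARDIUM, REDUNDANT = 0, 1, 2


@dataclass
class PreprocessConfig:
    """Preprocessing parameters (clinical-scale reference defaults).

    target_spacing_mm : isotropic voxel size after resampling
    cube_size : edge length of the network input cube, voxels
    clip_lo_hu / clip_hi_hu : HU clipping window before normalisation
    redundant_lo_hu / redundant_hi_hu : HU window of the redundant class
    inferior_fraction : fraction of axial slices (whole scan, counted from
        the most inferior slice) eligible for the redundant class
    """

    target_spacing_mm: float = 1.6
    cube_size: int = 128
    clip_lo_hu: float = -800.0
    clip_hi_hu: float = 1200.0
    redundant_lo_hu: float = -198.0
    redundant_hi_hu: float = -80.0
    inferior_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.clip_lo_hu >= self.clip_hi_hu:
            raise ValueError("clip_lo_hu must be < clip_hi_hu")
        if self.redundant_lo_hu >= self.redundant_hi_hu:
            raise ValueError("redundant_lo_hu must be < redundant_hi_hu")
        if not (0.0 < self.inferior_fraction < 1.0):
            raise ValueError("inferior_fraction must lie in (0, 1)")
        if self.cube_size < 1:
            raise ValueError("cube_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GridTransform:
    """Exact record of resample + pad/crop, sufficient to invert it."""

    native_shape: tuple[int, int, int]
    native_spacing: tuple[float, float, float]
    resampled_shape: tuple[int, int, int]
    pad_low: tuple[int, int, int] = (0, 0, 0)
    pad_high: tuple[int, int, int] = (0, 0, 0)
    crop_low: tuple[int, int, int] = (0, 0, 0)
    crop_high: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        for low, high in ((self.pad_low, self.pad_high), (self.crop_low, self.crop_high)):
            if any(v < 0 for v in low + high):
                raise ValueError("pad/crop counts must be non-negative")
        for ax in range(3):
            if (self.pad_low[ax] + self.pad_high[ax]) and (
                self.crop_low[ax] + self.crop_high[ax]
            ):
                raise ValueError(f"axis {ax}: pad and crop are mutually exclusive")

    def cube_shape(self) -> tuple[int, int, int]:
        return tuple(
            self.resampled_shape[a] + self.pad_low[a] + self.pad_high[a]
            - self.crop_low[a] - self.crop_high[a]
            for a in range(3)
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LabelVolume:
    """Categorical supervision grid: 0 background, 1 pericardium, 2 redundant."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1, 2))):
            raise ValueError(f"label values must be in {{0,1,2}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape


# ---------------------------------------------------------------------------
# separable resampling primitives
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def _resize_axis(a: np.ndarray, n_out: int, axis: int, mode: str) -> np.ndarray:
    """Resize one axis with the pixel-as-cell (align_corners=False) convention."""
    n_in = a.shape[axis]
    if n_in == n_out:
        return a
    if mode == "nearest":
        src = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(np.intp)
        np.clip(src, 0, n_in - 1, out=src)
        return np.take(a, src, axis=axis)
    if mode == "trilinear":
        centers = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        i0 = np.floor(centers).astype(np.intp)
        frac = (centers - i0).astype(a.dtype if a.dtype.kind == "f" else np.float32)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        i0 = np.clip(i0, 0, n_in - 1)
        shape = [1] * a.ndim
        shape[axis] = n_out
        frac = frac.reshape(shape)
        lo = np.take(a, i0, axis=axis)
        hi = np.take(a, i1, axis=axis)
        return lo * (1 - frac) + hi * frac
    raise ValueError(f"unknown interpolation mode {mode!r}")


def _resize(data: np.ndarray, out_shape, mode: str) -> np.ndarray:
    out = np.asarray(data, dtype=np.float32 if mode == "trilinear" else data.dtype)
    for ax in range(3):
        out = _resize_axis(out, int(out_shape[ax]), ax, mode)
    return out


def resample_isotropic(vol, target_spacing: float, mode: str = "trilinear"):
    """Resample to isotropic ``target_spacing`` mm.

    Output shape per axis is round-half-away-from-zero of
    ``native_shape · native_spacing / target_spacing`` (minimum 1). Use
    ``mode="trilinear"`` for images and ``mode="nearest"`` for masks/labels
    (nearest maps {0,1} inputs to {0,1} outputs).
    """
    if not np.isfinite(target_spacing) or target_spacing <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    out_shape = tuple(
        max(1, _round_half_away(n * s / target_spacing))
        for n, s in zip(vol.data.shape, vol.spacing)
    )
    out = _resize(vol.data, out_shape, mode)
    spacing = (float(target_spacing),) * 3
    if isinstance(vol, SegmentationMask):
        return SegmentationMask(out.astype(np.uint8), spacing, vol.origin, vol.axcodes)
    if isinstance(vol, LabelVolume):
        return LabelVolume(out.astype(np.uint8), spacing, vol.axcodes)
    return CTVolume(out, spacing, vol.origin, vol.axcodes)


def pad_crop_center(vol, cube_size: int, fill_value: float = 0.0):
    """Symmetrically pad and/or crop each axis to ``cube_size`` voxels.

    Per axis the low/high counts differ by at most one (extra voxel goes to
    the high side). Returns the fixed-size volume and the
    :class:`GridTransform` recording exactly what was done.
    """
    data = vol.data
    pad_low = [0, 0, 0]
    pad_high = [0, 0, 0]
    crop_low = [0, 0, 0]
    crop_high = [0, 0, 0]
    out = data
    for ax in range(3):
        n = out.shape[ax]
        diff = cube_size - n
        if diff > 0:
            pad_low[ax], pad_high[ax] = diff // 2, diff - diff // 2
        elif diff < 0:
            crop_low[ax], crop_high[ax] = (-diff) // 2, (-diff) - (-diff) // 2
    pads = [(pad_low[a], pad_high[a]) for a in range(3)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, mode="constant", constant_values=fill_value)
    slicer = tuple(
        slice(crop_low[a], out.shape[a] - crop_high[a]) for a in range(3)
    )
    out = out[slicer].copy()
    t = GridTransform(
        native_shape=tuple(data.shape),
        native_spacing=tuple(vol.spacing),
        resampled_shape=tuple(data.shape),
        pad_low=tuple(pad_low), pad_high=tuple(pad_high),
        crop_low=tuple(crop_low), crop_high=tuple(crop_high),
    )
    if isinstance(vol, SegmentationMask):
        return SegmentationMask(out.astype(np.uint8), vol.spacing, vol.origin, vol.axcodes), t
    if isinstance(vol, LabelVolume):
        return LabelVolume(out.astype(np.uint8), vol.spacing, vol.axcodes), t
    return CTVolume(out, vol.spacing, vol.origin, vol.axcodes), t


def clip_normalize(vol: CTVolume, lo: float = -800.0, hi: float = 1200.0) -> CTVolume:
    """Clamp HU to [lo, hi] and rescale linearly to [0, 1]."""
    if lo >= hi:
        raise ValueError(f"clip window requires lo < hi, got [{lo}, {hi}]")
    out = (np.clip(vol.data, lo, hi) - lo) / (hi - lo)
    return CTVolume(out.astype(np.float32), vol.spacing, vol.origin, vol.axcodes)


def inferior_boundary(nz: int, fraction: float) -> int:
    """First slice index NOT in the inferior fraction: ceil(fraction·nz)."""
    return int(math.ceil(fraction * nz))


def make_redundant_class(
    vol: CTVolume, pericardium: SegmentationMask, cfg: PreprocessConfig
) -> LabelVolume:
    """Build the 3-class supervision grid with the auxiliary redundant class.

    Label 1 wherever the pericardium mask is set (pericardium wins ties);
    label 2 for fat-density voxels (``redundant_lo_hu ≤ HU ≤
    redundant_hi_hu``) outside the pericardium in the inferior
    ``inferior_fraction`` of axial slices; 0 elsewhere. Requires canonical
    orientation so "inferior" means low slice index.
    """
    pericardium.check_same_grid(vol)
    hu = vol.data
    nz = hu.shape[2]
    boundary = inferior_boundary(nz, cfg.inferior_fraction)
    labels = np.zeros(hu.shape, dtype=np.uint8)
    in_window = (hu >= cfg.redundant_lo_hu) & (hu <= cfg.redundant_hi_hu)
    in_window[:, :, boundary:] = False
    labels[in_window & (pericardium.data == 0)] = REDUNDANT
    labels[pericardium.data == 1] = PERICARDIUM
    return LabelVolume(labels, vol.spacing, vol.axcodes)


def apply_pipeline(
    vol: CTVolume,
    pericardium: SegmentationMask | None = None,
    cfg: PreprocessConfig | None = None,
):
    """Full forward preprocessing.

    Order: resample (trilinear image / nearest mask) → redundant-class
    labelling on the resampled HU grid → centred pad/crop to
    ``cfg.cube_size`` (image padded with the clip floor, labels with 0) →
    clip + normalise the image to [0, 1].

    Returns ``(image_cube, label_cube_or_None, GridTransform)``.
    """
    cfg = cfg or PreprocessConfig()
    res_img = resample_isotropic(vol, cfg.target_spacing_mm, "trilinear")
    labels = None
    if pericardium is not None:
        pericardium.check_same_grid(vol)
        res_mask = resample_isotropic(pericardium, cfg.target_spacing_mm, "nearest")
        labels = make_redundant_class(res_img, res_mask, cfg)
    img_cube, t = pad_crop_center(res_img, cfg.cube_size, fill_value=cfg.clip_lo_hu)
    t = GridTransform(
        native_shape=tuple(vol.data.shape),
        native_spacing=tuple(vol.spacing),
        resampled_shape=tuple(res_img.data.shape),
        pad_low=t.pad_low, pad_high=t.pad_high,
        crop_low=t.crop_low, crop_high=t.crop_high,
    )
    img_cube = clip_normalize(img_cube, cfg.clip_lo_hu, cfg.clip_hi_hu)
    label_cube = None
    if labels is not None:
        label_cube, _ = pad_crop_center(labels, cfg.cube_size, fill_value=0)
    return img_cube, label_cube, t


def invert_to_native(
    mask_cube: SegmentationMask, t: GridTransform, native: CTVolume
) -> SegmentationMask:
    """Map a cube-grid binary mask back onto the native voxel grid.

    Undoes the pad (trim), undoes the crop (zero-fill), then
    nearest-neighbour resamples to the native shape.
    """
    if tuple(native.data.shape) != tuple(t.native_shape):
        raise GridMismatchError(
            f"native volume shape {native.data.shape} != transform record {t.native_shape}"
        )
    if tuple(mask_cube.data.shape) != t.cube_shape():
        raise GridMismatchError(
            f"cube mask shape {mask_cube.data.shape} != transform cube {t.cube_shape()}"
        )
    data = mask_cube.data
    # undo padding
    slicer = tuple(
        slice(t.pad_low[a], data.shape[a] - t.pad_high[a]) for a in range(3)
    )
    data = data[slicer]
    # undo cropping
    pads = [(t.crop_low[a], t.crop_high[a]) for a in range(3)]
    if any(p != (0, 0) for p in pads):
        data = np.pad(data, pads, mode="constant", constant_values=0)
    assert tuple(data.shape) == tuple(t.resampled_shape)
    out = _resize(data, t.native_shape, "nearest")
    return SegmentationMask(
        out.astype(np.uint8), t.native_spacing, native.origin, native.axcodes
    )
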