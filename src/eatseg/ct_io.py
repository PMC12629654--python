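"""Volumetric CT input/output and orientation handling.

Images are kept in a single canonical orientation so that anatomical
statements like "the inferior 20% of axial slices" are unambiguous
everywhere else in the package: after :func:`canonicalize`, axis 0 runs
left→right (R), axis 1 posterior→anterior (A) and axis 2 inferior→superior
(S), i.e. axial slice index 0 is the most inferior slice.

Intensities are Hounsfield units stored as floating point (interpolation
during resampling produces non-integer values even for integer sources).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
from nibabel import orientations as nio

__all__ = [
    "CANONICAL_AXCODES",
    "CTVolume",
    "SegmentationMask",
    "read_volume",
    "write_volume",
    "write_mask",
    "canonicalize",
]

#: Canonical anatomical axis codes: axis 2 is the inferior→superior axis.
CANONICAL_AXCODES = ("R", "A", "S")


class MetadataError(ValueError):
    """Orientation or spacing metadata is missing or unresolvable."""


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


def _check_grid(data: np.ndarray, spacing) -> None:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if min(data.shape) < 1:
        raise ValueError(f"degenerate volume shape {data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,):
        raise MetadataError(f"spacing must have 3 components, got {spacing}")
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise MetadataError(f"spacing must be strictly positive and finite, got {tuple(spacing)}")


@dataclass
class CTVolume:
    """A 3D CT intensity grid in Hounsfield units.

    Attributes
    ----------
    data : 3D float array, HU
    spacing : (sx, sy, sz) voxel size in mm, all > 0
    origin : physical coordinate of voxel (0, 0, 0), mm
    axcodes : anatomical direction of increasing index on each axis,
        e.g. ``("R", "A", "S")``
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = CANONICAL_AXCODES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        _check_grid(self.data, self.spacing)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axcodes = tuple(self.axcodes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_canonical(self) -> bool:
        return self.axcodes == CANONICAL_AXCODES

    def affine(self) -> np.ndarray:
        """Axis-aligned affine built from axcodes, spacing and origin."""
        return _build_affine(self.spacing, self.origin, self.axcodes)


@dataclass
class SegmentationMask:
    """Binary mask aligned voxel-for-voxel to a :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = CANONICAL_AXCODES

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        _check_grid(arr, self.spacing)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axcodes = tuple(self.axcodes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def affine(self) -> np.ndarray:
        """Axis-aligned affine built from axcodes, spacing and origin."""
        return _build_affine(self.spacing, self.origin, self.axcodes)

    def check_same_grid(self, other) -> None:
        if self.shape != other.data.shape or not np.allclose(
            self.spacing, other.spacing, rtol=0, atol=1e-6
        ):
            raise GridMismatchError(
                f"grids differ: shape {self.shape} vs {other.data.shape}, "
                f"spacing {self.spacing} vs {other.spacing}"
            )


def _build_affine(spacing, origin, axcodes) -> np.ndarray:
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for ax, code in enumerate(axcodes):
        world_ax, sign = _AXCODE_TO_WORLD[code]
        aff[world_ax, ax] = sign * spacing[ax]
    aff[:3, 3] = origin
    return aff


# world axes: 0 = L→R, 1 = P→A, 2 = I→S (RAS+ convention)
_AXCODE_TO_WORLD = {
    "R": (0, +1), "L": (0, -1),
    "A": (1, +1), "P": (1, -1),
    "S": (2, +1), "I": (2, -1),
}
_VALID_CODES = set(_AXCODE_TO_WORLD)


def canonicalize(vol: CTVolume | SegmentationMask):
    """Reorder/flip axes so axis 2 runs inferior→superior (RAS+).

    Voxel values are untouched as a multiset; spacing is permuted
    consistently and the origin is recomputed so physical positions of
    voxels are preserved. Idempotent. Raises :class:`MetadataError` for
    unresolvable axcodes rather than guessing.
    """
    codes = tuple(vol.axcodes)
    if codes == CANONICAL_AXCODES:
        return vol
    if len(codes) != 3 or any(c not in _VALID_CODES for c in codes):
        raise MetadataError(f"unresolvable orientation codes {codes!r}")
    world = [_AXCODE_TO_WORLD[c][0] for c in codes]
    if sorted(world) != [0, 1, 2]:
        raise MetadataError(f"orientation codes {codes!r} do not span three distinct axes")

    aff = vol.affine()
    ornt = nio.ornt_transform(
        nio.axcodes2ornt(codes), nio.axcodes2ornt(CANONICAL_AXCODES)
    )
    new_data = nio.apply_orientation(vol.data, ornt)
    new_aff = aff @ nio.inv_ornt_aff(ornt, vol.data.shape)
    new_spacing = tuple(float(s) for s in nib.affines.voxel_sizes(new_aff))
    new_origin = tuple(float(o) for o in new_aff[:3, 3])
    return replace(
        vol,
        data=np.ascontiguousarray(new_data),
        spacing=new_spacing,
        origin=new_origin,
        axcodes=CANONICAL_AXCODES,
    )


# ---------------------------------------------------------------------------
# NIfTI + DICOM I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> CTVolume:
    """Read a NIfTI file or a single-series DICOM directory as a canonical CTVolume.

    NIfTI intensities pass through nibabel's slope/intercept scaling; DICOM
    stored values are rescaled to HU with RescaleSlope/RescaleIntercept.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file or directory: {path}")
    if os.path.isdir(path):
        return _read_dicom_series(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # corrupt / not a NIfTI
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[:, :, :, 0]
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)  # RAS+
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise MetadataError(f"{path}: invalid voxel spacing {zooms}")
    data = np.asarray(img.get_fdata(dtype=np.float32))
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return CTVolume(data=data, spacing=tuple(float(z) for z in zooms),
                    origin=origin, axcodes=CANONICAL_AXCODES)


def write_volume(vol: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI (int16 when HU are integral and in range)."""
    data = vol.data
    rounded = np.round(data)
    if np.allclose(data, rounded, atol=1e-4) and rounded.min() >= -32768 and rounded.max() <= 32767:
        out = rounded.astype(np.int16)
    else:
        out = data.astype(np.float32)
    _save_nifti(out, vol, path)


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI."""
    _save_nifti(mask.data.astype(np.uint8), mask, path)


def _save_nifti(arr: np.ndarray, vol, path) -> None:
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    img = nib.Nifti1Image(arr, vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)


def read_mask(path) -> SegmentationMask:
    """Read a binary mask NIfTI (values must be exactly {0,1})."""
    vol = read_volume(path)
    return SegmentationMask(
        data=np.round(vol.data).astype(np.uint8),
        spacing=vol.spacing, origin=vol.origin, axcodes=vol.axcodes,
    )


def _read_dicom_series(directory: str) -> CTVolume:
    """Ingest a single axial DICOM series (monotone slice locations).

    Supported geometry is deliberately narrow: one series, axial
    acquisition (ImageOrientationPatient ≈ (1,0,0,0,1,0)), monotone slice
    positions. Anything else should be converted to NIfTI first. Gantry-tilt
    correction is unsupported.
    """
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        if os.path.isdir(f):
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise IOError(f"no readable DICOM images in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", "?") for ds in slices}
    if len(uids) > 1:
        raise MetadataError(f"{directory}: multiple DICOM series found ({len(uids)})")
    ref = slices[0]
    iop = [float(v) for v in getattr(ref, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise MetadataError(
            f"{directory}: only axial series are supported (IOP={iop}); convert to NIfTI first"
        )
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    except AttributeError:
        raise MetadataError(f"{directory}: ImagePositionPatient missing; cannot order slices")
    if len(slices) < 2:
        dz = float(getattr(ref, "SliceThickness", 0) or 0)
        if dz <= 0:
            raise MetadataError(f"{directory}: cannot determine slice spacing")
    else:
        steps = np.diff(zpos)
        if np.any(steps <= 0):
            raise MetadataError(f"{directory}: slice positions are not strictly monotone")
        dz = float(np.mean(steps))
    try:
        ps = [float(v) for v in ref.PixelSpacing]  # (row, col) mm
    except AttributeError:
        raise MetadataError(f"{directory}: PixelSpacing missing")

    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float32) * slope + inter)
    # pixel_array is (row, col) = (y, x); DICOM LPS: +x→Left, +y→Posterior,
    # +z→Superior. Stack as (col, row, slice) = (L, P, S), then canonicalize.
    data = np.stack([p.T for p in planes], axis=2)
    origin = tuple(float(v) for v in ref.ImagePositionPatient)
    vol = CTVolume(
        data=data, spacing=(ps[1], ps[0], dz), origin=origin, axcodes=("L", "P", "S")
    )
    return canonicalize(vol)
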