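"""Synthetic thorax-like NCCT phantoms with analytically known EAT volume.

The phantom emulates the HU landscape a cardiac calcium-scoring scan
presents to the pipeline: lung/air background (≈ −800 HU), a soft-tissue
mediastinum (≈ 40 HU), a closed ellipsoidal pericardial sac bounded by a
thin fibrous line (≈ 30 HU), an epicardial fat compartment (≈ −100 HU)
inside the sac, and optional paracardial fat *outside* the sac with the
same attenuation — the feature that makes naive global HU thresholding
overestimate EAT. A small calcified focus (> 130 HU) can be embedded in
the myocardial core.

Geometry, in normalised ellipsoid coordinates ρ = |((x−c)/a)| of the sac:

* sac interior: ρ ≤ 1 (this is the ground-truth pericardium mask);
* fat sub-shell: ρ ∈ [ρ_f(ζ), 1] with ρ_f²(ζ) = 1 − f(ζ)·(1−λ²), where
  λ is the inner (myocardial) scale and f(ζ) the fraction of the shell
  cross-section filled with fat at normalised height ζ;
* f(ζ) ramps linearly from ``fat_fraction_equator`` at/above the equator
  to ``fat_fraction_apex`` at the inferior pole, so the apical cap is
  fat-dominant — reproducing the inferior-heavy EAT distribution in which
  the most inferior ~20% of EAT slices hold over 20% of total volume;
* pericardial line: thin shell ρ ∈ (1, 1+δ], whose contrast fades toward
  the apex (the clinically difficult region).

The analytic EAT volume is an exact 1D integral of per-slice annulus
areas, V = πabc ∫ min(1−ζ², f(ζ)(1−λ²)) dζ — an oracle fully independent
of the voxel rendering, which uses supersampled occupancy instead.
Gaussian HU noise is added only after all truth quantities are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .contour_interp import SparseAnnotation
from .ct_io import CTVolume, SegmentationMask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate",
    "generate_dataset",
    "sparse_annotation_from_truth",
    "analytic_eat_volume_cm3",
    "DEFAULT_JITTER",
]

# material ids in PhantomTruth.material_map
LUNG, SOFT, FAT, LINE, CALCIUM, PARA_FAT = 0, 1, 2, 3, 4, 5

_DEFAULT_HU = {
    "lung": -800.0,
    "soft": 40.0,
    "fat": -100.0,
    "line": 30.0,
    "calcium": 300.0,
}


class PhantomSpecError(ValueError):
    """Phantom geometry inconsistent with the requested grid."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic thorax volume (all lengths in mm)."""

    shape: tuple[int, int, int] = (96, 96, 84)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    heart_center: tuple[float, float, float] | None = None
    heart_axes: tuple[float, float, float] = (50.0, 45.0, 55.0)
    pericardium_thickness: float = 2.0
    inner_scale: float = 0.75
    fat_fraction_equator: float = 0.30
    fat_fraction_apex: float = 0.95
    paracardial_fat: bool = True
    paracardial_radius: float = 20.0
    paracardial_gap: float = 3.0
    calcium: bool = True
    calcium_radius: float = 4.0
    hu_means: dict = field(default_factory=lambda: dict(_DEFAULT_HU))
    line_apex_fade: float = 0.6
    body_margin: float = 22.0
    noise_sd: float = 10.0
    supersample: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.spacing, (int, float)):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)
        self.shape = tuple(int(n) for n in self.shape)
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        if self.heart_center is None:
            self.heart_center = tuple(e / 2.0 for e in extent)
        self.heart_center = tuple(float(c) for c in self.heart_center)
        hu = dict(_DEFAULT_HU)
        hu.update(self.hu_means)
        self.hu_means = hu
        if not (0.0 < self.inner_scale < 1.0):
            raise PhantomSpecError("inner_scale must lie in (0, 1)")
        for name in ("fat_fraction_equator", "fat_fraction_apex"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PhantomSpecError(f"{name} must lie in [0, 1]")
        if self.fat_fraction_apex < self.fat_fraction_equator:
            raise PhantomSpecError("fat_fraction_apex must be >= fat_fraction_equator")
        fat_hu = self.hu_means["fat"]
        if not (-190.0 < fat_hu < -30.0) or not (-198.0 < fat_hu < -80.0):
            raise PhantomSpecError(
                f"fat HU mean {fat_hu} must lie inside both the adipose window "
                "(-190, -30) and the redundant-class window (-198, -80)"
            )
        if self.supersample < 1:
            raise PhantomSpecError("supersample must be >= 1")
        t = self.pericardium_thickness
        for ax in range(3):
            lo = self.heart_center[ax] - self.heart_axes[ax] - t
            hi = self.heart_center[ax] + self.heart_axes[ax] + t
            if lo < 0 or hi > extent[ax]:
                raise PhantomSpecError(
                    f"heart (axis {ax}: {lo:.1f}..{hi:.1f} mm) exceeds the grid "
                    f"extent 0..{extent[ax]:.1f} mm"
                )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom."""

    pericardium_mask: SegmentationMask
    eat_mask: SegmentationMask
    eat_volume_cm3: float          # analytic, pre-noise, pre-voxelisation
    paracardial_volume_cm3: float  # analytic volume of extra-pericardial fat
    material_map: np.ndarray       # per-voxel majority material id
    spec: PhantomSpec


def _fat_fraction(zeta: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Shell fat fraction as a function of normalised height ζ ∈ [−1, 1]."""
    ramp = np.clip(-zeta, 0.0, 1.0)
    return spec.fat_fraction_equator + (
        spec.fat_fraction_apex - spec.fat_fraction_equator
    ) * ramp


def analytic_eat_volume_cm3(spec: PhantomSpec, n_quad: int = 100_001) -> float:
    """Exact epicardial fat volume by 1D quadrature of per-slice areas."""
    a, b, c = spec.heart_axes
    lam2 = spec.inner_scale ** 2
    zeta = np.linspace(-1.0, 1.0, n_quad)
    area = np.minimum(1.0 - zeta**2, _fat_fraction(zeta, spec) * (1.0 - lam2))
    integral = np.trapezoid(area, zeta)
    return math.pi * a * b * c * integral / 1000.0


def _paracardial_center(spec: PhantomSpec) -> tuple[float, float, float]:
    cx, cy, cz = spec.heart_center
    b = spec.heart_axes[1]
    off = b + spec.pericardium_thickness + spec.paracardial_gap + spec.paracardial_radius
    return (cx, cy + off, cz)


def _calcium_center(spec: PhantomSpec) -> tuple[float, float, float]:
    cx, cy, cz = spec.heart_center
    a, _, c = spec.heart_axes
    return (cx + 0.35 * a, cy, cz + 0.15 * c)


def _evaluate(spec: PhantomSpec, x: np.ndarray, y: np.ndarray, z: float):
    """HU and material id at physical points (x broadcast × y broadcast, z).

    Priority: sac interior (fat/core) > pericardial line > calcium >
    paracardial fat > mediastinal soft tissue > lung.
    """
    hu_m = spec.hu_means
    cx, cy, cz = spec.heart_center
    a, b, c = spec.heart_axes
    u = (x - cx) / a
    v = (y - cy) / b
    w = (z - cz) / c
    rho2 = u * u + v * v + w * w
    t_n = spec.pericardium_thickness / (a * b * c) ** (1.0 / 3.0)
    lam2 = spec.inner_scale ** 2

    zeta = np.clip(w, -1.0, 1.0)
    f = _fat_fraction(zeta, spec)
    rho_f2 = 1.0 - f * (1.0 - lam2)

    hu = np.full(np.broadcast_shapes(u.shape, v.shape), hu_m["lung"], dtype=np.float32)
    mat = np.zeros(hu.shape, dtype=np.int8)

    # mediastinal soft tissue body
    bm = spec.body_margin
    body_b = b + bm + (
        2.0 * spec.paracardial_radius + spec.paracardial_gap
        if spec.paracardial_fat else 0.0
    )
    body = (
        ((x - cx) / (a + bm)) ** 2
        + ((y - cy) / body_b) ** 2
        + ((z - cz) / (c + bm * 0.7)) ** 2
    ) <= 1.0
    hu[body] = hu_m["soft"]
    mat[body] = SOFT

    if spec.paracardial_fat:
        px, py, pz = _paracardial_center(spec)
        r = spec.paracardial_radius
        para = ((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2) <= r * r
        para &= rho2 > (1.0 + t_n) ** 2  # never bleed inside the sac/line
        hu[para] = hu_m["fat"]
        mat[para] = PARA_FAT

    if spec.calcium:
        qx, qy, qz = _calcium_center(spec)
        r = spec.calcium_radius
        cal = ((x - qx) ** 2 + (y - qy) ** 2 + (z - qz) ** 2) <= r * r
        hu[cal] = hu_m["calcium"]
        mat[cal] = CALCIUM

    line = (rho2 > 1.0) & (rho2 <= (1.0 + t_n) ** 2)
    # fading apical contrast: line HU drifts toward soft tissue below equator
    fade = spec.line_apex_fade * np.clip(-zeta, 0.0, 1.0)
    line_hu = hu_m["line"] + (hu_m["soft"] - hu_m["line"]) * fade
    hu[line] = np.broadcast_to(line_hu, hu.shape)[line]
    mat[line] = LINE

    sac = rho2 <= 1.0
    core = sac & (rho2 < rho_f2)
    fat = sac & ~core
    hu[core] = hu_m["soft"]
    mat[core] = SOFT
    hu[fat] = hu_m["fat"]
    mat[fat] = FAT
    return hu, mat, sac, fat


def generate(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render one phantom by supersampled occupancy.

    Each voxel is subdivided into ``supersample³`` sample points; the voxel
    HU is the mean sample HU (a partial-volume model), a truth mask bit is
    set when the corresponding occupancy is ≥ 0.5, and the material map
    holds the per-voxel majority material. Deterministic for a fixed seed.
    """
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    ss = spec.supersample

    sub = (np.arange(ss) + 0.5) / ss
    xs = (np.arange(nx)[:, None] + sub[None, :]).reshape(-1) * sx  # (nx*ss,)
    ys = (np.arange(ny)[:, None] + sub[None, :]).reshape(-1) * sy

    X = xs[:, None].astype(np.float64)
    Y = ys[None, :].astype(np.float64)

    hu_out = np.empty(spec.shape, dtype=np.float32)
    sac_occ = np.zeros(spec.shape, dtype=np.float32)
    fat_occ = np.zeros(spec.shape, dtype=np.float32)
    n_mats = 6
    inv = 1.0 / (ss * ss * ss)

    for k in range(nz):
        hu_acc = np.zeros((nx, ny), dtype=np.float32)
        sac_acc = np.zeros((nx, ny), dtype=np.float32)
        fat_acc = np.zeros((nx, ny), dtype=np.float32)
        mat_counts = np.zeros((n_mats, nx, ny), dtype=np.int32)
        for j in range(ss):
            z = (k + sub[j]) * sz
            hu, mat, sac, fat = _evaluate(spec, X, Y, z)
            hu4 = hu.reshape(nx, ss, ny, ss)
            hu_acc += hu4.mean(axis=(1, 3))
            sac_acc += sac.reshape(nx, ss, ny, ss).mean(axis=(1, 3))
            fat_acc += fat.reshape(nx, ss, ny, ss).mean(axis=(1, 3))
            m4 = mat.reshape(nx, ss, ny, ss)
            for mid in range(n_mats):
                mat_counts[mid] += (m4 == mid).sum(axis=(1, 3), dtype=np.int32)
        hu_out[:, :, k] = hu_acc / ss
        sac_occ[:, :, k] = sac_acc / ss
        fat_occ[:, :, k] = fat_acc / ss
        if k == 0:
            material_map = np.empty(spec.shape, dtype=np.int8)
        material_map[:, :, k] = mat_counts.argmax(axis=0)

    peri_mask = SegmentationMask((sac_occ >= 0.5).astype(np.uint8), spec.spacing)
    eat_mask = SegmentationMask((fat_occ >= 0.5).astype(np.uint8), spec.spacing)

    truth = PhantomTruth(
        pericardium_mask=peri_mask,
        eat_mask=eat_mask,
        eat_volume_cm3=analytic_eat_volume_cm3(spec),
        paracardial_volume_cm3=(
            4.0 / 3.0 * math.pi * spec.paracardial_radius ** 3 / 1000.0
            if spec.paracardial_fat else 0.0
        ),
        material_map=material_map,
        spec=spec,
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu_out = hu_out + rng.normal(0.0, spec.noise_sd, size=hu_out.shape).astype(
            np.float32
        )
    vol = CTVolume(hu_out, spec.spacing)
    return vol, truth


#: Default per-case jitter ranges for :func:`generate_dataset`. Heart size
#: scales volumes by ≈ 0.55–1.5×, which together with the fat-fraction
#: ranges spans roughly 40–250 cm³ of EAT, mirroring the clinical spread.
DEFAULT_JITTER = {
    "heart_scale": (0.82, 1.15),
    "fat_fraction_equator": (0.20, 0.40),
    "fat_fraction_apex": (0.85, 1.00),
    "noise_sd": (5.0, 12.0),
    "center_jitter_mm": 6.0,
}


def generate_dataset(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: dict | None = None,
    seed: int = 0,
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Reproducibly draw ``n`` phantoms with jittered geometry.

    Per-case heart size, fat fractions, noise level and heart position are
    drawn uniformly from the ``jitter`` ranges (see :data:`DEFAULT_JITTER`).
    The same ``(n, base_spec, jitter, seed)`` always yields the same list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    jit = dict(DEFAULT_JITTER)
    jit.update(jitter or {})
    for key in ("heart_scale", "fat_fraction_equator", "fat_fraction_apex", "noise_sd"):
        lo, hi = jit[key]
        if hi < lo:
            raise PhantomSpecError(f"empty jitter range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        scale = rng.uniform(*jit["heart_scale"])
        f_eq = rng.uniform(*jit["fat_fraction_equator"])
        f_ap = rng.uniform(*jit["fat_fraction_apex"])
        f_ap = max(f_ap, f_eq)
        noise = rng.uniform(*jit["noise_sd"])
        cj = jit["center_jitter_mm"]
        offset = rng.uniform(-cj, cj, size=3) if cj > 0 else np.zeros(3)
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            heart_axes=tuple(ax * scale for ax in base.heart_axes),
            heart_center=tuple(c + o for c, o in zip(base.heart_center, offset)),
            fat_fraction_equator=f_eq,
            fat_fraction_apex=f_ap,
            noise_sd=noise,
            seed=case_seed,
        )
        out.append(generate(spec))
    return out


def sparse_annotation_from_truth(truth: PhantomTruth, step: int = 5) -> SparseAnnotation:
    """Emulate every-``step``-th-slice manual annotation of the truth mask.

    Keeps every ``step``-th slice over the mask's nonempty z-extent plus
    the first and last nonempty slices, the way a reader anchors the
    inferior and superior heart limits.
    """
    mask = truth.pericardium_mask
    nonempty = np.flatnonzero(mask.data.any(axis=(0, 1)))
    if nonempty.size == 0:
        raise ValueError("truth pericardium mask is empty")
    z0, z1 = int(nonempty[0]), int(nonempty[-1])
    zs = sorted(set(range(z0, z1 + 1, step)) | {z0, z1})
    slices = {z: mask.data[:, :, z].astype(bool) for z in zs}
    return SparseAnnotation(
        slices=slices, shape=mask.data.shape, spacing=mask.spacing, bounds=(z0, z1)
    )
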