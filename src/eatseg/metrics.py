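"""Agreement and accuracy statistics for method comparison.

Covers the standard suite used to compare an automated volumetric
measurement against a reference reader: Dice similarity coefficient,
relative volume error, Pearson correlation, Bland–Altman bias and 95%
limits of agreement, and the two-way random-effects absolute-agreement
single-measure intraclass correlation ICC(2,1) with its F-based confidence
interval (McGraw & Wong conventions).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .ct_io import GridMismatchError

__all__ = [
    "AgreementReport",
    "dice",
    "relative_volume_error",
    "bland_altman",
    "pearson",
    "icc_absolute",
    "bsa_index",
    "evaluate_pairs",
    "bland_altman_plot",
]


@dataclass
class AgreementReport:
    """Summary agreement statistics for paired volume measurements (cm³)."""

    n: int
    pearson_r: float
    bias_cm3: float
    loa_low_cm3: float
    loa_high_cm3: float
    mean_rel_vol_err_pct: float
    sd_rel_vol_err_pct: float
    icc: float
    icc_ci: tuple[float, float]
    mean_dice: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["icc_ci"] = list(self.icc_ci)
        return d


def dice(pred, ref) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Accepts binary arrays or SegmentationMask objects on the same grid.
    Both-empty masks score 1.0 (perfect agreement on absence).
    """
    a = np.asarray(getattr(pred, "data", pred)).astype(bool)
    b = np.asarray(getattr(ref, "data", ref)).astype(bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sp = getattr(pred, "spacing", None)
    sr = getattr(ref, "spacing", None)
    if sp is not None and sr is not None and not np.allclose(sp, sr, atol=1e-6):
        raise GridMismatchError(f"mask spacings differ: {sp} vs {sr}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def relative_volume_error(v_pred: float, v_ref: float) -> float:
    """Relative volume error in percent: 100·|V_pred − V_ref| / V_ref."""
    if not v_ref > 0:
        raise ValueError(f"reference volume must be > 0, got {v_ref}")
    return 100.0 * abs(v_pred - v_ref) / v_ref


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland–Altman bias and 95% limits of agreement.

    Differences are ``x − y`` (convention: x = predicted, y = reference, so
    a method that underestimates yields a negative bias). Limits are
    ``bias ± 1.96·sd`` with the sample (n−1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need two equal-length 1D arrays, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)


def icc_absolute(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``x`` and ``y`` are the two raters' measurements over the same n
    subjects. Returns ``(icc, ci_low, ci_high)`` with the 1−alpha
    confidence interval from the standard F-distribution construction.
    Degenerate (all-equal) data returns (1.0, 1.0, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1D arrays")
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 paired measurements, got {n}")
    data = np.stack([x, y], axis=1)  # n subjects × k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0):
        return 1.0, 1.0, 1.0
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1)
    if mse == 0 and msc == 0:
        return float(icc), float(icc), float(icc)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), float(icc), float(icc)
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den if v_den > 0 else 1.0
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(lo), float(hi)


def bsa_index(volume_cm3: float, bsa_m2: float) -> float:
    """Volume indexed to body surface area, cm³/m²."""
    if not bsa_m2 > 0:
        raise ValueError(f"BSA must be > 0 m², got {bsa_m2}")
    return volume_cm3 / bsa_m2


def evaluate_pairs(v_pred, v_ref, dices=None) -> AgreementReport:
    """Full agreement report for paired predicted/reference volumes (cm³)."""
    v_pred = np.asarray(v_pred, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    bias, lo, hi = bland_altman(v_pred, v_ref)
    rel = np.array([relative_volume_error(p, r) for p, r in zip(v_pred, v_ref)])
    try:
        r = pearson(v_pred, v_ref)
    except ValueError:
        r = float("nan")
    try:
        icc, ci_lo, ci_hi = icc_absolute(v_pred, v_ref)
    except ValueError:
        icc, ci_lo, ci_hi = float("nan"), float("nan"), float("nan")
    mean_dice = None
    if dices is not None and len(dices):
        mean_dice = float(np.mean(dices))
    return AgreementReport(
        n=int(v_pred.size),
        pearson_r=r,
        bias_cm3=bias,
        loa_low_cm3=lo,
        loa_high_cm3=hi,
        mean_rel_vol_err_pct=float(rel.mean()),
        sd_rel_vol_err_pct=float(rel.std(ddof=1)) if rel.size > 1 else 0.0,
        icc=icc,
        icc_ci=(ci_lo, ci_hi),
        mean_dice=mean_dice,
    )


def bland_altman_plot(v_pred, v_ref, path, title="Bland–Altman") -> None:
    """Scatter of difference vs mean with bias and 95% limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v_pred = np.asarray(v_pred, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    bias, lo, hi = bland_altman(v_pred, v_ref)
    mean = (v_pred + v_ref) / 2.0
    diff = v_pred - v_ref
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, alpha=0.7)
    for val, style, label in (
        (bias, "-", f"bias {bias:.1f}"),
        (lo, "--", f"LoA {lo:.1f}"),
        (hi, "--", f"LoA {hi:.1f}"),
    ):
        ax.axhline(val, linestyle=style, color="k", linewidth=1)
        ax.annotate(label, xy=(1.0, val), xycoords=("axes fraction", "data"),
                    fontsize=8, ha="right", va="bottom")
    ax.set_xlabel("mean of methods (cm³)")
    ax.set_ylabel("difference, predicted − reference (cm³)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
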