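"""Fixed/relative grey-value histograms and bleach-contrast statistics.

A 256-class whole-stack grey-value frequency distribution can be built two
ways.  A *fixed* histogram spans a constant global range (x_max chosen once
for the whole experiment), so a multiplicative intensity loss compresses
the distribution toward class 0 (a left shift).  A *relative* histogram
spans each stack's own min-max range, so an exact multiplicative loss
leaves the frequency vector unchanged.  Global thresholding reads the
relative shape, which is why threshold-based object quantities survive
photobleaching while the fixed-range picture visibly decays.

The statistics here quantify that contrast: a log10-log10 regression of
late-timepoint mean class frequencies on early ones (slope 1 means no
distributional change), an extra-sum-of-squares F-test of slope = 1,
area-under-curve differences between fitted frequency curves, the class
position of a threshold inside a histogram, and the correlation between
normalised thresholds and normalised fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import UnivariateSpline

__all__ = [
    "GreyHistogram",
    "FrequencyRegression",
    "DeltaArea",
    "grey_histogram",
    "log_frequency_regression",
    "delta_auc",
    "threshold_class_position",
    "threshold_bleach_correlation",
]

N_BINS = 256
FIXED_XMAX_PROCESSED = 30000.0
FIXED_XMAX_ORIGINAL = 7300.0


@dataclass
class GreyHistogram:
    mode: str                       # "fixed" or "relative"
    x_min: float
    x_max: float
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} classes")
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")

    @property
    def bin_width(self) -> float:
        return (self.x_max - self.x_min) / N_BINS

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty histogram")
        return self.counts / total


def grey_histogram(
    stack: np.ndarray,
    mode: str = "relative",
    x_max_fixed: float = FIXED_XMAX_PROCESSED,
    x_min: float = 0.0,
) -> GreyHistogram:
    """Whole-stack 256-class histogram in fixed or relative mode.

    Relative mode sets x_max to the stack maximum; fixed mode uses
    ``x_max_fixed`` and accumulates out-of-range values in the top class.
    """
    stack = np.asarray(stack)
    if stack.size == 0:
        raise ValueError("empty stack")
    if mode == "relative":
        x_max = float(stack.max())
        if x_max <= x_min:
            x_max = x_min + 1.0     # constant stack: everything in class 0
    elif mode == "fixed":
        x_max = float(x_max_fixed)
        if x_max <= 0:
            raise ValueError("x_max must be positive")
    else:
        raise ValueError(f"unknown histogram mode {mode!r}")
    width = (x_max - x_min) / N_BINS
    idx = np.floor((stack.ravel().astype(np.float64) - x_min) / width).astype(np.int64)
    np.clip(idx, 0, N_BINS - 1, out=idx)
    counts = np.bincount(idx, minlength=N_BINS)
    return GreyHistogram(mode=mode, x_min=x_min, x_max=x_max, counts=counts)


@dataclass
class FrequencyRegression:
    slope: float
    intercept: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    n_bins_used: int
    excluded_bins: int


def log_frequency_regression(
    freq_early: np.ndarray, freq_late: np.ndarray
) -> FrequencyRegression:
    """OLS of log10 late frequencies on log10 early frequencies, F-test b=1.

    Classes where either mean frequency is zero are excluded (their log is
    undefined).  The extra-sum-of-squares F statistic compares the free
    two-parameter fit against the slope-1 model (intercept still free):
    F = (RSS0 - RSS1) / (RSS1 / (n - 2)) with 1 and n-2 degrees of freedom.
    """
    x_all = np.asarray(freq_early, dtype=np.float64)
    y_all = np.asarray(freq_late, dtype=np.float64)
    if x_all.shape != y_all.shape:
        raise ValueError("frequency vectors must share shape")
    keep = (x_all > 0) & (y_all > 0)
    n = int(keep.sum())
    if n < 3:
        raise ValueError("fewer than 3 usable (non-zero) classes")
    x = np.log10(x_all[keep])
    y = np.log10(y_all[keep])

    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    rss1 = float(np.sum((y - slope * x - intercept) ** 2))

    a0 = ym - xm                    # slope fixed at 1, intercept free
    rss0 = float(np.sum((y - x - a0) ** 2))

    df_den = n - 2
    extra = max(rss0 - rss1, 0.0)
    if rss1 > 1e-300:
        f_stat = extra / (rss1 / df_den)
    else:
        f_stat = 0.0 if extra < 1e-300 else np.inf   # perfect fit either way
    p = float(stats.f.sf(f_stat, 1, df_den))
    return FrequencyRegression(
        slope=float(slope),
        intercept=float(intercept),
        f_statistic=float(f_stat),
        df_num=1,
        df_den=df_den,
        p_value=p,
        n_bins_used=n,
        excluded_bins=int((~keep).sum()),
    )


@dataclass
class DeltaArea:
    area_a: float
    area_b: float
    delta_area: float               # area_a - area_b, exactly
    percent_difference: float       # (area_b - area_a) / area_a * 100


def _fitted_curve_area(
    hist: GreyHistogram, smoothing: Optional[float], n_eval: int
) -> float:
    freq = hist.frequencies
    classes = np.arange(N_BINS, dtype=np.float64)
    keep = freq > 0
    if keep.sum() < 4:
        raise ValueError("too few non-zero classes to fit a curve")
    x = classes[keep]
    y = np.log10(freq[keep])
    s = smoothing if smoothing is not None else len(x) * 0.05
    try:
        spline = UnivariateSpline(x, y, k=3, s=s)
    except Exception as exc:        # pragma: no cover - scipy failure path
        raise ValueError(f"curve fit did not converge: {exc}") from exc
    grid = np.linspace(x.min(), x.max(), n_eval)
    curve = 10.0 ** spline(grid)
    return float(np.trapezoid(curve, grid))


def delta_auc(
    hist_a: GreyHistogram,
    hist_b: GreyHistogram,
    smoothing: Optional[float] = None,
    n_eval: int = 2048,
) -> DeltaArea:
    """Difference in area under fitted frequency curves (a minus b).

    Each distribution is fitted with a cubic smoothing spline in
    log10-frequency space over its non-zero classes and integrated
    numerically over the class axis.  The sign convention reports
    ``delta_area = area_a - area_b`` (early minus late), and the percent
    difference of b relative to a.
    """
    if hist_a.mode != hist_b.mode:
        raise ValueError("histograms must share mode")
    area_a = _fitted_curve_area(hist_a, smoothing, n_eval)
    area_b = _fitted_curve_area(hist_b, smoothing, n_eval)
    delta = area_a - area_b
    return DeltaArea(
        area_a=area_a,
        area_b=area_b,
        delta_area=delta,
        percent_difference=(area_b - area_a) / area_a * 100.0,
    )


def threshold_class_position(threshold: float, hist: GreyHistogram) -> int:
    """Class index (0-255) containing a grey value; exact bin edges round up.

    Values outside [x_min, x_max] are clamped (with a warning).
    """
    import warnings

    t = float(threshold)
    if t < hist.x_min or t > hist.x_max:
        warnings.warn("threshold outside histogram range; clamping", stacklevel=2)
        t = min(max(t, hist.x_min), hist.x_max)
    idx = int(np.floor((t - hist.x_min) / hist.bin_width))
    return min(max(idx, 0), N_BINS - 1)


def threshold_bleach_correlation(
    normalised_thresholds: Sequence[float],
    normalised_intensities: Sequence[float],
):
    """Pearson and Spearman correlation of threshold vs fluorescence ratios.

    Both series are late/early ratios, one pair per division.  Returns a
    dict with r, p for both statistics and the least-squares line.
    """
    t = np.asarray(normalised_thresholds, dtype=np.float64)
    f = np.asarray(normalised_intensities, dtype=np.float64)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("paired 1-D series required")
    if len(t) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(t) == 0 or np.ptp(f) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    pear = stats.pearsonr(f, t)
    spear = stats.spearmanr(f, t)
    slope, intercept = np.polyfit(f, t, 1)
    return {
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
        "slope": float(slope),
        "intercept": float(intercept),
        "n": int(len(t)),
    }
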