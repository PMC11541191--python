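"""Photobleaching traces, decay fitting and quantity-invariance statistics.

Fluorescence quantity is measured as integrated density (mean grey value
times area = sum of pixel values) inside per-slice cell contours, summed
over slices, one value per timepoint, normalised to the first timepoint.
Photobleaching makes this trace decay approximately linearly; a
least-squares line gives the decay rate per minute.  The headline analysis
compares, across many divisions, late/early ratios of (i) integrated
density along a multi-step timeseries, (ii) integrated density with only
two acquisitions, and (iii) globally-thresholded segmented quantity: the
first drops with bleaching while the other two stay centred at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rois import ROISet

__all__ = [
    "BleachSeries",
    "integrated_density",
    "integrated_density_trace",
    "fit_decay",
    "per_step_to_per_minute",
    "invariance_tests",
    "significance_stars",
    "compare_threshold_algorithms",
]

_STAR_CUTPOINTS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class BleachSeries:
    timepoints_min: np.ndarray
    integrated_density: np.ndarray
    normalised: np.ndarray = field(init=False)
    interval_s: float = 60.0

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=np.float64)
        self.integrated_density = np.asarray(self.integrated_density, dtype=np.float64)
        if self.integrated_density[0] == 0:
            raise ValueError("first-timepoint integrated density is zero")
        self.normalised = self.integrated_density / self.integrated_density[0]

    @property
    def max_consecutive_fluctuation(self) -> float:
        r = self.normalised
        return float(np.max(np.abs(np.diff(r) / r[:-1]))) if len(r) > 1 else 0.0


def integrated_density(volume: np.ndarray, rois: ROISet) -> float:
    """Sum of (mean grey x area) over per-slice ROIs = sum of pixels inside."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("need a (z, y, x) volume")
    total = 0.0
    for z, polys in rois.polygons.items():
        if not polys or not (0 <= z < volume.shape[0]):
            continue
        mask = rois.slice_mask(z, volume.shape[1:])
        total += float(volume[z][mask].sum())
    return total


def integrated_density_trace(
    volumes: Sequence[np.ndarray],
    rois_per_timepoint: Sequence[Optional[ROISet]],
    interval_s: float = 60.0,
) -> BleachSeries:
    """Per-timepoint integrated density inside cell ROIs, normalised to t=0."""
    if len(volumes) != len(rois_per_timepoint):
        raise ValueError("need one ROI set per timepoint")
    dens = []
    for t, (vol, rois) in enumerate(zip(volumes, rois_per_timepoint)):
        if rois is None:
            raise ValueError(f"missing ROI for timepoint {t}")
        dens.append(integrated_density(vol, rois))
    times = np.arange(len(volumes)) * interval_s / 60.0
    return BleachSeries(
        timepoints_min=times, integrated_density=np.asarray(dens), interval_s=interval_s
    )


def per_step_to_per_minute(slope_per_step: float, interval_s: float) -> float:
    """Convert a per-acquisition-step slope to a per-minute rate."""
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    return slope_per_step * 60.0 / interval_s


@dataclass
class DecayFit:
    slope_per_min: float
    intercept: float
    ci95: tuple[float, float]
    rate_percent_per_min: float     # positive decay percentage
    r_squared: float


def fit_decay(series: BleachSeries) -> DecayFit:
    """OLS line through the normalised trace vs time in minutes."""
    t = series.timepoints_min
    y = series.normalised
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    n = len(t)
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    slope = float(np.sum((t - tm) * (y - ym)) / sxx)
    intercept = ym - slope * tm
    resid = y - (slope * t + intercept)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - ym) ** 2))
    se = np.sqrt(rss / (n - 2) / sxx) if n > 2 else 0.0
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (slope - tcrit * se, slope + tcrit * se)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return DecayFit(
        slope_per_min=slope,
        intercept=float(intercept),
        ci95=(float(ci[0]), float(ci[1])),
        rate_percent_per_min=-slope * 100.0,
        r_squared=float(r2),
    )


def significance_stars(p: Optional[float]) -> str:
    if p is None or np.isnan(p):
        return "n/a"
    stars = sum(p <= c for c in _STAR_CUTPOINTS)
    return "*" * stars if stars else "ns"


def invariance_tests(values: Sequence[float], popmean: float = 1.0) -> dict:
    """One-sample test of normalised quantities against 1.0.

    Normality is screened with Shapiro-Wilk; a normal-looking sample gets a
    one-sample t test, otherwise a one-sample Wilcoxon signed-rank test.
    Degenerate all-identical samples are reported without a p value.
    """
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    out = {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "median": float(np.median(v)),
        "popmean": popmean,
    }
    if np.ptp(v) == 0:
        out.update(
            test="degenerate",
            p_value=None,
            statistic=None,
            stars="n/a",
            verdict="no change" if v[0] == popmean else "constant offset",
        )
        return out
    sw_stat, sw_p = stats.shapiro(v)
    out["shapiro_p"] = float(sw_p)
    if sw_p >= 0.05:
        res = stats.ttest_1samp(v, popmean)
        out.update(test="t", statistic=float(res.statistic), p_value=float(res.pvalue))
    else:
        res = stats.wilcoxon(v - popmean)
        out.update(
            test="wilcoxon", statistic=float(res.statistic), p_value=float(res.pvalue)
        )
    out["stars"] = significance_stars(out["p_value"])
    out["verdict"] = (
        "significant change" if out["p_value"] <= 0.05 else "no significant change"
    )
    return out


def compare_threshold_algorithms(
    stack_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    algorithms: Sequence[str] = ("isodata", "imagej_default", "otsu"),
) -> dict:
    """Per-algorithm early quantities and late/early ratios across divisions.

    Segments each (early, late) stack pair with each global-threshold
    algorithm, collects foreground counts, and compares algorithms with an
    omnibus Kruskal-Wallis test on the early quantities plus pairwise
    Mann-Whitney tests corrected by the two-stage
    Benjamini-Krieger-Yekutieli FDR procedure.  Per-item algorithm failures
    (e.g. a constant sub-image) are recorded, not fatal.
    """
    from .segmentation import global_threshold

    if len(algorithms) < 2:
        raise ValueError("need at least 2 algorithms to compare")
    rows = []
    for i, (early, late) in enumerate(stack_pairs):
        for alg in algorithms:
            row = {"pair": i, "algorithm": alg}
            try:
                te = global_threshold(early, algorithm=alg)
                tl = global_threshold(late, algorithm=alg)
                qe = int(np.count_nonzero(early > te.value))
                ql = int(np.count_nonzero(late > tl.value))
                row.update(
                    quantity_early=qe,
                    quantity_late=ql,
                    ratio=ql / qe if qe else np.nan,
                    error=None,
                )
            except ValueError as exc:
                row.update(
                    quantity_early=np.nan, quantity_late=np.nan, ratio=np.nan,
                    error=str(exc),
                )
            rows.append(row)
    table = pd.DataFrame(rows)

    groups = [
        table.loc[table.algorithm == alg, "quantity_early"].dropna().to_numpy()
        for alg in algorithms
    ]
    usable = [g for g in groups if len(g) >= 2]
    if len(usable) >= 2 and np.ptp(np.concatenate(usable)) > 0:
        kw = stats.kruskal(*usable)
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    else:
        kw_stat, kw_p = float("nan"), float("nan")

    pair_names, pair_ps = [], []
    for a in range(len(algorithms)):
        for b in range(a + 1, len(algorithms)):
            ga, gb = groups[a], groups[b]
            if len(ga) >= 2 and len(gb) >= 2:
                mw = stats.mannwhitneyu(ga, gb, alternative="two-sided")
                pair_names.append(f"{algorithms[a]} vs {algorithms[b]}")
                pair_ps.append(float(mw.pvalue))
    if pair_ps:
        reject, p_adj, *_ = multipletests(pair_ps, alpha=0.05, method="fdr_tsbky")
        pairwise = {
            name: {"p_raw": p, "p_adj": float(pa), "significant": bool(r)}
            for name, p, pa, r in zip(pair_names, pair_ps, p_adj, reject)
        }
    else:
        pairwise = {}
    return {
        "table": table,
        "kruskal_statistic": kw_stat,
        "kruskal_p": kw_p,
        "pairwise": pairwise,
    }
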