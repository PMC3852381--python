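"""Growth-curve phenotyping from OD600 time series.

Doubling times are extracted by the classic sliding-window method: on
log2(OD - background), the maximal slope over windows of consecutive
time points gives the maximal specific growth rate; its reciprocal is
the log-phase doubling time.  Lag is where the max-slope line crosses
the initial log2 OD, and efficiency is the total OD gain.  Group
comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney) test,
exact for small samples, with t-based 95% confidence intervals on the
group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "GrowthComparison",
    "fit_growth",
    "compare_growth",
    "hemizygote_report",
]

#: OD gain below which a curve is flagged as non-growing
MIN_OD_GAIN = 0.1
#: guard added before taking logs of background-subtracted OD
LOG_EPSILON = 1e-3


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate's OD600 time series (times in minutes, increasing)."""

    strain: str
    condition: str
    replicate: str
    time_min: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "od", od)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("time and OD must be equal-length 1-D arrays")
        if len(t) < 10:
            raise ValueError(f"growth curve needs >= 10 time points, got {len(t)}")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (od < 0).any():
            raise ValueError("OD readings must be >= 0")


@dataclass(frozen=True)
class GrowthFit:
    """Growth parameters extracted from one curve.

    ``max_rate_per_hr`` is on the log2 scale (doublings per hour), so
    ``doubling_time_min = 60 / max_rate_per_hr``.  Non-growing curves
    (total OD gain below threshold) carry ``grew = False`` and None
    rate/doubling time.
    """

    strain: str
    condition: str
    replicate: str
    lag_min: Optional[float]
    max_rate_per_hr: Optional[float]
    doubling_time_min: Optional[float]
    efficiency: float
    window: Optional[Tuple[int, int]]
    grew: bool


def fit_growth(
    curve: GrowthCurve,
    window_points: int = 5,
    background: float | str = 0.0,
    min_od_gain: float = MIN_OD_GAIN,
    min_signal_od: float = 0.03,
    smooth_points: int = 5,
) -> GrowthFit:
    """Sliding-window fit of one OD600 curve.

    The maximal slope of log2(od - background + eps) over all windows
    of ``window_points`` consecutive points whose signal stays above
    ``min_signal_od`` defines the growth rate.

    ``background`` is the optical density of the medium alone.  It
    defaults to 0, which is correct for pre-blanked readings (and for
    this package's simulated curves); pass the blank-well value for
    raw plate-reader data, or ``"auto"`` to estimate it as the minimum
    of the first three readings.  The auto estimate assumes the
    inoculum is optically negligible next to the blank — subtracting
    it from readings that already start at the culture's true OD
    steepens early log-slopes and biases the rate up.
    """
    t, od = curve.time_min, curve.od
    if window_points < 2:
        raise ValueError("window must span at least 2 points")
    if window_points > len(t):
        raise ValueError("window longer than the series")
    if background == "auto":
        background = float(od[:3].min())
    background = float(background)
    if min_signal_od < 0:
        raise ValueError("min_signal_od must be >= 0")
    efficiency = float(od.max() - od[0])
    if od.max() - od.min() < min_od_gain:
        return GrowthFit(
            curve.strain, curve.condition, curve.replicate,
            None, None, None, efficiency, None, grew=False,
        )
    signal = np.maximum(od - background, 0.0)
    y = np.log2(np.maximum(signal, LOG_EPSILON))
    if smooth_points > 1:
        # a centered moving average leaves a locally linear log-curve
        # (true exponential phase) unbiased while damping reader noise,
        # which otherwise inflates the maximum taken over windows;
        # edge points keep their raw values
        kernel = np.ones(smooth_points) / smooth_points
        inner = np.convolve(y, kernel, mode="valid")
        y_s = y.copy()
        half = (smooth_points - 1) // 2
        y_s[half : half + len(inner)] = inner
    else:
        y_s = y
    # windows dominated by read noise at near-blank densities produce
    # spuriously steep log-slopes; require a minimal signal level, and
    # fall back to all windows for curves that never reach it
    usable = signal >= min_signal_od
    starts = [
        s for s in range(len(t) - window_points + 1)
        if usable[s : s + window_points].all()
    ]
    if not starts:
        starts = list(range(len(t) - window_points + 1))
    best_slope, best_win, best_intercept = -np.inf, None, 0.0
    for start in starts:
        sl = slice(start, start + window_points)
        slope, intercept = np.polyfit(t[sl], y_s[sl], 1)
        if slope > best_slope:
            best_slope, best_win, best_intercept = slope, (start, start + window_points), intercept
    if best_slope <= 0:
        return GrowthFit(
            curve.strain, curve.condition, curve.replicate,
            None, None, None, efficiency, None, grew=False,
        )
    doubling = 1.0 / best_slope  # minutes per doubling on the log2 scale
    rate_per_hr = best_slope * 60.0
    # lag: where the max-slope line meets the initial log2 level
    lag = (y[0] - best_intercept) / best_slope
    lag = float(np.clip(lag, 0.0, t[-1]))
    return GrowthFit(
        curve.strain, curve.condition, curve.replicate,
        lag, rate_per_hr, doubling, efficiency, best_win, grew=True,
    )


@dataclass(frozen=True)
class GrowthComparison:
    """Fold change of mean doubling times between two groups, with a
    rank-sum p value and t-based 95% CIs on each group mean."""

    fold_change: float
    p_value: float
    mean_a: float
    mean_b: float
    ci_a: Tuple[float, float]
    ci_b: Tuple[float, float]
    n_a: int
    n_b: int


def _doubling_times(fits: Sequence[GrowthFit]) -> np.ndarray:
    dt = [f.doubling_time_min for f in fits if f.grew]
    return np.asarray(dt, dtype=float)


def _mean_ci(x: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    m = x.mean()
    if len(x) < 2 or np.ptp(x) == 0:
        return (float(m), float(m))
    half = stats.t.ppf(0.5 + level / 2, len(x) - 1) * stats.sem(x)
    return (float(m - half), float(m + half))


def compare_growth(
    fits_a: Sequence[GrowthFit], fits_b: Sequence[GrowthFit]
) -> GrowthComparison:
    """Compare doubling times between two groups of fitted curves.

    Fold change is mean(a)/mean(b); the p value is the two-sided
    Wilcoxon rank-sum test (exact when sample sizes permit).  Requires
    at least 3 growing replicates per side.
    """
    a, b = _doubling_times(fits_a), _doubling_times(fits_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            f"need >= 3 growing replicates per group, got {len(a)} and {len(b)}"
        )
    if np.ptp(np.concatenate([a, b])) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GrowthComparison(
        fold_change=float(a.mean() / b.mean()),
        p_value=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_a=_mean_ci(a),
        ci_b=_mean_ci(b),
        n_a=len(a),
        n_b=len(b),
    )


def hemizygote_report(
    fits: Sequence[GrowthFit],
    contrasts: Sequence[Tuple[str, str, str]],
) -> pd.DataFrame:
    """Tabulate genotype contrasts per condition.

    ``contrasts`` lists (label, genotype_a, genotype_b) pairs — e.g.
    a reciprocal-hemizygote pair for one locus, or parent vs parent,
    or parent vs hybrid; genotypes are matched against ``fit.strain``.
    Each contrast is evaluated within every condition where both
    genotypes were grown.
    """
    by_key: Dict[Tuple[str, str], List[GrowthFit]] = {}
    conditions: List[str] = []
    for f in fits:
        by_key.setdefault((f.strain, f.condition), []).append(f)
        if f.condition not in conditions:
            conditions.append(f.condition)
    rows = []
    for label, geno_a, geno_b in contrasts:
        for cond in conditions:
            fa = by_key.get((geno_a, cond))
            fb = by_key.get((geno_b, cond))
            if not fa or not fb:
                continue
            cmp = compare_growth(fa, fb)
            rows.append(
                {
                    "contrast": label,
                    "condition": cond,
                    "genotype_a": geno_a,
                    "genotype_b": geno_b,
                    "fold_change": cmp.fold_change,
                    "p_value": cmp.p_value,
                    "mean_doubling_a_min": cmp.mean_a,
                    "mean_doubling_b_min": cmp.mean_b,
                    "ci_a_low": cmp.ci_a[0],
                    "ci_a_high": cmp.ci_a[1],
                    "ci_b_low": cmp.ci_b[0],
                    "ci_b_high": cmp.ci_b[1],
                    "n_a": cmp.n_a,
                    "n_b": cmp.n_b,
                }
            )
    return pd.DataFrame(rows)
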