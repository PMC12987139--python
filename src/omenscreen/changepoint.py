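"""Sliding-window change-point detection for EEG band-power series.

The detector looks for a sustained shift in the mean level of a
band-power trace.  It composes two pieces of machinery:

1. A **sliding mean-difference statistic**: at each centre t, the means of
   the w samples left of t and the w samples right of t are compared via a
   pooled two-sample t-type statistic
   ``T(t) = (Rbar - Lbar) / (sigma_hat * sqrt(2 / w))``.
   Candidate epochs are maximal runs where T exceeds mu + k*sigma of its
   own baseline distribution (k = 3 by default) for at least the minimum
   duration (0.5 s by default, excluding blink/myoelectric transients).

2. A **local comparison scan** refining the location inside each flagged
   epoch: for every candidate i, ``Y_i = sum(d values from i) - sum(d
   values before i)``; the maximiser i* is the location estimate, and the
   scan maximum W = Y* is tested against the critical value
   ``C = sigma * sqrt(2d) * A(alpha)`` where sigma is the baseline SD of
   the raw series and A is, by default, the two-sided standard-normal
   quantile Bonferroni-corrected over the number of candidate positions
   scanned (under an iid null Var(Y_i) = 2 d sigma^2, which motivates the
   sqrt(2d) factor).  The jump size theta_hat is the mean of the series
   from the change point onward minus the mean before it.

All public indices are 0-based sample positions; times are seconds.  A
change point at index m means the new regime starts *at* sample m.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from omenscreen.cohort import canonical_band

__all__ = [
    "BandPowerSeries",
    "BaselineStats",
    "ChangePointResult",
    "DetectionConfig",
    "WindowStat",
    "critical_value",
    "default_band_configs",
    "detect_change_points",
    "jump_size",
    "local_comparison_scan",
    "t_statistic_series",
    "window_statistic",
]

#: Registry of candidate-quantile functions A(alpha, n_candidates) for the
#: critical value.  Pluggable via DetectionConfig.quantile_fn.
QUANTILE_FUNCTIONS = {
    "bonferroni-normal": lambda alpha, m: float(
        stats.norm.ppf(1.0 - alpha / (2.0 * max(m, 1)))
    ),
    "normal": lambda alpha, m: float(stats.norm.ppf(1.0 - alpha / 2.0)),
}


@dataclass(frozen=True)
class BandPowerSeries:
    """One driver x one band uniformly sampled power trace."""

    driver_id: str
    band: str
    sampling_rate_hz: float
    start_time_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("series must be 1-D with at least 2 samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    def time_of(self, index: int) -> float:
        return self.start_time_s + index / self.sampling_rate_hz

    def index_of(self, time_s: float) -> int:
        return int(round((time_s - self.start_time_s) * self.sampling_rate_hz))


@dataclass(frozen=True)
class DetectionConfig:
    """Per-band detector configuration.

    ``window_samples`` is the full detection window; the half-window used
    on each side of a centre is ``w = window_samples // 2``.  ``d`` is the
    local-scan half-width (defaults to ``w // 4``, clipped to [2, w]).
    """

    band: str
    window_s: float
    window_samples: int
    sampling_rate_hz: float = 250.0
    k_sigma: float = 3.0
    alpha: float = 0.05
    min_duration_s: float = 0.5
    d: int | None = None
    quantile_fn: str = "bonferroni-normal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", canonical_band(self.band))
        if self.window_samples < 4 or self.window_samples % 2:
            raise ValueError("window_samples must be even and >= 4")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k_sigma <= 0 or self.min_duration_s < 0:
            raise ValueError("k_sigma must be > 0 and min_duration_s >= 0")
        if self.d is not None and self.d < 1:
            raise ValueError("d must be >= 1")
        if self.quantile_fn not in QUANTILE_FUNCTIONS:
            raise ValueError(f"unknown quantile_fn {self.quantile_fn!r}")

    @property
    def half_window(self) -> int:
        return self.window_samples // 2

    @property
    def scan_half_width(self) -> int:
        if self.d is not None:
            return self.d
        return int(np.clip(self.half_window // 4, 2, self.half_window))


@dataclass(frozen=True)
class WindowStat:
    """Mean-difference statistic at one centre index."""

    t: int
    left_mean: float
    right_mean: float
    pooled_sd: float
    statistic: float


@dataclass(frozen=True)
class BaselineStats:
    """Baseline segment summary used for thresholding and the critical value."""

    start_s: float
    end_s: float
    t_mean: float
    t_sd: float
    series_sd: float


@dataclass(frozen=True)
class ChangePointResult:
    """One detected (candidate) change point."""

    driver_id: str
    band: str
    index: int
    time_s: float
    scan_statistic: float  # W = Y*
    critical_value: float  # C
    series_sd: float
    jump: float  # theta_hat
    significant: bool
    run_start_s: float = 0.0
    run_end_s: float = 0.0


def window_statistic(series: BandPowerSeries, t: int, w: int) -> WindowStat:
    """Two-sample mean-difference statistic at centre ``t`` (0-based).

    The left window is the w samples ending at t inclusive, the right
    window the w samples starting at t + 1.  When the pooled SD is zero
    the statistic is 0 for equal means and a signed infinity otherwise
    (treated as exceeding any finite threshold).
    """
    x = series.values
    n = x.size
    if w < 2:
        raise ValueError("half-window w must be >= 2")
    if t < w - 1 or t + w > n - 1:
        raise IndexError(
            f"windows out of bounds: need {w - 1} <= t <= {n - 1 - w}, got t={t}"
        )
    left = x[t - w + 1 : t + 1]
    right = x[t + 1 : t + w + 1]
    lbar = float(left.mean())
    rbar = float(right.mean())
    ssd = float(((left - lbar) ** 2).sum() + ((right - rbar) ** 2).sum())
    pooled = np.sqrt(ssd / (2 * w - 2))
    if pooled == 0.0:
        stat = 0.0 if rbar == lbar else float(np.sign(rbar - lbar) * np.inf)
    else:
        stat = (rbar - lbar) / (pooled * np.sqrt(2.0 / w))
    return WindowStat(t=t, left_mean=lbar, right_mean=rbar, pooled_sd=float(pooled), statistic=stat)


def t_statistic_series(series: BandPowerSeries, w: int):
    """Vectorised T(t) over all valid centres.

    Returns ``(centres, T)`` where centres are the 0-based indices
    ``w - 1 .. n - 1 - w``.
    """
    x = series.values
    n = x.size
    if n < 2 * w:
        raise ValueError(f"series of length {n} too short for half-window {w}")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    t = np.arange(w - 1, n - w)
    lsum = c1[t + 1] - c1[t + 1 - w]
    rsum = c1[t + 1 + w] - c1[t + 1]
    lbar = lsum / w
    rbar = rsum / w
    lss = np.maximum(c2[t + 1] - c2[t + 1 - w] - w * lbar**2, 0.0)
    rss = np.maximum(c2[t + 1 + w] - c2[t + 1] - w * rbar**2, 0.0)
    pooled = np.sqrt((lss + rss) / (2 * w - 2))
    diff = rbar - lbar
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = diff / (pooled * np.sqrt(2.0 / w))
    zero = pooled == 0.0
    stat[zero & (diff == 0.0)] = 0.0
    stat[zero & (diff > 0.0)] = np.inf
    stat[zero & (diff < 0.0)] = -np.inf
    return t, stat


def local_comparison_scan(series: BandPowerSeries, d: int):
    """Local comparison statistic Y over all candidate positions.

    For each 0-based candidate ``i`` in ``d .. n - d - 1``,
    ``Y_i = sum(x[i : i + d]) - sum(x[i - d : i])``: the new regime is
    taken to start at sample i.  Returns ``(candidates, Y, i_star,
    y_star)`` with ties in the maximum broken by the smallest index.
    """
    x = series.values
    n = x.size
    if d < 1:
        raise ValueError("d must be >= 1")
    if n < 2 * d + 1:
        raise ValueError(
            f"series of length {n} too short for scan half-width {d}; "
            f"need at least {2 * d + 1} samples"
        )
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(d, n - d)
    y = (c1[i + d] - c1[i]) - (c1[i] - c1[i - d])
    k = int(np.argmax(y))  # argmax returns the first maximiser: earliest tie wins
    return i, y, int(i[k]), float(y[k])


def critical_value(
    sigma: float,
    d: int,
    n_candidates: int,
    alpha: float,
    quantile_fn: str = "bonferroni-normal",
) -> float:
    """Critical value ``C = sigma * sqrt(2 d) * A(alpha)`` for the scan maximum.

    ``n_candidates`` is the number of positions the scan examined; the
    default quantile function applies a two-sided Bonferroni correction
    over them.  ``C = 0`` when sigma = 0 (noiseless series).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if d < 1 or n_candidates < 1:
        raise ValueError("d and n_candidates must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sigma == 0.0:
        return 0.0
    a = QUANTILE_FUNCTIONS[quantile_fn](alpha, n_candidates)
    return float(sigma * np.sqrt(2.0 * d) * a)


def jump_size(series: BandPowerSeries, m: int) -> float:
    """Average jump amplitude: mean of x[m:] minus mean of x[:m] (0-based m)."""
    x = series.values
    if not (1 <= m <= x.size - 1):
        raise IndexError(f"change index must satisfy 1 <= m <= {x.size - 1}, got {m}")
    return float(x[m:].mean() - x[:m].mean())


def _runs_above(mask: np.ndarray):
    """Maximal runs of True in a boolean mask as (start, stop) index pairs."""
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def compute_baseline(
    series: BandPowerSeries, config: DetectionConfig, bounds
) -> BaselineStats:
    """Estimate the T-statistic baseline and the raw-series SD over ``bounds``.

    ``bounds`` is ``(start_s, end_s)``; the segment is assumed change-free
    and must be at least one full detection window long.
    """
    start_s, end_s = bounds
    w = config.half_window
    i0 = max(series.index_of(start_s), 0)
    i1 = min(series.index_of(end_s), len(series))
    if i1 - i0 < config.window_samples:
        raise ValueError(
            f"baseline segment [{start_s}, {end_s}] s holds {i1 - i0} samples; "
            f"needs at least one full window ({config.window_samples})"
        )
    centres, tstat = t_statistic_series(series, w)
    in_base = (centres >= i0 + w - 1) & (centres <= i1 - 1 - w)
    base_t = tstat[in_base]
    if base_t.size < 2:
        raise ValueError("baseline segment yields fewer than 2 T values")
    seg = series.values[i0:i1]
    return BaselineStats(
        start_s=start_s,
        end_s=end_s,
        t_mean=float(base_t.mean()),
        t_sd=float(base_t.std(ddof=1)),
        series_sd=float(seg.std(ddof=1)),
    )


def detect_change_points(
    series: BandPowerSeries,
    config: DetectionConfig,
    baseline,
) -> list:
    """Full detection pass over one band-power series.

    Parameters
    ----------
    series : BandPowerSeries
    config : DetectionConfig
    baseline : BaselineStats or (start_s, end_s)
        Pre-computed baseline statistics, or the bounds (in seconds) of a
        change-free segment over which to estimate them.

    Returns
    -------
    list of ChangePointResult
        One result per flagged epoch (possibly empty), each carrying the
        refined location, the scan maximum W, the critical value C, the
        jump estimate and the significance decision W > C.
    """
    if not isinstance(baseline, BaselineStats):
        baseline = compute_baseline(series, config, baseline)
    w = config.half_window
    d = config.scan_half_width
    n = len(series)
    centres, tstat = t_statistic_series(series, w)
    threshold = baseline.t_mean + config.k_sigma * baseline.t_sd
    exceed = tstat > threshold
    min_len = int(round(config.min_duration_s * series.sampling_rate_hz))
    results = []
    for a, b in _runs_above(exceed):
        if b - a < max(min_len, 1):
            continue
        run_start = int(centres[a])
        run_stop = int(centres[b - 1])
        seg_lo = max(run_start - w, 0)
        seg_hi = min(run_stop + w + 1, n)
        if seg_hi - seg_lo < 2 * d + 1:
            continue
        segment = BandPowerSeries(
            driver_id=series.driver_id,
            band=series.band,
            sampling_rate_hz=series.sampling_rate_hz,
            start_time_s=series.time_of(seg_lo),
            values=series.values[seg_lo:seg_hi],
        )
        cand, _, i_star_local, y_star = local_comparison_scan(segment, d)
        m = seg_lo + i_star_local
        c = critical_value(
            baseline.series_sd, d, cand.size, config.alpha, config.quantile_fn
        )
        theta = jump_size(series, m) if 1 <= m <= n - 1 else 0.0
        results.append(
            ChangePointResult(
                driver_id=series.driver_id,
                band=series.band,
                index=m,
                time_s=series.time_of(m),
                scan_statistic=y_star,
                critical_value=c,
                series_sd=baseline.series_sd,
                jump=theta,
                significant=bool(y_star > c),
                run_start_s=series.time_of(run_start),
                run_end_s=series.time_of(run_stop),
            )
        )
    return results


def default_band_configs(path=None) -> dict:
    """Per-band detector configurations shipped with the package.

    Window lengths of 4 s (alpha, beta) and 3 s (theta, delta, gamma)
    reflect the typical 3-6 s temporal scale of omen perception at the
    250 Hz feature rate; each band carries its own scan significance
    level.  Returns ``{band: DetectionConfig}``.
    """
    if path is None:
        ref = importlib.resources.files("omenscreen") / "data" / "band_config.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    configs = {}
    for band, c in raw["bands"].items():
        band = canonical_band(band)
        configs[band] = DetectionConfig(
            band=band,
            window_s=float(c["window_s"]),
            window_samples=int(c["window_samples"]),
            sampling_rate_hz=float(c.get("sampling_rate_hz", 250.0)),
            k_sigma=float(c.get("k_sigma", 3.0)),
            alpha=float(c["alpha"]),
            min_duration_s=float(c.get("min_duration_s", 0.5)),
            d=c.get("d"),
            quantile_fn=c.get("quantile_fn", "bonferroni-normal"),
        )
    return configs
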