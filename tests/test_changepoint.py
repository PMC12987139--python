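"""Sliding-window change-point detector: oracles, examples and invariants."""

import numpy as np
import pytest
from scipy import stats

from omenscreen.changepoint import (
    BandPowerSeries,
    DetectionConfig,
    critical_value,
    default_band_configs,
    detect_change_points,
    jump_size,
    local_comparison_scan,
    t_statistic_series,
    window_statistic,
)


def make_series(values, fs=1.0, band="alpha", driver="drv"):
    return BandPowerSeries(
        driver_id=driver, band=band, sampling_rate_hz=fs,
        start_time_s=0.0, values=np.asarray(values, dtype=float),
    )


def brute_force_scan(x, d):
    """Independent oracle: literal double sum over both local windows."""
    x = np.asarray(x, dtype=float)
    out = []
    for i in range(d, len(x) - d):
        right = sum(x[j] for j in range(i, i + d))
        left = sum(x[j] for j in range(i - d, i))
        out.append((i, right - left))
    return out


class TestWindowStatistic:
    def test_constant_series_gives_zero(self):
        ws = window_statistic(make_series([5.0] * 10), t=4, w=3)
        assert ws.statistic == 0.0

    def test_noiseless_step_gives_sentinel(self):
        ws = window_statistic(make_series([0, 0, 0, 0, 2, 2, 2, 2]), t=3, w=4)
        assert (ws.left_mean, ws.right_mean, ws.pooled_sd) == (0.0, 2.0, 0.0)
        assert ws.statistic == np.inf

    def test_hand_computed_value(self):
        ws = window_statistic(make_series([1, 2, 3, 4, 5, 6]), t=2, w=3)
        assert (ws.left_mean, ws.right_mean) == (2.0, 5.0)
        assert ws.pooled_sd == pytest.approx(1.0)
        assert ws.statistic == pytest.approx(3.0 / np.sqrt(2.0 / 3.0))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            window_statistic(make_series([1, 2, 3, 4, 5, 6]), t=1, w=3)

    def test_vectorized_matches_pointwise(self, rng):
        series = make_series(rng.normal(size=60))
        centres, tstat = t_statistic_series(series, w=8)
        for t, got in zip(centres[::7], tstat[::7]):
            assert got == pytest.approx(window_statistic(series, int(t), 8).statistic)


class TestLocalComparisonScan:
    def test_constant_series_all_zero(self):
        _, y, _, y_star = local_comparison_scan(make_series([3.0] * 12), d=3)
        assert np.allclose(y, 0.0) and y_star == 0.0

    def test_step_example(self):
        cand, y, i_star, y_star = local_comparison_scan(
            make_series([0, 0, 0, 1, 1, 1]), d=2
        )
        assert list(cand) == [2, 3]
        assert list(y) == [1.0, 2.0]
        assert (i_star, y_star) == (3, 2.0)

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="5"):
            local_comparison_scan(make_series([1, 2, 3, 4]), d=2)

    def test_ties_take_smallest_index(self):
        cand, y, i_star, _ = local_comparison_scan(make_series([0, 0, 0, 0, 0, 0]), d=2)
        assert i_star == cand[0]

    def test_matches_brute_force_oracle(self, rng):
        """Exact agreement with the double-sum oracle on random series."""
        for _ in range(200):
            n = int(rng.integers(5, 200))
            d = int(rng.integers(1, max(n // 2, 2)))
            if n < 2 * d + 1:
                d = (n - 1) // 2
            x = rng.normal(size=n)
            cand, y, i_star, y_star = local_comparison_scan(make_series(x), d)
            oracle = brute_force_scan(x, d)
            assert list(cand) == [i for i, _ in oracle]
            assert np.allclose(y, [v for _, v in oracle])
            best = max(oracle, key=lambda iv: (iv[1], -iv[0]))
            assert y_star == pytest.approx(best[1])


class TestCriticalValue:
    def test_zero_sigma_gives_zero(self):
        assert critical_value(0.0, 2, 6, 0.1) == 0.0

    def test_closed_form_with_bonferroni_quantile(self):
        want = 2.0 * stats.norm.ppf(1 - 0.1 / (2 * 6))
        assert critical_value(1.0, 2, 6, 0.1) == pytest.approx(want)

    def test_linear_in_sigma(self):
        assert critical_value(2.0, 3, 10, 0.05) == pytest.approx(
            2 * critical_value(1.0, 3, 10, 0.05)
        )

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            critical_value(1.0, 2, 6, 1.5)


class TestJumpSize:
    @pytest.mark.parametrize(
        "x,m,want",
        [([0, 0, 0, 1, 1, 1], 3, 1.0), ([7, 7, 7, 7], 2, 0.0), ([0, 0, 2, 2], 2, 2.0)],
    )
    def test_examples(self, x, m, want):
        assert jump_size(make_series(x), m) == pytest.approx(want)

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            jump_size(make_series([1, 2, 3]), 0)


class TestTableConfiguration:
    def test_shipped_defaults(self):
        configs = default_band_configs()
        want = {
            "alpha": (4.0, 1000, 0.042), "beta": (4.0, 1000, 0.087),
            "theta": (3.0, 750, 0.035), "delta": (3.0, 750, 0.061),
            "gamma": (3.0, 750, 0.029),
        }
        assert set(configs) == set(want)
        for band, (win_s, samples, alpha) in want.items():
            c = configs[band]
            assert (c.window_s, c.window_samples, c.alpha) == (win_s, samples, alpha)
            assert c.sampling_rate_hz == 250.0
            assert c.k_sigma == 3.0
            assert c.min_duration_s == 0.5

    def test_alpha_half_window(self):
        assert default_band_configs()["alpha"].half_window == 500

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(band="alpha", window_s=4.0, window_samples=999)


def noisy_step(seed, amplitude_sd, n_s=60.0, fs=250.0, level=1.0, noise=0.1, at=30.0):
    rng = np.random.default_rng(seed)
    n = int(n_s * fs)
    x = level + rng.normal(0.0, noise, size=n)
    x[int(at * fs):] += amplitude_sd * noise
    return make_series(x, fs=fs)


class TestDetectChangePoints:
    def test_constant_series_empty(self):
        cfg = DetectionConfig(band="alpha", window_s=4.0, window_samples=40,
                              sampling_rate_hz=10.0, alpha=0.042, min_duration_s=0.5)
        series = make_series(np.ones(400), fs=10.0)
        assert detect_change_points(series, cfg, (0.0, 20.0)) == []

    def test_injected_step_located_and_sized(self):
        cfg = default_band_configs()["alpha"]
        series = noisy_step(seed=42, amplitude_sd=10.0)
        results = detect_change_points(series, cfg, (0.0, 25.0))
        significant = [r for r in results if r.significant]
        assert len(significant) == 1
        r = significant[0]
        assert abs(r.time_s - 30.0) <= 0.5
        assert r.jump == pytest.approx(1.0, rel=0.10)

    def test_shift_equivariance(self):
        cfg = default_band_configs()["alpha"]
        base = noisy_step(seed=7, amplitude_sd=8.0)
        shifted = make_series(base.values + 123.456, fs=250.0)
        ra = detect_change_points(base, cfg, (0.0, 25.0))
        rb = detect_change_points(shifted, cfg, (0.0, 25.0))
        assert [r.index for r in ra] == [r.index for r in rb]
        assert [r.significant for r in ra] == [r.significant for r in rb]
        for a, b in zip(ra, rb):
            assert a.jump == pytest.approx(b.jump)

    def test_scale_equivariance(self):
        cfg = default_band_configs()["theta"]
        base = noisy_step(seed=8, amplitude_sd=8.0)
        scaled = make_series(base.values * 3.5, fs=250.0)
        ra = detect_change_points(base, cfg, (0.0, 25.0))
        rb = detect_change_points(scaled, cfg, (0.0, 25.0))
        assert [r.index for r in ra] == [r.index for r in rb]
        assert [r.significant for r in ra] == [r.significant for r in rb]
        for a, b in zip(ra, rb):
            assert b.jump == pytest.approx(3.5 * a.jump)

    def test_baseline_shorter_than_window_rejected(self):
        cfg = default_band_configs()["alpha"]
        series = noisy_step(seed=1, amplitude_sd=5.0)
        with pytest.raises(ValueError, match="baseline"):
            detect_change_points(series, cfg, (0.0, 2.0))
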