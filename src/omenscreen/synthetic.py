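"""Synthetic driver cohorts and band-power series.

The study population this module emulates is a cohort of 134 drivers — 56
who could not perceive dangerous omens (D1) and 78 who could (D2) — whose
nine physiological features were summarised group-wise by mean/SD and by
median/quartiles.  Both summary sets are stored verbatim as calibration
targets; the generator draws each feature independently from the matched
distribution of the driver's group.

Band-power time series are emulated at the 250 Hz feature sampling rate as
a constant baseline plus Gaussian noise; D2 drivers additionally receive a
sustained level step (the neural response to the perceived omen) starting
at the hazard time and persisting to the end of the record, matching the
before/after mean-difference model of the change-point stage.

The printed median and quartiles of the gamma band for group D2 are
mutually inconsistent (median below P25); quantile-matched sampling of
that single cell therefore raises :class:`~omenscreen.distributions.CalibrationError`
unless the caller overrides the median.  Parameter solving is lazy, so
every other cell of the quantile calibration remains usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from omenscreen.cohort import (
    BIO_FEATURES,
    CohortTable,
    DriverRecord,
    EEG_BANDS,
    EYE_FEATURES,
    FEATURES,
    GROUPS,
    canonical_band,
)
from omenscreen.distributions import (
    CalibrationError,
    FeatureDistribution,
    moment_match,
)

__all__ = [
    "PRINTED_MOMENTS",
    "PRINTED_QUARTILES",
    "ConfigurationError",
    "SyntheticSpec",
    "TimeSeriesParams",
    "default_calibration",
    "generate_cohort",
    "generate_factor_cohort",
    "generate_timeseries",
]


class ConfigurationError(ValueError):
    """A SyntheticSpec field violates its contract."""


# --------------------------------------------------------------------------
# Published group-level calibration targets.
#
# PRINTED_MOMENTS[group][feature] = (mean, SD)
# PRINTED_QUARTILES[group][feature] = (P25, median, P75)
#
# EEG band powers in uV^2/Hz, ECG in uV, GV in px/ms, pupil diameters in mm.
# The gamma/D2 quartile row is stored exactly as printed even though its
# median lies below its P25; see the module docstring.
# --------------------------------------------------------------------------

PRINTED_MOMENTS = {
    "D1": {
        "alpha": (5.812e-13, 4.869e-13),
        "beta": (1.709e-13, 7.518e-14),
        "theta": (3.091e-12, 6.576e-12),
        "delta": (1.530e-11, 2.412e-11),
        "gamma": (8.173e-14, 3.421e-14),
        "ecg": (-2.377, 4.436),
        "gv": (0.163, 0.172),
        "lpd": (3.413, 0.807),
        "rpd": (3.813, 0.336),
    },
    "D2": {
        "alpha": (5.769e-12, 1.119e-11),
        "beta": (7.752e-13, 1.792e-12),
        "theta": (6.005e-11, 2.182e-11),
        "delta": (2.818e-10, 6.893e-10),
        "gamma": (4.709e-13, 1.653e-11),
        "ecg": (47.384, 80.659),
        "gv": (1.088, 1.426),
        "lpd": (3.108, 0.845),
        "rpd": (3.663, 0.373),
    },
}

PRINTED_QUARTILES = {
    "D1": {
        "alpha": (3.238e-13, 4.582e-13, 6.320e-13),
        "beta": (1.179e-13, 1.547e-13, 1.981e-13),
        "theta": (6.804e-13, 1.198e-12, 2.745e-12),
        "delta": (2.099e-12, 4.279e-12, 1.747e-11),
        "gamma": (6.432e-14, 7.206e-14, 8.661e-14),
        "ecg": (-4.984, -1.853, -0.134),
        "gv": (0.064, 0.108, 0.217),
        "lpd": (2.623, 2.976, 4.165),
        "rpd": (3.572, 3.810, 4.060),
    },
    "D2": {
        "alpha": (2.221e-13, 2.135e-12, 6.333e-12),
        "beta": (1.237e-13, 1.999e-13, 4.891e-13),
        "theta": (2.879e-12, 2.182e-11, 7.308e-11),
        "delta": (1.336e-11, 1.087e-10, 2.179e-10),
        "gamma": (5.802e-13, 8.596e-14, 9.118e-13),  # median < P25 as printed
        "ecg": (-13.184, 36.538, 97.288),
        "gv": (0.213, 0.470, 1.495),
        "lpd": (2.482, 2.801, 4.057),
        "rpd": (3.382, 3.716, 3.895),
    },
}

#: Strictly positive, right-skewed features default to lognormal families.
LOGNORMAL_FEATURES = EEG_BANDS + ("gv",)


def _default_family(feature: str, mode: str) -> str:
    kind = "lognormal" if feature in LOGNORMAL_FEATURES else "normal"
    return f"{mode}-matched-{kind}"


@dataclass(frozen=True)
class TimeSeriesParams:
    """Band-power time-series generation parameters.

    ``noise_sd_frac`` is the baseline noise SD as a fraction of the baseline
    level; ``step_amplitude_sd`` is the injected sustained step in units of
    that baseline SD (D2 drivers only).
    """

    duration_s: float = 60.0
    sampling_rate_hz: float = 250.0
    noise_sd_frac: float = 0.1
    step_amplitude_sd: float = 8.0
    hazard_time_s: float = 30.0

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be > 0")
        if not (0.0 < self.hazard_time_s < self.duration_s):
            raise ConfigurationError(
                "hazard_time_s must lie strictly inside the series duration"
            )
        if self.step_amplitude_sd < 0:
            raise ConfigurationError("step_amplitude_sd must be >= 0")
        if self.noise_sd_frac <= 0:
            raise ConfigurationError("noise_sd_frac must be > 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort.

    ``distributions[group][feature]`` maps to a
    :class:`~omenscreen.distributions.FeatureDistribution`.
    """

    distributions: dict
    n1: int = 56
    n2: int = 78
    timeseries: TimeSeriesParams = field(default_factory=TimeSeriesParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ConfigurationError(
                f"group sizes must be >= 2, got n1={self.n1}, n2={self.n2}"
            )
        for g in GROUPS:
            if g not in self.distributions:
                raise ConfigurationError(f"missing distribution map for group {g}")
            for f in FEATURES:
                if f not in self.distributions[g]:
                    raise ConfigurationError(f"missing distribution for {g}/{f}")
        self.timeseries.validate()

    def distribution(self, group: str, feature: str) -> FeatureDistribution:
        return self.distributions[group][feature]


def default_calibration(
    mode: str = "moment",
    overrides: dict | None = None,
    timeseries: TimeSeriesParams | None = None,
    seed: int = 0,
) -> SyntheticSpec:
    """Spec calibrated to the published group summaries.

    Parameters
    ----------
    mode : {"moment", "quantile"}
        Whether distributions match the printed means/SDs or the printed
        medians/quartiles.  EEG band powers and gaze velocity use lognormal
        families, ECG and pupil diameters normal ones.
    overrides : dict, optional
        ``(group, feature) -> FeatureDistribution`` replacements; the
        supported escape hatch for the internally inconsistent printed
        gamma/D2 quartile row.
    """
    if mode not in ("moment", "quantile"):
        raise ConfigurationError(f"mode must be 'moment' or 'quantile', got {mode!r}")
    table = PRINTED_MOMENTS if mode == "moment" else PRINTED_QUARTILES
    dists: dict = {}
    for g in GROUPS:
        dists[g] = {}
        for f in FEATURES:
            if overrides and (g, f) in overrides:
                dists[g][f] = overrides[(g, f)]
            elif mode == "moment":
                dists[g][f] = moment_match(_default_family(f, mode), *table[g][f])
            else:
                # Lazy construction: parameters are solved on first use so
                # the inconsistent gamma/D2 cell errors only when touched.
                dists[g][f] = FeatureDistribution(
                    family=_default_family(f, mode), quartiles=table[g][f]
                )
    return SyntheticSpec(
        distributions=dists,
        timeseries=timeseries or TimeSeriesParams(),
        seed=seed,
    )


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> CohortTable:
    """Draw a labeled cohort of ``n1`` D1 and ``n2`` D2 drivers.

    Every feature is drawn independently from its group's distribution.
    D2 drivers carry the hazard time as their true perception time (the
    step onset of their generated series).  Identical spec and seed give
    identical cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records = []
    for group, n in (("D1", spec.n1), ("D2", spec.n2)):
        for i in range(n):
            feats = {
                f: float(spec.distribution(group, f).sample(1, rng)[0])
                for f in FEATURES
            }
            records.append(
                DriverRecord(
                    driver_id=f"{group}-{i + 1:03d}",
                    label=group,
                    features=feats,
                    perception_time_s=(
                        spec.timeseries.hazard_time_s if group == "D2" else None
                    ),
                )
            )
    return CohortTable(
        records,
        provenance="synthetic",
        seed=spec.seed if seed is None else seed,
    )


def generate_timeseries(
    record: DriverRecord,
    band: str,
    spec: SyntheticSpec,
    seed: int,
):
    """Band-power series for one driver: baseline noise, plus a step for D2.

    Returns
    -------
    series : omenscreen.changepoint.BandPowerSeries
    onset_s : float or None
        True step onset (the hazard time) for D2 records, ``None`` for D1.
    """
    from omenscreen.changepoint import BandPowerSeries  # avoid import cycle

    band = canonical_band(band)
    ts = spec.timeseries
    ts.validate()
    rng = np.random.default_rng(seed)
    n = int(round(ts.duration_s * ts.sampling_rate_hz))
    baseline = record.features.get(band)
    if baseline is None or baseline <= 0:
        raise ConfigurationError(
            f"driver {record.driver_id} lacks a positive {band} baseline level"
        )
    noise_sd = ts.noise_sd_frac * baseline
    values = baseline + rng.normal(0.0, noise_sd, size=n)
    onset_s = None
    if record.label == "D2":
        onset_idx = int(round(ts.hazard_time_s * ts.sampling_rate_hz))
        values[onset_idx:] += ts.step_amplitude_sd * noise_sd
        onset_s = onset_idx / ts.sampling_rate_hz
    series = BandPowerSeries(
        driver_id=record.driver_id,
        band=band,
        sampling_rate_hz=ts.sampling_rate_hz,
        start_time_s=0.0,
        values=values,
    )
    return series, onset_s


# --------------------------------------------------------------------------
# Two-factor mode for measurement-model parameter-recovery tests.
# --------------------------------------------------------------------------

DEFAULT_FACTOR_LOADINGS = {
    "alpha": 0.80, "beta": 0.55, "theta": 0.70, "delta": 0.75,
    "gamma": 0.45, "ecg": 0.50, "gv": 0.70, "lpd": 0.60, "rpd": 0.80,
}


def generate_factor_cohort(
    n1: int,
    n2: int,
    seed: int,
    loadings: dict | None = None,
    factor_corr: float = 0.30,
    group_shift_bio: float = 2.0,
    group_shift_eye: float = 0.5,
) -> CohortTable:
    """Cohort whose features follow a correlated two-factor model.

    Each driver draws latent scores (bioelectrical, eye-movement) from a
    bivariate normal with unit variances and correlation ``factor_corr``;
    D2 drivers' latents are shifted by the group shifts.  Indicator j of
    factor f is ``lambda_j * f + sqrt(1 - lambda_j^2) * e_j``, so within
    each group the indicators have unit variance and loadings equal to the
    requested values — the ground truth for refit-recovery tests.

    Features are on the standardized scale (they are not transformed back
    to physical units); pupil-diameter positivity is maintained by an
    affine offset that does not change loadings.
    """
    lam = dict(DEFAULT_FACTOR_LOADINGS)
    if loadings:
        lam.update(loadings)
    if not (-1.0 < factor_corr < 1.0):
        raise ConfigurationError("factor_corr must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, factor_corr], [factor_corr, 1.0]])
    records = []
    for group, n, shift in (
        ("D1", n1, (0.0, 0.0)),
        ("D2", n2, (group_shift_bio, group_shift_eye)),
    ):
        fac = rng.multivariate_normal([shift[0], shift[1]], cov, size=n)
        for i in range(n):
            feats = {}
            for f in BIO_FEATURES:
                l = lam[f]
                feats[f] = float(
                    l * fac[i, 0] + np.sqrt(1 - l**2) * rng.normal()
                )
            for f in EYE_FEATURES:
                l = lam[f]
                feats[f] = float(
                    l * fac[i, 1] + np.sqrt(1 - l**2) * rng.normal()
                )
            # keep support constraints of the record container
            for f in EEG_BANDS + ("gv",):
                feats[f] = feats[f] - (-10.0)  # shift well above zero
            for f in ("lpd", "rpd"):
                feats[f] = feats[f] + 10.0
            records.append(
                DriverRecord(
                    driver_id=f"{group}-{i + 1:03d}", label=group, features=feats
                )
            )
    return CohortTable(records, provenance="synthetic-two-factor", seed=seed)
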