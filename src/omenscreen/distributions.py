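"""Calibrated feature distributions for the synthetic cohort generator.

Two calibration modes are supported for every feature:

* **moment matching** — the distribution reproduces a published group mean
  and standard deviation exactly (in the population);
* **quantile matching** — the distribution reproduces a published median
  and quartiles (P25, P75) exactly.

Each mode exists in a normal and a lognormal flavour.  Lognormal families
keep strictly positive support, appropriate for EEG band powers and gaze
velocity; normal families allow negative values (ECG amplitude) and
near-symmetric data (pupil diameters).

Quantile-family parameters are solved lazily, on first use: a published
summary row can be stored verbatim even when its printed quartiles are
internally inconsistent, and the error surfaces only if that particular
cell is actually sampled or inspected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationError",
    "FeatureDistribution",
    "moment_match",
    "quantile_match",
]

FAMILIES = (
    "moment-matched-normal",
    "quantile-matched-normal",
    "moment-matched-lognormal",
    "quantile-matched-lognormal",
)

#: Upper-quartile deviate of the standard normal, Phi^-1(0.75).
_Z75 = float(stats.norm.ppf(0.75))


class CalibrationError(ValueError):
    """A published summary cannot be matched by the requested family."""


@dataclass(frozen=True)
class FeatureDistribution:
    """One feature's calibrated sampling distribution.

    ``mean``/``sd`` hold the moment targets (moment families); ``quartiles``
    holds ``(P25, median, P75)`` targets (quantile families).  ``location``
    and ``scale`` are the solved parameters of the underlying normal — on
    the log scale for lognormal families.
    """

    family: str
    mean: float | None = None
    sd: float | None = None
    quartiles: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family.startswith("moment"):
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.family} requires mean and sd")
            if not (self.sd > 0):
                raise ValueError(f"scale must be > 0, got sd={self.sd}")
            if "lognormal" in self.family and not (self.mean > 0):
                raise CalibrationError(
                    f"lognormal moment matching needs a positive mean, got {self.mean}"
                )
        else:
            if self.quartiles is None or len(self.quartiles) != 3:
                raise ValueError(f"{self.family} requires (P25, median, P75) targets")

    # -- parameter solving -------------------------------------------------

    @property
    def location(self) -> float:
        return self._params()[0]

    @property
    def scale(self) -> float:
        return self._params()[1]

    def _params(self) -> tuple:
        """Solve (location, scale) of the underlying normal.

        Moment-matched lognormal: if m, s are the target mean and SD on the
        data scale, sigma^2 = ln(1 + s^2/m^2) and mu = ln(m) - sigma^2/2.
        Quantile matching: location = (log-)median and
        scale = (P75 - P25) / (2 * Phi^-1(0.75)) on the (log-)scale.
        """
        if self.family == "moment-matched-normal":
            return float(self.mean), float(self.sd)
        if self.family == "moment-matched-lognormal":
            sigma2 = math.log1p((self.sd / self.mean) ** 2)
            return math.log(self.mean) - sigma2 / 2.0, math.sqrt(sigma2)
        p25, med, p75 = self.quartiles
        if "lognormal" in self.family:
            if min(self.quartiles) <= 0:
                raise CalibrationError(
                    f"lognormal quantile targets must be positive, got {self.quartiles}"
                )
            p25, med, p75 = math.log(p25), math.log(med), math.log(p75)
        if not (p25 < med < p75):
            raise CalibrationError(
                "quantile targets must be strictly increasing "
                f"(after log transform for lognormal families); got {self.quartiles}"
            )
        return float(med), float(p75 - p25) / (2.0 * _Z75)

    # -- sampling and queries ---------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        loc, scale = self._params()
        draws = rng.normal(loc, scale, size=n)
        if "lognormal" in self.family:
            draws = np.exp(draws)
        return draws

    def true_quantile(self, q: float) -> float:
        loc, scale = self._params()
        x = float(stats.norm.ppf(q, loc=loc, scale=scale))
        return math.exp(x) if "lognormal" in self.family else x

    def true_mean(self) -> float:
        loc, scale = self._params()
        if "lognormal" in self.family:
            return math.exp(loc + scale**2 / 2.0)
        return loc

    def validate(self) -> None:
        """Force parameter solving; raises :class:`CalibrationError` if impossible."""
        self._params()


def moment_match(family: str, mean: float, sd: float) -> FeatureDistribution:
    """Distribution whose population mean and SD equal the targets."""
    if not family.startswith("moment"):
        raise ValueError(f"moment_match expects a moment family, got {family!r}")
    return FeatureDistribution(family=family, mean=mean, sd=sd)


def quantile_match(
    family: str, p25: float, median: float, p75: float
) -> FeatureDistribution:
    """Distribution whose population P25/median/P75 equal the targets.

    Raises :class:`CalibrationError` immediately when the targets are not
    strictly increasing (after log transform for lognormal families).
    """
    if not family.startswith("quantile"):
        raise ValueError(f"quantile_match expects a quantile family, got {family!r}")
    dist = FeatureDistribution(family=family, quartiles=(p25, median, p75))
    dist.validate()
    return dist
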