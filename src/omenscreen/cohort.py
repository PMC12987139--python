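"""Driver-level records and cohort containers shared across the pipeline.

A *driver record* is one row of the analysis table: nine median-aggregated
physiological features (five EEG band powers, an ECG amplitude feature,
gaze velocity and the two pupil diameters), a D1/D2 label where known, and
an optional perception timestamp.  A *cohort table* is an ordered
collection of such records with provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

#: Canonical feature order: bioelectrical block first, oculomotor block second.
EEG_BANDS = ("alpha", "beta", "theta", "delta", "gamma")
BIO_FEATURES = EEG_BANDS + ("ecg",)
EYE_FEATURES = ("gv", "lpd", "rpd")
FEATURES = BIO_FEATURES + EYE_FEATURES

#: Unicode band names accepted anywhere a band is named.
BAND_ALIASES = {
    "α": "alpha", "β": "beta", "θ": "theta", "δ": "delta", "γ": "gamma",
    "alpha": "alpha", "beta": "beta", "theta": "theta", "delta": "delta",
    "gamma": "gamma",
}

GROUPS = ("D1", "D2")

#: Measurement units per feature (EEG band powers are spectral densities).
FEATURE_UNITS = {
    "alpha": "uV^2/Hz", "beta": "uV^2/Hz", "theta": "uV^2/Hz",
    "delta": "uV^2/Hz", "gamma": "uV^2/Hz", "ecg": "uV",
    "gv": "px/ms", "lpd": "mm", "rpd": "mm",
}


def canonical_band(name: str) -> str:
    """Map a band name (Greek letter or ascii) to its canonical ascii form."""
    try:
        return BAND_ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown EEG band {name!r}; expected one of {sorted(set(BAND_ALIASES))}"
        ) from None


@dataclass
class DriverRecord:
    """One driver's aggregated feature vector.

    Parameters
    ----------
    driver_id : str
        Unique identifier within a cohort.
    label : str
        ``"D1"`` (cannot perceive dangerous omens), ``"D2"`` (can), or
        ``"unknown"`` before label fusion.
    features : dict
        Map from canonical feature name to its median-aggregated value;
        a missing feature is stored as ``None``.
    perception_time_s : float or None
        Moment of omen perception (seconds); present only for D2 drivers.
    """

    driver_id: str
    label: str = "unknown"
    features: dict = field(default_factory=dict)
    perception_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("D1", "D2", "unknown"):
            raise ValueError(f"label must be D1/D2/unknown, got {self.label!r}")
        for name, value in self.features.items():
            if name not in FEATURES:
                raise ValueError(f"unknown feature {name!r}")
            if value is None:
                continue
            if name in EEG_BANDS + ("gv",) and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
            if name in ("lpd", "rpd") and value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")

    def feature_vector(self, names: Sequence[str] = FEATURES) -> list:
        missing = [n for n in names if self.features.get(n) is None]
        if missing:
            raise ValueError(
                f"driver {self.driver_id} is missing features: {missing}"
            )
        return [self.features[n] for n in names]


@dataclass
class CohortTable:
    """Ordered collection of :class:`DriverRecord` with provenance."""

    records: list
    provenance: str = "loaded"
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [r.driver_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("driver identifiers must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DriverRecord]:
        return iter(self.records)

    def labels(self) -> list:
        return [r.label for r in self.records]

    def subset(self, indices: Iterable[int]) -> "CohortTable":
        idx = list(indices)
        return CohortTable(
            [self.records[i] for i in idx],
            provenance=self.provenance,
            seed=self.seed,
        )

    def group(self, label: str) -> "CohortTable":
        return CohortTable(
            [r for r in self.records if r.label == label],
            provenance=self.provenance,
            seed=self.seed,
        )

    def feature_values(self, name: str) -> pd.Series:
        return self.to_frame()[name]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: driver_id, group, the nine features, perception time."""
        rows = []
        for r in self.records:
            row = {"driver_id": r.driver_id, "group": r.label}
            for f in FEATURES:
                row[f] = r.features.get(f)
            row["perception_time_s"] = r.perception_time_s
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, provenance: str = "loaded", seed: int | None = None
    ) -> "CohortTable":
        records = []
        for _, row in frame.iterrows():
            feats = {
                f: (None if pd.isna(row[f]) else float(row[f]))
                for f in FEATURES
                if f in frame.columns
            }
            pt = row.get("perception_time_s")
            records.append(
                DriverRecord(
                    driver_id=str(row["driver_id"]),
                    label=str(row.get("group", "unknown")),
                    features=feats,
                    perception_time_s=None if pd.isna(pt) else float(pt),
                )
            )
        return cls(records, provenance=provenance, seed=seed)

    def with_labels(self, labels: Mapping[str, str]) -> "CohortTable":
        """Return a copy whose labels are replaced from ``driver_id -> label``."""
        return CohortTable(
            [replace(r, label=labels.get(r.driver_id, r.label)) for r in self.records],
            provenance=self.provenance,
            seed=self.seed,
        )
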