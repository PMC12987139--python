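"""Delimited-text readers/writers for cohorts, series, reports and models.

All formats are plain text.  Cohort tables are CSV with one row per driver
(scientific notation accepted for EEG powers); band-power series are CSV
with a single comment header naming the driver, band and sampling rate;
calibrated screening models round-trip through YAML so a calibrated
screener is a portable artifact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from omenscreen.changepoint import BandPowerSeries
from omenscreen.cohort import CohortTable
from omenscreen.labeling import InterviewResponse
from omenscreen.sem import PdoModel

__all__ = [
    "read_cohort",
    "read_interviews",
    "read_pdo_model",
    "read_series",
    "write_cohort",
    "write_detections",
    "write_pdo_model",
    "write_series",
]


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path) -> CohortTable:
    return CohortTable.from_frame(pd.read_csv(path), provenance=str(path))


def write_series(series: BandPowerSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# driver={series.driver_id} band={series.band} "
            f"sampling_rate_hz={series.sampling_rate_hz:g}\n"
        )
        fh.write("time_s,power\n")
        for i, v in enumerate(series.values):
            fh.write(f"{series.time_of(i):.6f},{v:.10e}\n")


def read_series(path) -> BandPowerSeries:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing '# driver=... band=...' header line")
    meta = dict(tok.split("=", 1) for tok in header[1:].split())
    table = pd.read_csv(path, comment="#")
    return BandPowerSeries(
        driver_id=meta["driver"],
        band=meta["band"],
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        start_time_s=float(table["time_s"].iloc[0]),
        values=table["power"].to_numpy(dtype=float),
    )


def write_detections(detections, path) -> None:
    rows = [
        {
            "driver_id": d.driver_id, "band": d.band, "time_s": d.time_s,
            "W": d.scan_statistic, "C": d.critical_value,
            "theta_hat": d.jump, "significant": d.significant,
        }
        for d in detections
    ]
    pd.DataFrame(
        rows,
        columns=["driver_id", "band", "time_s", "W", "C", "theta_hat", "significant"],
    ).to_csv(path, index=False)


def read_interviews(path) -> list:
    table = pd.read_csv(path)
    return [
        InterviewResponse(
            driver_id=str(r["driver_id"]),
            response=str(r["response"]),
            hazard_time_s=float(r["hazard_time_s"]),
        )
        for _, r in table.iterrows()
    ]


def write_pdo_model(model: PdoModel, path) -> None:
    doc = {
        "mode": model.mode,
        "lambda_bio": {k: float(v) for k, v in model.lambda_bio.items()},
        "lambda_eye": {k: float(v) for k, v in model.lambda_eye.items()},
        "rho": [float(r) for r in model.rho],
        "threshold": float(model.threshold),
        "standardization": (
            None
            if model.standardization is None
            else {k: [float(m), float(s)] for k, (m, s) in model.standardization.items()}
        ),
        "bounds": None if model.bounds is None else [float(b) for b in model.bounds],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_pdo_model(path) -> PdoModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    std = doc.get("standardization")
    bounds = doc.get("bounds")
    return PdoModel(
        lambda_bio=doc["lambda_bio"],
        lambda_eye=doc["lambda_eye"],
        rho=tuple(doc["rho"]),
        standardization=None if std is None else {k: tuple(v) for k, v in std.items()},
        bounds=None if bounds is None else tuple(bounds),
        threshold=doc["threshold"],
        mode=doc.get("mode", "published"),
    )
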