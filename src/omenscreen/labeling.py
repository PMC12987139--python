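"""Fusion of change-point detections and interview responses into labels.

A driver is labeled D2 (able to perceive dangerous omens) only when two
conditions hold jointly: at least one band shows a *significant* change
point inside the hazard window, and the driver confirmed perceiving the
omen in the post-drive interview.  Everything else — no detection, a
"no", or an ambiguous answer — yields D1.  Ambiguous responses map to D1
deliberately: a driver who cannot articulate having perceived the omen is
treated as not having perceived it.

When several bands fire, significant in-window detections are clustered
by time (single-linkage with a configurable gap) and the earliest cluster
representative defines the perception moment: the omen precedes the
hazard, so the earliest neural response is the quantity of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "InterviewResponse",
    "PerceptionLabel",
    "cluster_detections",
    "default_hazard_window",
    "fuse_label",
]

RESPONSES = ("yes", "no", "ambiguous")

#: Seconds before the hazard onset still counted as omen perception,
#: reflecting the typical 3-6 s anticipation horizon.
DEFAULT_PRE_MARGIN_S = 6.0


@dataclass(frozen=True)
class InterviewResponse:
    driver_id: str
    response: str
    hazard_time_s: float

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(
                f"response must be one of {RESPONSES}, got {self.response!r}"
            )
        if self.hazard_time_s < 0:
            raise ValueError("hazard_time_s must be >= 0")


@dataclass(frozen=True)
class PerceptionLabel:
    driver_id: str
    label: str
    perception_time_s: float | None = None
    bands: frozenset = field(default_factory=frozenset)
    #: significant detections outside the hazard window, kept for diagnostics
    out_of_window: tuple = ()

    def __post_init__(self) -> None:
        if self.label == "D2" and self.perception_time_s is None:
            raise ValueError("D2 labels must carry a perception time")
        if self.label == "D1" and self.perception_time_s is not None:
            raise ValueError("D1 labels must not carry a perception time")


def default_hazard_window(
    hazard_start_s: float,
    hazard_end_s: float | None = None,
    pre_margin_s: float = DEFAULT_PRE_MARGIN_S,
):
    """Window ``[start - pre_margin, end]`` in which detections count as
    omen perception."""
    end = hazard_start_s if hazard_end_s is None else hazard_end_s
    if end < hazard_start_s:
        raise ValueError("hazard window must be well-ordered")
    return (hazard_start_s - pre_margin_s, end)


def cluster_detections(detections, gap: float = 1.0):
    """Single-linkage time clustering of detections.

    Detections are sorted by time and merged whenever consecutive times
    differ by at most ``gap`` seconds.  Returns a list of clusters (lists
    of detections), each sorted by time so its first element is the
    representative.
    """
    if gap <= 0:
        raise ValueError("gap must be > 0")
    ordered = sorted(detections, key=lambda r: r.time_s)
    clusters = []
    for det in ordered:
        if clusters and det.time_s - clusters[-1][-1].time_s <= gap:
            clusters[-1].append(det)
        else:
            clusters.append([det])
    return clusters


def fuse_label(
    detections,
    interview: InterviewResponse,
    hazard_window,
    gap: float = 1.0,
) -> PerceptionLabel:
    """Combine per-band detections with an interview response.

    Parameters
    ----------
    detections : mapping band -> list of ChangePointResult, or a flat list
    interview : InterviewResponse
    hazard_window : (start_s, end_s)
        Time window in which a significant detection counts as omen
        perception (see :func:`default_hazard_window`).
    gap : float
        Clustering gap in seconds for multi-band agreement.
    """
    if hasattr(detections, "values") and not isinstance(detections, list):
        flat = [d for band in detections.values() for d in band]
    else:
        flat = list(detections)
    drivers = {d.driver_id for d in flat}
    if drivers and drivers != {interview.driver_id}:
        raise ValueError(
            f"detections refer to drivers {sorted(drivers)} but the interview "
            f"is for {interview.driver_id!r}"
        )
    lo, hi = hazard_window
    if hi < lo:
        raise ValueError("hazard window must be well-ordered")
    significant = [d for d in flat if d.significant]
    in_window = [d for d in significant if lo <= d.time_s <= hi]
    outside = tuple(d for d in significant if not (lo <= d.time_s <= hi))
    if not in_window or interview.response != "yes":
        return PerceptionLabel(
            driver_id=interview.driver_id, label="D1", out_of_window=outside
        )
    first = cluster_detections(in_window, gap=gap)[0]
    return PerceptionLabel(
        driver_id=interview.driver_id,
        label="D2",
        perception_time_s=first[0].time_s,
        bands=frozenset(d.band for d in first),
        out_of_window=outside,
    )
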