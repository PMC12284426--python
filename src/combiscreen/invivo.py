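"""Tumor volumetrics, trial logic and survival analysis for mouse cohorts.

Tumors imaged sonographically in three orthogonal axes are summarized by the
ellipsoid approximation V = ½ · width · depth · height (mm³). Trial logic
follows the standard preclinical protocol for spontaneous abdominal tumors:

* treatment starts ("day 0") at the first scan where the maximal tumor
  diameter reaches 5 mm;
* animals are euthanized when the maximal diameter reaches 15 mm;
* the per-animal response at day x is 100 · (b_x − a) / a, where a is the
  volume on the trigger day and b_x the volume at day x (−100% = complete
  regression) — the quantity plotted on spider plots;
* a relapse is a volume rebound (≥ ``RELAPSE_MM3``) after the tumor had
  regressed below ``REGRESSION_MM3`` (a proxy for "sonographically
  undetectable").

Kaplan–Meier curves and the Mantel–Cox log-rank test are computed with
lifelines behind this module's small survival surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import DomainError, InsufficientDataError, UndefinedTestError

#: treatment-trigger threshold on the maximal tumor diameter, mm
TRIGGER_MM = 5.0
#: humane-endpoint threshold on the maximal tumor diameter, mm
ENDPOINT_MM = 15.0
#: volume below which a tumor counts as regressed (undetectable proxy), mm³
REGRESSION_MM3 = 1.0
#: volume at/above which a previously regressed tumor counts as relapsed, mm³
RELAPSE_MM3 = 10.0
#: a response query day may match a scan at most this many days away
DAY_TOLERANCE = 2

EVENT_STATUSES = ("death", "euthanized", "censored")


def tumor_volume(width: float, depth: float, height: float) -> float:
    """Ellipsoid tumor volume ½·w·d·h (mm³ for mm axes); axis-symmetric."""
    for axis in (width, depth, height):
        if axis < 0:
            raise DomainError(f"tumor axes must be >= 0, got {axis}")
    return 0.5 * width * depth * height


@dataclass
class TumorMeasurement:
    """One scan: three orthogonal diameters (mm) on a given study day."""

    subject_id: str
    day: int
    width: float
    depth: float
    height: float

    @property
    def volume(self) -> float:
        return tumor_volume(self.width, self.depth, self.height)

    @property
    def max_diameter(self) -> float:
        return max(self.width, self.depth, self.height)


def treatment_trigger(m: TumorMeasurement) -> bool:
    """True once the maximal diameter reaches the 5 mm treatment threshold."""
    return m.max_diameter >= TRIGGER_MM


def endpoint_check(m: TumorMeasurement) -> bool:
    """True once the maximal diameter reaches the 15 mm humane endpoint."""
    return m.max_diameter >= ENDPOINT_MM


@dataclass
class TumorTrack:
    """One animal's measurement series plus its survival event.

    ``event`` is ``(day, status)`` with status in ``death | euthanized |
    censored``. Measurements are kept day-ordered; days are relative to the
    animal's own timeline (the simulator and readers place the treatment
    trigger at day 0, with pre-trigger scans at negative days).
    """

    subject_id: str
    arm: str
    measurements: list[TumorMeasurement] = field(default_factory=list)
    event: tuple[int, str] | None = None

    def __post_init__(self):
        self.measurements.sort(key=lambda m: m.day)
        if self.event is not None and self.event[1] not in EVENT_STATUSES:
            raise DomainError(f"unknown event status {self.event[1]!r}")

    def baseline(self) -> TumorMeasurement:
        """First measurement satisfying the treatment trigger."""
        for m in self.measurements:
            if treatment_trigger(m):
                return m
        raise InsufficientDataError(
            f"{self.subject_id}: no measurement reaches the "
            f"{TRIGGER_MM} mm treatment trigger"
        )

    def measurement_at(self, day: int) -> TumorMeasurement:
        """Measurement at ``day``, or the nearest within ±DAY_TOLERANCE days."""
        best = None
        for m in self.measurements:
            gap = abs(m.day - day)
            if gap <= DAY_TOLERANCE and (best is None or gap < abs(best.day - day)):
                best = m
        if best is None:
            raise InsufficientDataError(
                f"{self.subject_id}: no measurement within ±{DAY_TOLERANCE} "
                f"days of day {day}"
            )
        return best


def tumor_response(track: TumorTrack, day: int) -> float:
    """Spider-plot response % at ``day``: 100 · (b_x − a) / a.

    ``a`` is the baseline (trigger-day) volume, ``b_x`` the volume at the
    requested day (nearest scan within ±2 days). −100% means the tumor is
    gone; +1400% means 15-fold growth.
    """
    base = track.baseline()
    a = base.volume
    if a <= 0:
        raise InsufficientDataError(
            f"{track.subject_id}: baseline volume must be positive, got {a}"
        )
    b = track.measurement_at(day).volume
    return 100.0 * (b - a) / a


def detect_relapse(track: TumorTrack) -> list[int]:
    """Days on which a regressed tumor rebounded.

    A relapse day is the first scan with volume ≥ RELAPSE_MM3 after a prior
    scan with volume < REGRESSION_MM3; repeated regression–rebound cycles
    each contribute one day.
    """
    if len(track.measurements) < 2:
        raise InsufficientDataError(
            f"{track.subject_id}: relapse detection needs >= 2 measurements"
        )
    days = []
    regressed = False
    for m in track.measurements:
        v = m.volume
        if v < REGRESSION_MM3:
            regressed = True
        elif regressed and v >= RELAPSE_MM3:
            days.append(m.day)
            regressed = False
    return days


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate: step times, S(t), and risk set."""

    times: list[float]
    survival: list[float]
    at_risk: list[int]


def _durations_observed(events):
    events = list(events)
    if not events:
        raise InsufficientDataError("survival analysis needs >= 1 subject")
    durations, observed = [], []
    for day, status in events:
        if status not in EVENT_STATUSES:
            raise DomainError(f"unknown event status {status!r}")
        durations.append(float(day))
        observed.append(status != "censored")
    return np.array(durations), np.array(observed)


def km_curve(events) -> SurvivalCurve:
    """Kaplan–Meier product-limit curve from (day, status) pairs.

    ``death`` and ``euthanized`` count as events; ``censored`` subjects leave
    the risk set without a survival drop.
    """
    durations, observed = _durations_observed(events)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    times = [float(t) for t in sf.index]
    survival = [float(s) for s in sf.iloc[:, 0]]
    at_risk = [int(kmf.event_table.loc[t, "at_risk"]) for t in sf.index]
    return SurvivalCurve(times=times, survival=survival, at_risk=at_risk)


def logrank_test(groups) -> tuple[float, float]:
    """Mantel–Cox log-rank test across ≥2 groups of (day, status) pairs.

    Returns the chi-square statistic (k−1 degrees of freedom for k groups)
    and its two-sided p-value.
    """
    groups = [list(g) for g in groups]
    if len(groups) < 2:
        raise UndefinedTestError("log-rank test needs >= 2 groups")
    durations, observed, labels = [], [], []
    for i, g in enumerate(groups):
        d, o = _durations_observed(g)
        durations.append(d)
        observed.append(o)
        labels.append(np.full(d.shape, i))
    durations = np.concatenate(durations)
    observed = np.concatenate(observed)
    labels = np.concatenate(labels)
    if not observed.any():
        raise UndefinedTestError("log-rank test is undefined with zero events")
    res = multivariate_logrank_test(durations, labels, observed)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# I/O


def read_measurements(path) -> list[TumorTrack]:
    """Read a measurement CSV (subject_id,arm,day,width,depth,height,unit).

    Axis units may be mm or cm; cm values are converted to mm on ingest.
    """
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str, "arm": str})
    required = ["subject_id", "arm", "day", "width", "depth", "height"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"measurement table missing column(s) {missing}")
    tracks: dict[str, TumorTrack] = {}
    for _, row in df.iterrows():
        unit = str(row.get("unit", "mm"))
        scale = {"mm": 1.0, "cm": 10.0}.get(unit)
        if scale is None:
            raise DomainError(f"unknown axis unit {unit!r} (use mm or cm)")
        sid = str(row["subject_id"])
        if sid not in tracks:
            tracks[sid] = TumorTrack(subject_id=sid, arm=str(row["arm"]))
        tracks[sid].measurements.append(
            TumorMeasurement(
                subject_id=sid,
                day=int(row["day"]),
                width=float(row["width"]) * scale,
                depth=float(row["depth"]) * scale,
                height=float(row["height"]) * scale,
            )
        )
    for t in tracks.values():
        t.measurements.sort(key=lambda m: m.day)
    return list(tracks.values())


def read_events(path) -> dict[str, tuple[str, int, str]]:
    """Read an events CSV (subject_id,arm,event_day,status) keyed by subject."""
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str, "arm": str})
    required = ["subject_id", "arm", "event_day", "status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"events table missing column(s) {missing}")
    out = {}
    for _, row in df.iterrows():
        status = str(row["status"])
        if status not in EVENT_STATUSES:
            raise DomainError(f"unknown event status {status!r}")
        out[str(row["subject_id"])] = (str(row["arm"]), int(row["event_day"]), status)
    return out


def attach_events(tracks: list[TumorTrack], events: dict[str, tuple[str, int, str]]):
    """Attach (day, status) events to their tracks in place."""
    for t in tracks:
        if t.subject_id in events:
            _arm, day, status = events[t.subject_id]
            t.event = (day, status)
    return tracks
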