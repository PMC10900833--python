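"""The five simulated kidney-replacement-therapy (KRT) timelines.

Settings
--------
1. Thrice-weekly (Mon/Wed/Fri) 4-h hemodialysis (HD) at Qd 300 mL/min.
2. Daily 4-h HD at Qd 300 mL/min.
3. Daily sequential therapy: 4-h HD at Qd 300 immediately followed by
   20-h ultrafiltration (UF) at Quf 5 mL/min.
4. Daily 9-h prolonged intermittent KRT (PIKRT) at Qd 100 mL/min, with an
   "early" variant (first dose at PIKRT start) and a "late" variant
   (first dose 15 h before PIKRT).
5. Daily 24-h extended PIKRT at Qd 50 mL/min (continuous coverage).

Clock convention: t = 0 is the start of the first KRT session of the week
(settings 1-3, 4-early, 5); sessions recur at the same clock time daily
(every 48 h Mon/Wed/Fri for setting 1).  For setting 4-late the origin is
the first dose and the first session starts at t = 15 h.  Sessions repeat
past 168 h so that the seventh therapy day (which ends a few hours after
the KRT week when dosing starts post-HD) sees the next week's sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .drug_params import VirtualPatient

__all__ = [
    "KRTSession",
    "KRTSchedule",
    "ClearanceTimeline",
    "build_setting",
    "transmembrane_clearance",
    "clearance_timeline",
    "ML_MIN_TO_L_H",
    "SETTING_LABELS",
]

#: 1 mL/min = 0.06 L/h.
ML_MIN_TO_L_H = 0.06

WEEK_H = 168.0

SETTING_LABELS = {
    "1": "thrice-weekly 4-h HD (Qd 300)",
    "2": "daily 4-h HD (Qd 300)",
    "3": "daily 4-h HD (Qd 300) + 20-h UF (Quf 5)",
    "4early": "early 9-h PIKRT (Qd 100)",
    "4late": "late 9-h PIKRT (Qd 100)",
    "5": "extended 24-h PIKRT (Qd 50)",
}


@dataclass(frozen=True)
class KRTSession:
    """One extracorporeal therapy session.

    ``effluent_rate`` is Qd (mL/min) for HD and Quf (mL/min) for UF; the
    modality decides whether a saturation (SA) or sieving (SC) coefficient
    converts it into transmembrane clearance.
    """

    start: float
    duration: float
    modality: str  # "HD" | "UF"
    effluent_rate: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("session duration must be > 0")
        if self.modality not in ("HD", "UF"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class KRTSchedule:
    """A week-plus timeline of KRT sessions and its dose-anchoring policy."""

    name: str
    sessions: Tuple[KRTSession, ...]
    dose_anchor: str  # post_first_HD | at_PIKRT_start | 15h_before_PIKRT | at_origin
    first_dose_time: float
    horizon: float

    def __post_init__(self) -> None:
        ordered = sorted(self.sessions, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"overlapping sessions at t={b.start}")

    def session_at(self, t: float) -> Optional[KRTSession]:
        """Session covering time ``t`` (session intervals are [start, end))."""
        for s in self.sessions:
            if s.start <= t < s.end:
                return s
        return None

    def total_session_hours(self, t_max: Optional[float] = None) -> float:
        t_max = self.horizon if t_max is None else t_max
        return sum(
            max(0.0, min(s.end, t_max) - s.start) for s in self.sessions if s.start < t_max
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular audit view (start/stop/modality/effluent rate)."""
        return pd.DataFrame(
            {
                "start_h": [s.start for s in self.sessions],
                "stop_h": [s.end for s in self.sessions],
                "modality": [s.modality for s in self.sessions],
                "effluent_ml_min": [s.effluent_rate for s in self.sessions],
            }
        )


def _recurring(starts_in_week, duration, modality, rate, horizon, offset=0.0):
    sessions = []
    week = 0
    while True:
        base = week * WEEK_H + offset
        if base >= horizon:
            break
        for s0 in starts_in_week:
            start = base + s0
            if start >= horizon:
                continue
            dur = min(duration, horizon - start)
            sessions.append(KRTSession(start, dur, modality, rate))
        week += 1
    return sessions


def build_setting(
    setting_id: int, variant: Optional[str] = None, horizon: float = 180.0
) -> KRTSchedule:
    """Build one of the five KRT schedules.

    ``variant`` ("early" | "late") is meaningful only for setting 4.
    ``horizon`` extends session recurrence past one week so day-7 metrics
    (anchored at the first dose, up to 4 h after the KRT week starts) see
    the next cycle's sessions.
    """
    if variant not in (None, "early", "late"):
        raise ValueError(f"unknown variant {variant!r}")
    if setting_id != 4 and variant is not None:
        raise ValueError("variant applies to setting 4 only")

    daily = [24.0 * d for d in range(7)]
    if setting_id == 1:
        sessions = _recurring([0.0, 48.0, 96.0], 4.0, "HD", 300.0, horizon)
        return KRTSchedule("1", tuple(sessions), "post_first_HD", 4.0, horizon)
    if setting_id == 2:
        sessions = _recurring(daily, 4.0, "HD", 300.0, horizon)
        return KRTSchedule("2", tuple(sessions), "post_first_HD", 4.0, horizon)
    if setting_id == 3:
        hd = _recurring(daily, 4.0, "HD", 300.0, horizon)
        uf = _recurring([d + 4.0 for d in daily], 20.0, "UF", 5.0, horizon)
        sessions = sorted(hd + uf, key=lambda s: s.start)
        return KRTSchedule("3", tuple(sessions), "post_first_HD", 4.0, horizon)
    if setting_id == 4:
        if variant is None:
            raise ValueError("setting 4 requires variant='early' or 'late'")
        if variant == "early":
            sessions = _recurring(daily, 9.0, "HD", 100.0, horizon)
            return KRTSchedule("4early", tuple(sessions), "at_PIKRT_start", 0.0, horizon)
        sessions = _recurring(daily, 9.0, "HD", 100.0, horizon, offset=15.0)
        return KRTSchedule("4late", tuple(sessions), "15h_before_PIKRT", 0.0, horizon)
    if setting_id == 5:
        sessions = _recurring(daily, 24.0, "HD", 50.0, horizon)
        return KRTSchedule("5", tuple(sessions), "at_origin", 0.0, horizon)
    raise ValueError(f"unknown setting id {setting_id}")


def build_setting_by_key(key: str, horizon: float = 180.0) -> KRTSchedule:
    """Build a schedule from a compact key: '1','2','3','4early','4late','5'."""
    key = str(key)
    if key.startswith("4"):
        variant = key[1:] or None
        return build_setting(4, variant, horizon)
    return build_setting(int(key), None, horizon)


def transmembrane_clearance(coef: float, effluent_rate: float) -> float:
    """Transmembrane clearance (mL/min) = extraction coefficient x effluent flow.

    ``CL_HD = SA * Qd`` for dialysis, ``CL_UF = SC * Quf`` for ultrafiltration.
    """
    if not 0.0 <= coef <= 1.0:
        raise ValueError(f"extraction coefficient must be in [0, 1], got {coef}")
    if effluent_rate < 0:
        raise ValueError("effluent rate must be >= 0")
    return coef * effluent_rate


@dataclass(frozen=True)
class ClearanceTimeline:
    """Piecewise-constant total clearance: value[i] holds on [times[i], times[i+1])."""

    times: np.ndarray  # breakpoints, h; len m+1
    values: np.ndarray  # mL/min; len m

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        i = min(max(i, 0), self.values.size - 1)
        return float(self.values[i])

    @property
    def values_l_per_h(self) -> np.ndarray:
        return self.values * ML_MIN_TO_L_H


def _session_coef(patient: VirtualPatient, session: KRTSession) -> float:
    if session.modality == "HD":
        qd = int(session.effluent_rate)
        if qd not in patient.sa:
            raise KeyError(
                f"patient has no saturation coefficient for Qd {qd} mL/min"
            )
        return patient.sa[qd]
    return patient.sc


def clearance_timeline(
    patient: VirtualPatient, schedule: KRTSchedule, t_max: Optional[float] = None
) -> ClearanceTimeline:
    """Total clearance (mL/min) over time for one patient under a schedule.

    Inside a session, clearance = CL_NR + coef x effluent rate; between
    sessions only the non-renal clearance CL_NR remains (anuric patients).
    Breakpoints fall exactly at session boundaries.
    """
    t_max = schedule.horizon if t_max is None else t_max
    breaks = {0.0, t_max}
    for s in schedule.sessions:
        if s.start < t_max:
            breaks.add(s.start)
            breaks.add(min(s.end, t_max))
    times = np.array(sorted(breaks))
    values = np.empty(times.size - 1)
    for i, (t0, t1) in enumerate(zip(times[:-1], times[1:])):
        mid = 0.5 * (t0 + t1)
        sess = schedule.session_at(mid)
        cl = patient.cl_nr
        if sess is not None:
            cl += transmembrane_clearance(_session_coef(patient, sess), sess.effluent_rate)
        values[i] = cl
    return ClearanceTimeline(times=times, values=values)
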