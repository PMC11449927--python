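"""Night-level lnRMSSD extraction from wearable RR + EDA streams.

A recording session carries a stream of interbeat (RR) intervals and a 4 Hz
electrodermal activity (EDA) channel. Extraction proceeds as:

1. off-body detection — EDA below 0.05 μS marks the device as not worn;
2. selection of the first full 22:00–05:00 night window after session start;
3. 5-minute sliding windows advanced in 1-minute steps over the night;
4. per-window quality control and RMSSD (root mean square of successive
   RR differences);
5. the night value is the mean RMSSD over valid windows, reported on the
   natural-log scale (lnRMSSD).

Quality control flags a window when it overlaps an off-body (or non-sleep)
interval, contains too few beats, or has an excess of implausibly large
successive differences; flagged windows contribute no RMSSD.

All within-session times are seconds since ``session_start``; clock
arithmetic (night boundaries) happens in the session's own timezone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyInputError,
    InsufficientDataError,
    IntervalError,
    NoNightError,
    NoValidWindowError,
)

__all__ = [
    "RawRecording",
    "WindowResult",
    "NightHRV",
    "QCConfig",
    "detect_off_body",
    "select_first_night",
    "sliding_windows",
    "rmssd",
    "window_qc",
    "night_lnrmssd",
    "read_session",
    "write_night_hrv_csv",
]

OFF_BODY_THRESHOLD_US = 0.05
NIGHT_START = time(22, 0)
NIGHT_END = time(5, 0)


@dataclass
class RawRecording:
    """One session's RR and EDA streams.

    ``rr`` is an (n, 2) array of (onset time s, RR interval ms); ``eda`` an
    (m, 2) array of (time s, conductance μS); times are seconds since
    ``session_start``, which must be timezone-aware.
    """

    rr: np.ndarray
    eda: np.ndarray
    session_start: datetime
    session_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float).reshape(-1, 2)
        self.eda = np.asarray(self.eda, dtype=float).reshape(-1, 2)
        if self.session_start.tzinfo is None:
            raise DomainError("session_start must carry a timezone")
        if self.rr.size and np.any(np.diff(self.rr[:, 0]) <= 0):
            raise DomainError("RR onset times must be strictly increasing")
        if self.rr.size and np.any(self.rr[:, 1] <= 0):
            raise DomainError("RR intervals must be positive")
        if self.eda.size and np.any(np.diff(self.eda[:, 0]) < 0):
            raise DomainError("EDA times must be nondecreasing")


@dataclass
class WindowResult:
    start: datetime
    end: datetime
    n_intervals: int
    rmssd: float | None
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def valid(self) -> bool:
        return not self.qc_flags


@dataclass
class NightHRV:
    """Night-level summary with window-QC accounting."""

    subject_id: str
    session_id: str
    night_date: str
    ln_rmssd: float
    mean_rmssd: float
    n_valid_windows: int
    n_total_windows: int

    @property
    def invalid_fraction(self) -> float:
        return 1.0 - self.n_valid_windows / self.n_total_windows


@dataclass
class QCConfig:
    """Window quality-control thresholds.

    ``min_beats``: fewer RR intervals than this flags ``too_few_beats``
    (150 over 5 min is a ~30 bpm floor). ``artifact_diff_ms`` /
    ``artifact_fraction``: a window where more than the given fraction of
    absolute successive differences exceed the threshold is flagged
    ``artifact_excess``.
    """

    min_beats: int = 150
    artifact_diff_ms: float = 250.0
    artifact_fraction: float = 0.2


def detect_off_body(
    eda: np.ndarray, threshold: float = OFF_BODY_THRESHOLD_US
) -> list[tuple[float, float]]:
    """Maximal intervals during which every EDA sample is below threshold.

    Each below-threshold sample covers ``[t, t + dt)`` where ``dt`` is the
    median sampling period; maximal runs of such samples are merged into one
    interval. Returns disjoint, sorted (start_s, end_s) pairs.
    """
    eda = np.asarray(eda, dtype=float).reshape(-1, 2)
    if eda.size == 0:
        raise EmptyInputError("EDA stream is empty")
    t = eda[:, 0]
    below = eda[:, 1] < threshold
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.25
    intervals: list[tuple[float, float]] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = t[i]
        elif not b and start is not None:
            intervals.append((start, t[i - 1] + dt))
            start = None
    if start is not None:
        intervals.append((start, t[-1] + dt))
    return intervals


def select_first_night(
    recording: RawRecording,
    night_start: time = NIGHT_START,
    night_end: time = NIGHT_END,
) -> tuple[tuple[float, float], np.ndarray]:
    """First complete night window at or after session start, plus its RR.

    The night runs from the first ``night_start`` clock time that is not
    before ``session_start`` to the following ``night_end``; a session
    beginning mid-night therefore waits for the next complete window.
    Returns ((start_s, end_s) offsets, RR rows with onset inside the window).
    """
    s0 = recording.session_start
    candidate = datetime.combine(s0.date(), night_start, tzinfo=s0.tzinfo)
    if candidate < s0:
        candidate += timedelta(days=1)
    end = datetime.combine(candidate.date(), night_end, tzinfo=s0.tzinfo)
    if end <= candidate:
        end += timedelta(days=1)
    start_s = (candidate - s0).total_seconds()
    end_s = (end - s0).total_seconds()
    if recording.rr.size == 0 or recording.rr[-1, 0] <= start_s:
        raise NoNightError(
            f"recording ends before the first {night_start:%H:%M} night window"
        )
    mask = (recording.rr[:, 0] >= start_s) & (recording.rr[:, 0] < end_s)
    return (start_s, end_s), recording.rr[mask]


def sliding_windows(
    interval: tuple[float, float],
    length_s: float = 300.0,
    step_s: float = 60.0,
) -> list[tuple[float, float]]:
    """Sliding windows from interval start; last window ends at or before end."""
    start, end = interval
    if end - start < length_s:
        return []
    n = int(math.floor((end - start - length_s) / step_s)) + 1
    return [(start + k * step_s, start + k * step_s + length_s) for k in range(n)]


def rmssd(rr: Sequence[float]) -> float:
    """Root mean square of successive RR-interval differences (ms).

    ``sqrt( sum (R[i+1]-R[i])^2 / (N-1) )`` over N intervals.
    """
    arr = np.asarray(rr, dtype=float)
    if arr.ndim != 1:
        raise DomainError("rmssd expects a flat sequence of RR intervals")
    n = arr.size
    if n < 2:
        raise InsufficientDataError("RMSSD requires at least two RR intervals")
    d = np.diff(arr)
    return float(np.sqrt(np.sum(d * d) / (n - 1)))


def _overlaps(window: tuple[float, float], intervals) -> bool:
    ws, we = window
    return any(s < we and ws < e for s, e in intervals)


def window_qc(
    window: tuple[float, float],
    rr: np.ndarray,
    off_body: Sequence[tuple[float, float]] = (),
    start_dt: datetime | None = None,
    qc: QCConfig | None = None,
) -> WindowResult:
    """Quality-control one window; never raises, only flags.

    ``rr`` is the full (onset_s, rr_ms) array; intervals are assigned to the
    window by onset time, half-open [start, end).
    """
    qc = qc or QCConfig()
    ws, we = window
    rr = np.asarray(rr, dtype=float).reshape(-1, 2)
    inside = rr[(rr[:, 0] >= ws) & (rr[:, 0] < we), 1]
    flags = set()
    if _overlaps(window, off_body):
        flags.add("off_body_overlap")
    if inside.size < qc.min_beats:
        flags.add("too_few_beats")
    if inside.size >= 2:
        d = np.abs(np.diff(inside))
        if np.mean(d > qc.artifact_diff_ms) > qc.artifact_fraction:
            flags.add("artifact_excess")
    mk = lambda s: (start_dt + timedelta(seconds=s - ws)) if start_dt else None
    return WindowResult(
        start=mk(ws),
        end=mk(we),
        n_intervals=int(inside.size),
        rmssd=rmssd(inside) if not flags else None,
        qc_flags=frozenset(flags),
    )


def night_lnrmssd(
    recording: RawRecording,
    off_body: Sequence[tuple[float, float]] | None = None,
    sleep_intervals: Sequence[tuple[float, float]] | None = None,
    eda_threshold: float = OFF_BODY_THRESHOLD_US,
    window_s: float = 300.0,
    step_s: float = 60.0,
    qc: QCConfig | None = None,
) -> NightHRV:
    """Full extraction for one session: first night's mean valid-window RMSSD, logged.

    ``off_body`` defaults to EDA-threshold detection on the recording's own
    stream. When ``sleep_intervals`` are supplied, time outside them is
    masked exactly like off-body time; otherwise the whole clock window
    counts as sleep.
    """
    if off_body is None:
        off_body = detect_off_body(recording.eda, eda_threshold)
    (start_s, end_s), rr_night = select_first_night(recording)
    masked = list(off_body)
    if sleep_intervals is not None:
        masked.extend(_complement(sleep_intervals, start_s, end_s))
    windows = sliding_windows((start_s, end_s), window_s, step_s)
    night_dt = recording.session_start + timedelta(seconds=start_s)
    results = [
        window_qc(
            w,
            rr_night,
            masked,
            start_dt=recording.session_start + timedelta(seconds=w[0]),
            qc=qc,
        )
        for w in windows
    ]
    valid = [r.rmssd for r in results if r.valid]
    if not valid:
        raise NoValidWindowError(
            f"session {recording.session_id}: no window passed quality control"
        )
    mean_rmssd = float(np.mean(valid))
    if mean_rmssd <= 0:
        raise DomainError("mean night RMSSD is zero; lnRMSSD undefined")
    return NightHRV(
        subject_id=recording.subject_id,
        session_id=recording.session_id,
        night_date=night_dt.date().isoformat(),
        ln_rmssd=float(np.log(mean_rmssd)),
        mean_rmssd=mean_rmssd,
        n_valid_windows=len(valid),
        n_total_windows=len(results),
    )


def _complement(
    intervals: Sequence[tuple[float, float]], start: float, end: float
) -> list[tuple[float, float]]:
    """Gaps of [start, end] not covered by the (validated) intervals."""
    ordered = sorted(intervals)
    for (a, b), (c, _) in zip(ordered, ordered[1:]):
        if b > c:
            raise IntervalError("sleep intervals overlap")
    gaps = []
    cursor = start
    for a, b in ordered:
        if a > cursor:
            gaps.append((cursor, min(a, end)))
        cursor = max(cursor, b)
    if cursor < end:
        gaps.append((cursor, end))
    return [(a, b) for a, b in gaps if b > a]


def read_session(session_dir, session_start: datetime, subject_id="", session_id="") -> RawRecording:
    """Read the ``rr.csv`` / ``eda.csv`` pair written by the simulator."""
    session_dir = Path(session_dir)
    rr = pd.read_csv(session_dir / "rr.csv")[["onset_time_s", "rr_ms"]].to_numpy()
    eda = pd.read_csv(session_dir / "eda.csv")[["time_s", "eda_uS"]].to_numpy()
    return RawRecording(
        rr=rr,
        eda=eda,
        session_start=session_start,
        session_id=session_id or session_dir.name,
        subject_id=subject_id,
    )


def write_night_hrv_csv(rows: Sequence[NightHRV], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "session_id": r.session_id,
                "ln_rmssd": r.ln_rmssd,
                "mean_rmssd": r.mean_rmssd,
                "n_valid_windows": r.n_valid_windows,
                "n_total_windows": r.n_total_windows,
                "invalid_fraction": r.invalid_fraction,
            }
            for r in rows
        ]
    ).to_csv(path, index=False)
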