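"""Recording I/O, analysis-window search and baseline assignment.

A recording is a uniformly sampled single-channel PPG trace with an absolute
time axis (seconds).  For every study day one contiguous 5-minute window is
selected near a target time; a window is accepted only if the fraction of
inter-pulse intervals discarded by the preprocessing rules stays at or below
the quality threshold (default 20%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: analysis window length (s)
SEGMENT_DURATION = 300.0
#: maximum fraction of discarded inter-pulse intervals for an accepted window
QUALITY_THRESHOLD = 0.20


class RecordingParseError(ValueError):
    """Raised when a recording file cannot be parsed into a valid trace."""


@dataclass
class PPGRecording:
    """Uniformly sampled PPG signal.

    Parameters
    ----------
    samples : ndarray
        PPG values, arbitrary units.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Absolute time of the first sample, seconds.
    events : dict
        Labelled absolute timestamps (e.g. ``injection1``, ``injection2``).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    def slice_time(self, start: float, duration: float) -> "PPGRecording":
        """Extract a sub-recording of ``duration`` seconds starting at absolute ``start``."""
        i0 = int(round((start - self.start_time) * self.fs))
        i1 = i0 + int(round(duration * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, self.samples.size)
        if i1 <= i0:
            raise ValueError("requested slice lies outside the recording")
        return PPGRecording(
            samples=self.samples[i0:i1],
            fs=self.fs,
            start_time=self.start_time + i0 / self.fs,
            events=self.events,
        )


@dataclass
class SegmentWindow:
    """One candidate/selected 5-minute analysis window."""

    participant_id: str
    day_index: int
    start: float
    duration: float = SEGMENT_DURATION
    discarded_ipi_fraction: float = float("nan")
    accepted: bool = False

    def __post_init__(self) -> None:
        if self.accepted and not (self.discarded_ipi_fraction <= QUALITY_THRESHOLD):
            raise ValueError(
                "accepted window must have discarded fraction <= "
                f"{QUALITY_THRESHOLD}, got {self.discarded_ipi_fraction}"
            )


@dataclass
class BaselineAssignment:
    participant_id: str
    baseline_day: int
    source: str  # "pre-injection" | "washout"

    def __post_init__(self) -> None:
        if self.baseline_day not in (0, 4):
            raise ValueError("baseline day must be 0 or 4")


def write_recording(recording: PPGRecording, path: str | Path) -> None:
    """Write a recording as a two-column CSV (``time_s, ppg``)."""
    df = pd.DataFrame({"time_s": recording.times, "ppg": recording.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(path: str | Path) -> PPGRecording:
    """Read a two-column ``time_s, ppg`` CSV into a :class:`PPGRecording`.

    The sampling rate is inferred from the median sample spacing.  Spacings
    larger than two sample periods are flagged as gaps in the log; outside
    flagged gaps the spacing must stay within half a sample period of the
    nominal one.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingParseError(f"{path}: no such file")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise RecordingParseError(f"{path}: empty file") from exc
    for col in ("time_s", "ppg"):
        if col not in df.columns:
            raise RecordingParseError(
                f"{path}: missing required column {col!r} (header row required)"
            )
    if len(df) < 2:
        raise RecordingParseError(f"{path}: fewer than two samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise RecordingParseError(
            f"{path}: non-monotonic time column at row {int(bad[0]) + 3}"  # 1-based incl. header
        )
    period = float(np.median(dt))
    fs = 1.0 / period
    gaps = np.flatnonzero(dt > 2.0 * period)
    if gaps.size:
        logger.warning(
            "%s: %d gap(s) in time column (first at t=%.3f s, %.3f s long)",
            path, gaps.size, t[gaps[0]], dt[gaps[0]],
        )
    regular = dt[dt <= 2.0 * period]
    if regular.size and np.max(np.abs(regular - period)) >= 0.5 * period:
        raise RecordingParseError(f"{path}: irregular sample spacing")
    return PPGRecording(samples=df["ppg"].to_numpy(dtype=float), fs=fs, start_time=float(t[0]))


def candidate_windows(
    recording: PPGRecording,
    target_time: float,
    tolerance: float,
    cap_time: Optional[float] = None,
    step: float = 30.0,
) -> list[float]:
    """Candidate window start times near ``target_time``.

    Starts lie on a ``step``-spaced grid anchored at the target, restricted to
    ``[target - tolerance, max(target - tolerance, target + tolerance - 300)]``
    and to spans the recording can host.  With ``cap_time`` given, no window
    may end after it.  Starts are ordered by distance to the target; ties go to
    the earlier start.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    lo = target_time - tolerance
    hi = max(lo, target_time + tolerance - SEGMENT_DURATION)
    lo = max(lo, recording.start_time)
    hi = min(hi, recording.end_time - SEGMENT_DURATION)
    if cap_time is not None:
        hi = min(hi, cap_time - SEGMENT_DURATION)
    if hi < lo:
        return []
    n_back = int(np.floor((target_time - lo) / step)) if step > 0 else 0
    n_fwd = int(np.floor((hi - target_time) / step)) if step > 0 else 0
    starts = {target_time + k * step for k in range(-n_back, n_fwd + 1)}
    starts &= {s for s in starts if lo <= s <= hi}
    if not starts:
        # grid missed the feasible interval entirely; fall back to its endpoint
        starts = {min(max(target_time, lo), hi)}
    return sorted(starts, key=lambda s: (abs(s - target_time), s))


def select_segment(
    candidates: Sequence[float],
    recording: PPGRecording,
    participant_id: str = "",
    day_index: int = -1,
    threshold: float = QUALITY_THRESHOLD,
) -> Optional[SegmentWindow]:
    """Pick the first candidate window whose discarded-IPI fraction is within the gate.

    The fraction is computed by the same preprocessing pipeline used for
    analysis (single source of truth).  If no candidate qualifies, the best
    (lowest-fraction) window is returned with ``accepted=False``; with no
    candidates at all the result is ``None``.
    """
    from . import ipi as ipi_mod

    best: Optional[SegmentWindow] = None
    for start in candidates:
        try:
            sub = recording.slice_time(start, SEGMENT_DURATION)
        except ValueError:
            continue
        if sub.duration < SEGMENT_DURATION - 1.0 / recording.fs:
            continue
        try:
            series = ipi_mod.extract_ipis(sub)
            frac = ipi_mod.gate_fraction(series, sub.start_time, sub.end_time)
        except (ipi_mod.SegmentQualityError, ValueError):
            frac = 1.0
        window = SegmentWindow(
            participant_id=participant_id,
            day_index=day_index,
            start=start,
            discarded_ipi_fraction=frac,
            accepted=frac <= threshold,
        )
        if window.accepted:
            return window
        if best is None or frac < best.discarded_ipi_fraction:
            best = window
    if best is None:
        logger.info("no candidate windows for %s day %s", participant_id, day_index)
    else:
        logger.info(
            "no window passed the %.0f%% gate for %s day %s (best %.1f%%)",
            100 * threshold, participant_id, day_index,
            100 * best.discarded_ipi_fraction,
        )
    return best


def assign_baseline(
    participant_id: str, accepted_days: Iterable[int]
) -> Optional[BaselineAssignment]:
    """Baseline = day 0 when available, else day 4, else no assignment."""
    days = set(accepted_days)
    if 0 in days:
        return BaselineAssignment(participant_id, 0, "pre-injection")
    if 4 in days:
        return BaselineAssignment(participant_id, 4, "washout")
    return None


def paired_inclusion(accepted_days: Iterable[int]) -> bool:
    """Whether a participant enters the paired analysis.

    Requires a baseline (day 0 or day 4) plus accepted days 1, 2 and 3.
    """
    days = set(accepted_days)
    return assign_baseline("", days) is not None and {1, 2, 3} <= days


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "day", "file"}
    missing = required - set(df.columns)
    if missing:
        raise RecordingParseError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
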