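"""Trough detection, inter-pulse intervals, rejection rules and interpolation.

Inter-pulse intervals (IPIs) are the differences between consecutive waveform
troughs.  An IPI is rejected when outside 0.4–2.0 s or when it differs from
its preceding (valid) interval by more than 20%; rejected positions are filled
by a natural cubic spline through the valid intervals for the features that
need a gap-free series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io_segments import PPGRecording

logger = logging.getLogger(__name__)

IPI_MIN = 0.4  # s, physiological lower bound
IPI_MAX = 2.0  # s, physiological upper bound
REL_TOL = 0.20  # max relative difference to the preceding interval
MIN_VALID_FOR_SPLINE = 4


class SegmentQualityError(ValueError):
    """Segment unusable for analysis (too few valid intervals)."""


@dataclass
class IPISeries:
    """Inter-pulse intervals of one segment with validity and interpolation.

    ``interpolated_ipis`` has the same length as ``raw_ipis``; interior
    invalid positions are spline-filled, edge positions that cannot be
    interpolated (before the first / after the last valid interval) are NaN.
    """

    trough_times: np.ndarray
    raw_ipis: np.ndarray
    valid_mask: np.ndarray
    interpolated_ipis: np.ndarray

    @property
    def clean_ipis(self) -> np.ndarray:
        return self.raw_ipis[self.valid_mask]

    @property
    def discarded_fraction(self) -> float:
        if self.raw_ipis.size == 0:
            return 1.0
        return 1.0 - float(np.count_nonzero(self.valid_mask)) / self.raw_ipis.size

    def successive_pairs(self) -> np.ndarray:
        """Differences of adjacent valid intervals (no pairing across gaps)."""
        both = self.valid_mask[:-1] & self.valid_mask[1:]
        return np.diff(self.raw_ipis)[both]

    def interpolated_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) of the gap-free series with NaN edges dropped."""
        ok = ~np.isnan(self.interpolated_ipis)
        return self.trough_times[:-1][ok], self.interpolated_ipis[ok]


def detect_troughs(recording: PPGRecording, refractory: float = IPI_MIN) -> np.ndarray:
    """Detect pulse trough times (seconds, absolute).

    Band-pass 0.5–8 Hz zero-phase filter, minima via peak search on the
    negated signal with a refractory distance, adaptive prominence gate at 30%
    of the median prominence, then refinement to the local raw-signal minimum.
    A flat (detached) signal yields an empty result, not an error.
    """
    if recording.fs < 16:
        raise ValueError(f"sampling rate too low for trough detection: {recording.fs} Hz")
    if recording.duration < 10.0:
        raise ValueError("recording shorter than 10 s")
    x = recording.samples
    fs = recording.fs
    if np.ptp(x) == 0:
        logger.info("flat signal: no troughs detected")
        return np.array([])
    high = min(8.0, 0.45 * fs)
    sos = sps.butter(2, [0.5, high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    distance = max(1, int(round(refractory * fs)))
    idx, props = sps.find_peaks(-y, distance=distance, prominence=1e-12)
    if idx.size == 0:
        logger.info("no troughs detected")
        return np.array([])
    gate = 0.3 * float(np.median(props["prominences"]))
    idx = idx[props["prominences"] >= gate]
    # refine on the raw signal: true trough may sit a sample or two away
    # from the band-passed minimum
    half = max(1, int(round(0.06 * fs)))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        refined.append(lo + int(np.argmin(x[lo:hi])))
    refined = np.unique(refined)
    # re-impose the refractory distance after refinement
    keep = [refined[0]]
    for i in refined[1:]:
        if i - keep[-1] >= distance:
            keep.append(i)
        elif x[i] < x[keep[-1]]:
            keep[-1] = i
    return recording.start_time + np.asarray(keep, dtype=float) / fs


def reject_ipis(
    raw_ipis: np.ndarray,
    lo: float = IPI_MIN,
    hi: float = IPI_MAX,
    rel_tol: float = REL_TOL,
    compare_to: str = "last_valid",
) -> np.ndarray:
    """Validity mask for raw IPIs.

    An interval is invalid when outside ``[lo, hi]`` or when differing from
    its preceding interval by more than ``rel_tol``.  ``compare_to`` selects
    whether the predecessor is the nearest preceding *valid* interval
    (default; prevents one outlier from cascading) or the raw predecessor.
    The first interval — and any interval with no valid predecessor — is
    judged on the range rule only.
    """
    raw_ipis = np.asarray(raw_ipis, dtype=float)
    if raw_ipis.size == 0:
        raise ValueError("raw_ipis is empty")
    if compare_to not in ("last_valid", "raw"):
        raise ValueError(f"unknown compare_to: {compare_to!r}")
    in_range = (raw_ipis >= lo) & (raw_ipis <= hi)
    mask = np.zeros(raw_ipis.size, dtype=bool)
    prev_valid: float | None = None
    for i, ipi in enumerate(raw_ipis):
        if not in_range[i]:
            ok = False
        elif compare_to == "raw":
            ok = i == 0 or abs(ipi - raw_ipis[i - 1]) <= rel_tol * raw_ipis[i - 1]
        else:
            ok = prev_valid is None or abs(ipi - prev_valid) <= rel_tol * prev_valid
        mask[i] = ok
        if ok:
            prev_valid = ipi
    return mask


def interpolate_ipis(
    trough_times: np.ndarray, raw_ipis: np.ndarray, valid_mask: np.ndarray
) -> np.ndarray:
    """Fill rejected IPIs with a natural cubic spline through the valid ones.

    Abscissa = trough time at the start of each interval.  Valid positions
    are returned unchanged; edge gaps are not extrapolated (NaN).
    """
    trough_times = np.asarray(trough_times, dtype=float)
    raw_ipis = np.asarray(raw_ipis, dtype=float)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if raw_ipis.size != trough_times.size - 1 or valid_mask.size != raw_ipis.size:
        raise ValueError("inconsistent lengths")
    n_valid = int(np.count_nonzero(valid_mask))
    if n_valid < MIN_VALID_FOR_SPLINE:
        raise SegmentQualityError(
            f"only {n_valid} valid IPIs; need >= {MIN_VALID_FOR_SPLINE} for spline interpolation"
        )
    starts = trough_times[:-1]
    xs = starts[valid_mask]
    ys = raw_ipis[valid_mask]
    spline = CubicSpline(xs, ys, bc_type="natural")
    out = raw_ipis.copy()
    invalid = ~valid_mask
    interior = invalid & (starts >= xs[0]) & (starts <= xs[-1])
    out[interior] = spline(starts[interior])
    out[invalid & ~interior] = np.nan
    if np.any(out[interior] <= 0):
        logger.warning("spline produced non-positive IPIs; clipping to %.2f s", IPI_MIN)
        out[interior] = np.clip(out[interior], IPI_MIN, None)
    return out


def gate_fraction(series: IPISeries, window_start: float, window_end: float) -> float:
    """Discarded fraction used by the 20% segment-quality gate.

    Extends the count-based :attr:`IPISeries.discarded_fraction` with an
    estimate of beats hidden inside undetected stretches (detachment or edge
    gaps produce no troughs, hence no countable IPIs); every such phantom
    interval counts as discarded.
    """
    n_raw = series.raw_ipis.size
    n_invalid = int(np.count_nonzero(~series.valid_mask))
    clean = series.clean_ipis
    med = float(np.median(clean)) if clean.size else 0.8
    phantom = 0
    lead = series.trough_times[0] - window_start
    tail = window_end - series.trough_times[-1]
    phantom += max(int(round((lead + tail) / med)) - 1, 0)  # ~1 interval of edge slack
    for val in series.raw_ipis[~series.valid_mask]:
        if val > IPI_MAX:
            phantom += max(int(round(val / med)) - 1, 0)
    return (n_invalid + phantom) / (n_raw + phantom)


def extract_ipis(recording: PPGRecording, compare_to: str = "last_valid") -> IPISeries:
    """Full preprocessing of one segment: troughs → IPIs → rejection → interpolation."""
    troughs = detect_troughs(recording)
    if troughs.size < 2:
        raise SegmentQualityError("fewer than two troughs detected")
    raw = np.diff(troughs)
    mask = reject_ipis(raw, compare_to=compare_to)
    interp = interpolate_ipis(troughs, raw, mask)
    return IPISeries(
        trough_times=troughs, raw_ipis=raw, valid_mask=mask, interpolated_ipis=interp
    )


def export_ipis(series: IPISeries, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "trough_time_s": series.trough_times[:-1],
            "ipi_s": series.raw_ipis,
            "valid": series.valid_mask,
            "ipi_interpolated_s": series.interpolated_ipis,
        }
    ).to_csv(path, index=False)
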