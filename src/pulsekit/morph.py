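"""Pulse-wave morphology: fiducial points, per-pulse features, ensemble pulses.

Each pulse spans two consecutive troughs (IT → FT).  Fiducials are the
systolic peak (SP), the extrema of the first derivative (a1, b1, plus the
end-diastolic velocity EDV) and of the second derivative (a2, b2, e2).
Derivatives come from cubic-spline interpolation of the sampled pulse,
evaluated on an upsampled grid — second-derivative landmarks at 32 Hz are
otherwise too coarse.  Features are aggregated per segment by the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io_segments import PPGRecording
from .ipi import IPISeries

logger = logging.getLogger(__name__)

NAN = float("nan")

#: target rate (Hz) of the internal fine grid used for derivative landmarks
UPSAMPLE_FS = 256.0

WIDTH_LEVELS = {"10": 0.10, "25": 0.25, "50": 0.50, "60": 0.60}

FEATURE_NAMES = [
    "pwa", "b2_amplitude", "pwd", "spd", "dpd",
    "t_a1", "t_a1b1", "t_a2b2", "t_b2e2",
    "auc_total", "auc1", "auc2",
    "mean_v", "idr_v", "mean_acc", "msv", "sfv",
    "dw10_sw10", "dw25_sw25", "dw50_sw50", "dw60_sw60",
    "t_s_pwd", "t_a1_pwd", "t_a1b1_pwd", "t_a2b2_pwd", "t_b2e2_pwd",
    "b2_a2", "e2_a2", "spd_pwd", "sp_spd", "pulsatility_index",
    "slope_it_sp", "slope_sp_ft", "angle_alpha", "angle_gamma",
]


@dataclass
class PulseFiducials:
    """Fiducial times (s, relative to pulse start); ``edv`` is a velocity value."""

    it: float = NAN
    sp: float = NAN
    ft: float = NAN
    a1: float = NAN
    b1: float = NAN
    edv: float = NAN
    a2: float = NAN
    b2: float = NAN
    e2: float = NAN
    complete: bool = False


@dataclass
class MorphologyFeatures:
    pwa: float = NAN
    b2_amplitude: float = NAN
    pwd: float = NAN
    spd: float = NAN
    dpd: float = NAN
    t_a1: float = NAN
    t_a1b1: float = NAN
    t_a2b2: float = NAN
    t_b2e2: float = NAN
    auc_total: float = NAN
    auc1: float = NAN
    auc2: float = NAN
    mean_v: float = NAN
    idr_v: float = NAN
    mean_acc: float = NAN
    msv: float = NAN
    sfv: float = NAN
    dw10_sw10: float = NAN
    dw25_sw25: float = NAN
    dw50_sw50: float = NAN
    dw60_sw60: float = NAN
    t_s_pwd: float = NAN
    t_a1_pwd: float = NAN
    t_a1b1_pwd: float = NAN
    t_a2b2_pwd: float = NAN
    t_b2e2_pwd: float = NAN
    b2_a2: float = NAN
    e2_a2: float = NAN
    spd_pwd: float = NAN
    sp_spd: float = NAN
    pulsatility_index: float = NAN
    slope_it_sp: float = NAN
    slope_sp_ft: float = NAN
    angle_alpha: float = NAN
    angle_gamma: float = NAN

    def as_row(self) -> dict:
        return asdict(self)


@dataclass
class EnsemblePulse:
    day_index: int
    n_pulses: int
    grid: np.ndarray       # relative time 0–1 of the pulse span
    waveform: np.ndarray   # mean amplitude, absolute units preserved

    def __post_init__(self) -> None:
        if self.n_pulses <= 0:
            raise ValueError("n_pulses must be > 0")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _fine(pulse: np.ndarray, fs: float, smooth_window: int = 1):
    """Cubic-spline model of the pulse and its fine evaluation grid."""
    x = _smooth(np.asarray(pulse, dtype=float), smooth_window)
    t = np.arange(x.size) / fs
    spl = CubicSpline(t, x)
    factor = max(1, int(round(UPSAMPLE_FS / fs)))
    tf = np.arange((x.size - 1) * factor + 1) / (fs * factor)
    return spl, tf


def _first_local_min(y: np.ndarray, start: int) -> Optional[int]:
    for j in range(max(start, 1), y.size - 1):
        if y[j - 1] > y[j] <= y[j + 1]:
            return j
    return None


def _first_local_max(y: np.ndarray, start: int) -> Optional[int]:
    for j in range(max(start, 1), y.size - 1):
        if y[j - 1] < y[j] >= y[j + 1]:
            return j
    return None


def segment_pulses(
    recording: PPGRecording, series: IPISeries
) -> list[tuple[int, int]]:
    """(start, end) sample-index spans, one per consecutive trough pair.

    Spans whose inter-pulse interval was rejected are excluded.
    """
    idx = np.round((series.trough_times - recording.start_time) * recording.fs).astype(int)
    spans = []
    for i in range(idx.size - 1):
        if series.valid_mask[i] and idx[i + 1] - idx[i] >= 8:
            spans.append((int(idx[i]), int(idx[i + 1])))
    return spans


def locate_fiducials(
    pulse: np.ndarray, fs: float, smooth_window: int = 1
) -> PulseFiducials:
    """Locate waveform and derivative fiducials of one pulse.

    ``complete`` is False whenever any landmark cannot be found; such pulses
    are excluded from the feature analysis.
    """
    pulse = np.asarray(pulse, dtype=float)
    if pulse.size < 8:
        raise ValueError("pulse span must be at least 8 samples")
    spl, tf = _fine(pulse, fs, smooth_window)
    return _locate(spl, tf)


def _locate(spl, tf: np.ndarray) -> PulseFiducials:
    y = spl(tf)
    d1 = spl(tf, 1)
    d2 = spl(tf, 2)
    fid = PulseFiducials(it=0.0, ft=float(tf[-1]))
    fid.edv = float(d1[-1])

    sp_i = int(np.argmax(y))
    if sp_i in (0, y.size - 1):
        return fid  # monotone pulse: no interior systolic peak
    fid.sp = float(tf[sp_i])

    a1_i = int(np.argmax(d1[: sp_i + 1]))
    if a1_i in (0, sp_i):
        return fid
    fid.a1 = float(tf[a1_i])

    b1_i = _first_local_min(d1, a1_i + 1)
    if b1_i is None:
        return fid
    fid.b1 = float(tf[b1_i])

    a2_i = _first_local_max(d2, 1)
    if a2_i is None or a2_i >= sp_i or d2[a2_i] <= 0:
        return fid
    fid.a2 = float(tf[a2_i])

    pwd_i = y.size - 1
    b2_hi = min(pwd_i, sp_i + int(0.25 * pwd_i))
    if b2_hi <= a2_i + 1:
        return fid
    b2_i = a2_i + 1 + int(np.argmin(d2[a2_i + 1: b2_hi + 1]))
    if d2[b2_i] >= 0:
        return fid
    fid.b2 = float(tf[b2_i])

    e2_hi = int(0.8 * pwd_i)
    if e2_hi <= b2_i + 1:
        return fid
    seg = d2[b2_i: e2_hi + 1]
    peaks, props = sps.find_peaks(seg, prominence=0.0)
    if peaks.size == 0:
        return fid
    e2_i = b2_i + int(peaks[np.argmax(props["prominences"])])
    fid.e2 = float(tf[e2_i])

    fid.complete = True
    return fid


def _cross_time(tf: np.ndarray, y: np.ndarray, level: float, sp_i: int, side: str
                ) -> float:
    """Linear-interpolated crossing time of ``level`` on the rising/falling limb."""
    if side == "rise":
        below = np.flatnonzero(y[:sp_i] < level)
        if below.size == 0:
            return NAN
        j = below[-1]  # last sample below the level before SP
        if y[j + 1] == y[j]:
            return float(tf[j])
        frac = (level - y[j]) / (y[j + 1] - y[j])
        return float(tf[j] + frac * (tf[j + 1] - tf[j]))
    above = np.flatnonzero(y[sp_i:] < level)
    if above.size == 0:
        return NAN
    j = sp_i + above[0] - 1  # last sample above the level after SP
    if j < sp_i:
        return NAN
    if y[j + 1] == y[j]:
        return float(tf[j + 1])
    frac = (y[j] - level) / (y[j] - y[j + 1])
    return float(tf[j] + frac * (tf[j + 1] - tf[j]))


def compute_features(
    pulse: np.ndarray, fid: PulseFiducials, fs: float, smooth_window: int = 1,
    _grid=None,
) -> MorphologyFeatures:
    """Evaluate the full morphology feature catalogue for one pulse.

    Features whose fiducials or level crossings are unavailable come back NaN.
    Widths are measured at fractions of the pulse amplitude above the IT
    baseline; areas use a straight IT→FT baseline; angles use amplitude
    normalized to PWA with time in seconds, reported in degrees.
    """
    pulse = np.asarray(pulse, dtype=float)
    if _grid is not None:
        spl, tf = _grid
    else:
        spl, tf = _fine(pulse, fs, smooth_window)
    y = spl(tf)
    out = MorphologyFeatures()
    if not (np.isfinite(fid.sp) and np.isfinite(fid.ft)):
        return out
    y_it = float(spl(fid.it))
    y_sp = float(spl(fid.sp))
    y_ft = float(spl(fid.ft))
    out.pwa = y_sp - y_it
    out.pwd = fid.ft - fid.it
    out.spd = fid.sp - fid.it
    out.dpd = fid.ft - fid.sp
    if out.spd > 0:
        out.slope_it_sp = (y_sp - y_it) / out.spd
        out.sp_spd = out.pwa / out.spd
    if out.dpd > 0:
        out.slope_sp_ft = (y_ft - y_sp) / out.dpd
    if out.pwa > 0:
        if out.spd > 0:
            out.angle_alpha = float(np.degrees(np.arctan(((y_sp - y_it) / out.pwa) / out.spd)))
        if out.dpd > 0:
            out.angle_gamma = float(np.degrees(np.arctan(((y_ft - y_sp) / out.pwa) / out.dpd)))

    # areas above the IT→FT baseline, split at the SP ordinate
    baseline = y_it + (y_ft - y_it) * (tf - fid.it) / (fid.ft - fid.it)
    above = y - baseline
    sp_i = int(np.argmin(np.abs(tf - fid.sp)))
    out.auc1 = float(np.trapezoid(above[: sp_i + 1], tf[: sp_i + 1]))
    out.auc2 = float(np.trapezoid(above[sp_i:], tf[sp_i:]))
    out.auc_total = out.auc1 + out.auc2

    d1 = spl(tf, 1)
    d2 = spl(tf, 2)
    span = float(tf[-1] - tf[0])
    # time-averages of the derivatives = endpoint differences / span
    out.mean_v = float(np.trapezoid(d1, tf)) / span
    out.idr_v = float(np.percentile(d1, 90) - np.percentile(d1, 10))
    out.mean_acc = float(np.trapezoid(d2, tf)) / span
    out.sfv = float(spl(fid.it, 1))

    if out.pwa > 0:
        for name, frac in WIDTH_LEVELS.items():
            level = y_it + frac * out.pwa
            t_rise = _cross_time(tf, y, level, sp_i, "rise")
            t_fall = _cross_time(tf, y, level, sp_i, "fall")
            if np.isfinite(t_rise) and np.isfinite(t_fall):
                sw = fid.sp - t_rise
                dw = t_fall - fid.sp
                if sw > 0:
                    setattr(out, f"dw{name}_sw{name}", dw / sw)

    if out.pwd > 0:
        out.spd_pwd = out.spd / out.pwd

    if np.isfinite(fid.a1):
        out.t_a1 = fid.a1 - fid.it
        out.msv = float(spl(fid.a1, 1))
        if out.pwd > 0:
            out.t_a1_pwd = out.t_a1 / out.pwd
            out.t_s_pwd = (fid.sp - fid.a1) / out.pwd
        if np.isfinite(fid.edv) and out.mean_v != 0:
            out.pulsatility_index = (out.msv - fid.edv) / out.mean_v
    if np.isfinite(fid.a1) and np.isfinite(fid.b1):
        out.t_a1b1 = fid.b1 - fid.a1
        if out.pwd > 0:
            out.t_a1b1_pwd = out.t_a1b1 / out.pwd
    if np.isfinite(fid.a2) and np.isfinite(fid.b2):
        out.t_a2b2 = fid.b2 - fid.a2
        a2_val = float(spl(fid.a2, 2))
        b2_val = float(spl(fid.b2, 2))
        out.b2_amplitude = abs(b2_val)
        if a2_val > 0:
            out.b2_a2 = abs(b2_val) / a2_val
        if out.pwd > 0:
            out.t_a2b2_pwd = out.t_a2b2 / out.pwd
        if np.isfinite(fid.e2):
            out.t_b2e2 = fid.e2 - fid.b2
            e2_val = float(spl(fid.e2, 2))
            if a2_val > 0:
                out.e2_a2 = e2_val / a2_val
            if out.pwd > 0:
                out.t_b2e2_pwd = out.t_b2e2 / out.pwd
    return out


def aggregate_segment(
    per_pulse: Sequence[MorphologyFeatures],
) -> tuple[Optional[MorphologyFeatures], int]:
    """Per-feature median across accepted pulses; (None, 0) when empty."""
    if not per_pulse:
        return None, 0
    agg = MorphologyFeatures()
    for f in dc_fields(MorphologyFeatures):
        vals = np.array([getattr(p, f.name) for p in per_pulse], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            setattr(agg, f.name, float(np.median(vals)))
    return agg, len(per_pulse)


def ensemble_average(
    pulses: Sequence[np.ndarray], day_index: int, n_grid: int = 100
) -> EnsemblePulse:
    """Mean pulse on a common relative-time grid; amplitudes are not normalized."""
    if not pulses:
        raise ValueError("need at least one pulse")
    grid = np.linspace(0.0, 1.0, n_grid)
    stack = np.empty((len(pulses), n_grid))
    for i, p in enumerate(pulses):
        p = np.asarray(p, dtype=float)
        rel = np.linspace(0.0, 1.0, p.size)
        stack[i] = np.interp(grid, rel, p)
    return EnsemblePulse(
        day_index=day_index, n_pulses=len(pulses), grid=grid,
        waveform=stack.mean(axis=0),
    )


def analyze_segment(
    recording: PPGRecording, series: IPISeries, smooth_window: int = 1
) -> tuple[Optional[MorphologyFeatures], int, list[np.ndarray]]:
    """Morphology of one segment: (aggregate features, n pulses used, accepted pulses)."""
    spans = segment_pulses(recording, series)
    feats: list[MorphologyFeatures] = []
    accepted: list[np.ndarray] = []
    n_excluded = 0
    for i0, i1 in spans:
        pulse = recording.samples[i0: i1 + 1]
        if pulse.size < 8:
            n_excluded += 1
            continue
        grid = _fine(pulse, recording.fs, smooth_window)
        fid = _locate(*grid)
        if not fid.complete:
            n_excluded += 1
            continue
        feats.append(compute_features(pulse, fid, recording.fs, smooth_window, _grid=grid))
        accepted.append(pulse)
    if n_excluded:
        logger.debug("%d/%d pulses excluded (incomplete fiducials)", n_excluded, len(spans))
    agg, n = aggregate_segment(feats)
    return agg, n, accepted
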