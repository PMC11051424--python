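"""Synthetic wrist-PPG generator with known ground truth.

Beat times follow a sinusoidally modulated interval model (LF + HF bands plus
white noise), each beat contributes a two-lobe pulse (systolic + delayed
diastolic Gaussian), and configurable day-wise effects (heart-rate shift,
HF-variability suppression, pulse-amplitude attenuation) plus motion/detachment
artifacts let every downstream stage be tested against a known answer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_segments import PPGRecording, write_recording

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)  # Hz
HF_BAND = (0.15, 0.40)  # Hz

#: systolic lobe centre, in units of systolic_width after the beat onset
_SYSTOLIC_PEAK_FACTOR = 2.2


@dataclass(frozen=True)
class PulseTemplate:
    """Two-lobe parametric pulse: systolic Gaussian + delayed diastolic Gaussian."""

    systolic_amplitude: float = 1.0
    systolic_width: float = 0.11
    diastolic_amplitude: float = 0.30
    diastolic_delay: float = 0.28
    diastolic_width: float = 0.14

    def __post_init__(self) -> None:
        if self.systolic_amplitude <= 0:
            raise ValueError("systolic_amplitude must be > 0")
        if self.diastolic_amplitude < 0 or self.diastolic_delay < 0:
            raise ValueError("diastolic amplitude/delay must be >= 0")
        if not (0 < self.systolic_width < 1.0 and 0 < self.diastolic_width < 1.0):
            raise ValueError("widths must be in (0, 1) s")
        if self.systolic_amplitude <= self.diastolic_amplitude:
            raise ValueError("systolic amplitude must exceed diastolic amplitude")

    @property
    def systolic_peak_time(self) -> float:
        """Time of the systolic lobe centre after the beat onset (s)."""
        return _SYSTOLIC_PEAK_FACTOR * self.systolic_width

    @property
    def extent(self) -> float:
        """Support (s) after which the pulse is numerically negligible."""
        return self.systolic_peak_time + self.diastolic_delay + 5.0 * self.diastolic_width

    def waveform(self, tau: np.ndarray) -> np.ndarray:
        """Closed-form pulse value at time ``tau`` (s) after the beat onset."""
        tau = np.asarray(tau, dtype=float)
        mu_s = self.systolic_peak_time
        mu_d = mu_s + self.diastolic_delay
        out = self.systolic_amplitude * np.exp(-0.5 * ((tau - mu_s) / self.systolic_width) ** 2)
        out = out + self.diastolic_amplitude * np.exp(
            -0.5 * ((tau - mu_d) / self.diastolic_width) ** 2
        )
        return out


@dataclass(frozen=True)
class BeatIntervalModel:
    """Sinusoidal LF + HF interval modulation plus white noise."""

    mean_ipi: float = 0.8
    lf_amplitude: float = 0.0
    lf_freq: float = 0.1
    hf_amplitude: float = 0.0
    hf_freq: float = 0.25
    white_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.4 <= self.mean_ipi <= 2.0):
            raise ValueError(f"mean_ipi must be in [0.4, 2.0] s, got {self.mean_ipi}")
        if self.lf_amplitude and not (LF_BAND[0] <= self.lf_freq <= LF_BAND[1]):
            raise ValueError(f"lf_freq must be in {LF_BAND}")
        if self.hf_amplitude and not (HF_BAND[0] <= self.hf_freq <= HF_BAND[1]):
            raise ValueError(f"hf_freq must be in {HF_BAND}")
        if self.white_noise_sd < 0:
            raise ValueError("white_noise_sd must be >= 0")


@dataclass(frozen=True)
class DayEffect:
    """Generator knobs for one study day (values are user configuration)."""

    day_index: int
    hr_shift: float = 0.0       # bpm, added to the participant's base HR
    hf_scale: float = 1.0       # multiplies hf_amplitude
    amplitude_scale: float = 1.0  # multiplies pulse amplitudes

    def __post_init__(self) -> None:
        if not (0 <= self.day_index <= 4):
            raise ValueError("day_index must be in 0..4")
        if self.hf_scale < 0 or self.amplitude_scale <= 0:
            raise ValueError("hf_scale must be >= 0 and amplitude_scale > 0")


@dataclass(frozen=True)
class ArtifactSpec:
    motion_burst_rate: float = 0.0   # events per minute
    motion_burst_sd: float = 0.0     # PPG units
    detachment_rate: float = 0.0     # events per hour
    detachment_duration: float = 10.0  # s
    motion_burst_duration: float = 1.0  # s

    def __post_init__(self) -> None:
        if min(self.motion_burst_rate, self.motion_burst_sd, self.detachment_rate) < 0:
            raise ValueError("artifact rates must be >= 0")


def generate_beat_times(
    model: BeatIntervalModel, duration: float
) -> tuple[np.ndarray, np.ndarray]:
    """Beat times over ``[0, duration]`` plus the ground-truth IPI list.

    The first beat is at t=0 and successive differences equal the returned
    IPIs exactly.  Reproducible under the model's seed.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rng = np.random.default_rng(model.seed)
    beats = [0.0]
    ipis: list[float] = []
    t = 0.0
    floor = 0.25  # hard positivity floor (s)
    while True:
        ipi = model.mean_ipi
        if model.lf_amplitude:
            ipi += model.lf_amplitude * math.sin(2 * math.pi * model.lf_freq * t)
        if model.hf_amplitude:
            ipi += model.hf_amplitude * math.sin(2 * math.pi * model.hf_freq * t)
        if model.white_noise_sd:
            ipi += rng.normal(0.0, model.white_noise_sd)
        if ipi < floor:
            logger.warning("IPI clipped to %.2f s (model produced %.3f s)", floor, ipi)
            ipi = floor
        if t + ipi > duration:
            break
        t += ipi
        beats.append(t)
        ipis.append(ipi)
    return np.asarray(beats), np.asarray(ipis)


#: reference pulse span (s) for beat-anchored rendering
REF_PULSE_SPAN = 0.85


def render_ppg(
    beat_times: np.ndarray,
    template: PulseTemplate = PulseTemplate(),
    fs: float = 32.0,
    artifacts: Optional[ArtifactSpec] = None,
    amplitude_scale: float = 1.0,
    duration: Optional[float] = None,
    start_time: float = 0.0,
    seed: int = 0,
    mode: str = "anchored",
) -> PPGRecording:
    """Render beat times into a sampled PPG trace.

    Each beat contributes one two-lobe pulse.  In ``anchored`` mode (default)
    the template is time-scaled to each inter-beat interval with its endpoints
    closed to zero, so the clean-signal minima coincide exactly with the beat
    times (diastole shortens with faster rate, as in real pulses).  In
    ``superpose`` mode pulses are plainly summed at fixed time scale.  Motion
    bursts are additive broadband noise; detachment freezes the signal at a
    constant (sensor off wrist).
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if fs < 16:
        raise ValueError("fs must be >= 16 Hz")
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if mode not in ("anchored", "superpose"):
        raise ValueError(f"unknown render mode: {mode!r}")
    if beat_times.size >= 2:
        mean_ipi = float(np.mean(np.diff(beat_times)))
        if mode == "superpose" and template.extent > 1.5 * mean_ipi:
            logger.warning(
                "pulse template extent %.2f s exceeds mean IPI %.2f s; pulses overlap",
                template.extent, mean_ipi,
            )
    if duration is None:
        duration = float(beat_times[-1]) + 1.0 if beat_times.size else 1.0
    n = int(math.ceil(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    if mode == "superpose":
        extent = template.extent
        for beat in beat_times:
            i0 = max(0, int(math.floor(beat * fs)))
            i1 = min(n, int(math.ceil((beat + extent) * fs)) + 1)
            if i1 > i0:
                x[i0:i1] += template.waveform(t[i0:i1] - beat)
    else:
        v0 = float(template.waveform(np.array(0.0)))
        v1 = float(template.waveform(np.array(REF_PULSE_SPAN)))
        bounds = list(beat_times)
        if bounds:
            # extend past the final beat with the last interval's scale
            last_ipi = (
                float(bounds[-1] - bounds[-2]) if len(bounds) >= 2 else REF_PULSE_SPAN
            )
            bounds.append(bounds[-1] + max(last_ipi, duration - bounds[-1]))
        for k in range(len(bounds) - 1):
            b0, b1 = bounds[k], bounds[k + 1]
            ipi_k = b1 - b0
            i0 = max(0, int(math.ceil(b0 * fs - 1e-9)))
            i1 = min(n, int(math.ceil(b1 * fs - 1e-9)))
            if i1 <= i0:
                continue
            phase = (t[i0:i1] - b0) * (REF_PULSE_SPAN / ipi_k)
            closure = v0 + (v1 - v0) * phase / REF_PULSE_SPAN
            x[i0:i1] += template.waveform(phase) - closure
    x *= amplitude_scale

    if artifacts is not None:
        rng = np.random.default_rng(seed)
        n_bursts = rng.poisson(artifacts.motion_burst_rate * duration / 60.0)
        for _ in range(n_bursts):
            c = rng.uniform(0, duration)
            i0 = max(0, int((c - artifacts.motion_burst_duration / 2) * fs))
            i1 = min(n, int((c + artifacts.motion_burst_duration / 2) * fs))
            if i1 > i0:
                x[i0:i1] += rng.normal(0.0, artifacts.motion_burst_sd, i1 - i0)
        n_det = rng.poisson(artifacts.detachment_rate * duration / 3600.0)
        for _ in range(n_det):
            c = rng.uniform(0, duration)
            i0 = max(0, int(c * fs))
            i1 = min(n, int((c + artifacts.detachment_duration) * fs))
            if i1 > i0:
                x[i0:i1] = x[i0]
    return PPGRecording(samples=x, fs=fs, start_time=start_time)


@dataclass
class CohortDesign:
    """Configuration of a synthetic multi-day cohort."""

    n_participants: int = 61
    day_effects: Sequence[DayEffect] = field(
        default_factory=lambda: tuple(DayEffect(d) for d in range(5))
    )
    day0_fraction: float = 8.0 / 61.0
    recording_duration: float = 370.0
    base_hr_mean: float = 82.0       # bpm, between-participant mean
    base_hr_sd: float = 7.0          # bpm, between-participant spread
    day_jitter_hr_sd: float = 2.0    # bpm, within-participant day-to-day noise
    lf_amplitude: float = 0.02       # s
    hf_amplitude: float = 0.025      # s
    white_noise_sd: float = 0.008    # s
    artifacts: Optional[ArtifactSpec] = None
    dropout_rate: float = 0.0        # chance a non-baseline day is missing
    circadian_hr_amplitude: float = 0.0  # bpm; 24-h sinusoidal HR modulation, off by default
    fs: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not self.day_effects:
            raise ValueError("day_effects must not be empty")
        days = [e.day_index for e in self.day_effects]
        if len(set(days)) != len(days):
            raise ValueError("duplicate day_index in day_effects")
        if not set(days) <= set(range(5)):
            raise ValueError("day indices must be within 0..4")


@dataclass
class Cohort:
    """In-memory synthetic cohort: recordings, manifest and ground truth."""

    recordings: dict  # (participant_id, day) -> PPGRecording
    manifest: pd.DataFrame
    truth: pd.DataFrame
    design: CohortDesign


def _day_target_time(day: int, injection1: float) -> float:
    """Measurement target: 1 h before injection 1 on day 0, +24 h steps after."""
    if day == 0:
        return injection1 - 3600.0
    return injection1 + day * 24 * 3600.0


def generate_cohort(design: CohortDesign = CohortDesign()) -> Cohort:
    """Generate per-participant, per-day recordings with a ground-truth table.

    A configurable fraction of participants carries a day-0 (pre-injection)
    recording; day-1 recordings end before the second injection.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_participants
    n_day0 = int(round(design.day0_fraction * n))
    day0_participants = set(rng.permutation(n)[:n_day0])
    child_seeds = np.random.SeedSequence(design.seed).spawn(n)

    injection1 = 10.0 * 3600.0  # 10:00 on the admission day
    injection2 = injection1 + 24 * 3600.0 + 1800.0  # day-1 windows must precede this

    recordings: dict = {}
    manifest_rows = []
    truth_rows = []
    margin = (design.recording_duration - 300.0) / 2.0
    for p in range(n):
        prng = np.random.default_rng(child_seeds[p])
        pid = f"P{p:03d}"
        base_hr = float(np.clip(prng.normal(design.base_hr_mean, design.base_hr_sd), 55, 115))
        amp = float(np.clip(prng.normal(1.0, 0.10), 0.5, 1.5))
        template = PulseTemplate(systolic_amplitude=amp, diastolic_amplitude=0.30 * amp)
        for effect in sorted(design.day_effects, key=lambda e: e.day_index):
            day = effect.day_index
            if day == 0 and p not in day0_participants:
                continue
            if day != 0 and design.dropout_rate > 0 and prng.uniform() < design.dropout_rate:
                continue
            target = _day_target_time(day, injection1)
            hr = base_hr + effect.hr_shift + float(prng.normal(0.0, design.day_jitter_hr_sd))
            if design.circadian_hr_amplitude:
                hr += design.circadian_hr_amplitude * math.sin(
                    2 * math.pi * target / (24 * 3600.0)
                )
            hr = float(np.clip(hr, 45, 140))
            model = BeatIntervalModel(
                mean_ipi=60.0 / hr,
                lf_amplitude=design.lf_amplitude,
                lf_freq=0.1,
                hf_amplitude=design.hf_amplitude * effect.hf_scale,
                hf_freq=0.25,
                white_noise_sd=design.white_noise_sd,
                seed=int(prng.integers(2**31)),
            )
            beats, ipis = generate_beat_times(model, design.recording_duration)
            start = target - margin
            rec = render_ppg(
                beats,
                template=template,
                fs=design.fs,
                artifacts=design.artifacts,
                amplitude_scale=effect.amplitude_scale,
                duration=design.recording_duration,
                start_time=start,
                seed=int(prng.integers(2**31)),
            )
            rec.events = {"injection1": injection1, "injection2": injection2}
            recordings[(pid, day)] = rec
            manifest_rows.append(
                {
                    "participant_id": pid,
                    "day": day,
                    "file": f"{pid}_day{day}.csv",
                    "injection1_time": injection1,
                    "injection2_time": injection2,
                }
            )
            truth_rows.append(
                {
                    "participant_id": pid,
                    "day": day,
                    "true_hr_bpm": 60.0 / float(np.mean(ipis)),
                    "target_hr_bpm": hr,
                    "hr_shift_bpm": effect.hr_shift,
                    "hf_amplitude_s": design.hf_amplitude * effect.hf_scale,
                    "hf_scale": effect.hf_scale,
                    "amplitude_scale": effect.amplitude_scale,
                    "n_beats": beats.size,
                }
            )
    return Cohort(
        recordings=recordings,
        manifest=pd.DataFrame(manifest_rows),
        truth=pd.DataFrame(truth_rows),
        design=design,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort as CSVs: one recording per participant-day, a manifest and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for row in cohort.manifest.itertuples():
        write_recording(cohort.recordings[(row.participant_id, row.day)], outdir / row.file)
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    return outdir
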