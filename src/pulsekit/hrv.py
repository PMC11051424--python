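"""Heart-rate and heart-rate-variability features of one 5-minute segment.

Time domain: HR, SDNN, RMSSD, pNN50.  Frequency domain: total power, LF
(0.04–0.15 Hz), HF (0.15–0.40 Hz) and LF/HF from a Welch spectrum of the
uniformly resampled interval series.  Non-linear: Poincaré SD1/SD2, sample
entropy (m=2, r=0.2·SD) and the short-term detrended-fluctuation exponent
over 4–16 beats.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .ipi import IPISeries

NAN = float("nan")

FEATURE_COLUMNS = [
    "hr_bpm", "sdnn_ms", "rmssd_ms", "pnn50_pct",
    "tp_ms2", "lf_ms2", "hf_ms2", "lf_hf",
    "sd1_ms", "sd2_ms", "sd1_sd2", "sampen", "dfa_alpha1",
]


@dataclass(frozen=True)
class SampEnConfig:
    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1 or self.r_factor <= 0:
            raise ValueError("m must be >= 1 and r_factor > 0")


@dataclass(frozen=True)
class DFAConfig:
    min_box: int = 4
    max_box: int = 16

    def __post_init__(self) -> None:
        if not (4 <= self.min_box < self.max_box):
            raise ValueError("need 4 <= min_box < max_box")


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimator settings for the interval spectrum.

    The tachogram is cubic-spline resampled to ``resample_fs`` on interval-start
    abscissae, linearly detrended and Hann-windowed in ``welch_segment_s``
    segments with 50% overlap.  Total power spans ``tp_band``.
    """

    resample_fs: float = 4.0
    welch_segment_s: float = 120.0
    tp_band: tuple = (0.003, 0.40)
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.40)


@dataclass
class HRVFeatures:
    hr: float = NAN        # bpm
    sdnn: float = NAN      # ms
    rmssd: float = NAN     # ms
    pnn50: float = NAN     # %
    tp: float = NAN        # ms^2
    lf: float = NAN        # ms^2
    hf: float = NAN        # ms^2
    lf_hf: float = NAN
    sd1: float = NAN       # ms
    sd2: float = NAN       # ms
    sd1_sd2: float = NAN
    sampen: float = NAN
    dfa_alpha1: float = NAN

    def as_row(self) -> dict:
        vals = asdict(self)
        return dict(zip(FEATURE_COLUMNS, [vals[k] for k in (
            "hr", "sdnn", "rmssd", "pnn50", "tp", "lf", "hf", "lf_hf",
            "sd1", "sd2", "sd1_sd2", "sampen", "dfa_alpha1")]))


def _successive_diffs(ipis: IPISeries | np.ndarray) -> np.ndarray:
    """Successive interval differences (s); across-gap pairs excluded for IPISeries."""
    if isinstance(ipis, IPISeries):
        return ipis.successive_pairs()
    return np.diff(np.asarray(ipis, dtype=float))


def _clean(ipis: IPISeries | np.ndarray) -> np.ndarray:
    if isinstance(ipis, IPISeries):
        return ipis.clean_ipis
    return np.asarray(ipis, dtype=float)


def time_domain(ipis: IPISeries | np.ndarray) -> tuple[float, float, float, float]:
    """(hr_bpm, sdnn_ms, rmssd_ms, pnn50_pct); missing features are NaN."""
    x = _clean(ipis)
    hr = sdnn = rmssd = pnn50 = NAN
    if x.size >= 2:
        hr = 60.0 / float(np.mean(x))
        sdnn = 1000.0 * float(np.std(x, ddof=1))
    diffs = _successive_diffs(ipis)
    if x.size >= 3 and diffs.size >= 1:
        rmssd = 1000.0 * float(np.sqrt(np.mean(diffs**2)))
        pnn50 = 100.0 * float(np.count_nonzero(np.abs(diffs) > 0.050)) / diffs.size
    return hr, sdnn, rmssd, pnn50


def frequency_domain(
    series: IPISeries, config: SpectralConfig = SpectralConfig()
) -> tuple[float, float, float, float]:
    """(tp, lf, hf, lf_hf) in ms² via Welch on the resampled tachogram."""
    times, values = series.interpolated_series()
    if times.size < 4:
        return NAN, NAN, NAN, NAN
    fs = config.resample_fs
    grid = np.arange(times[0], times[-1], 1.0 / fs)
    resampled = CubicSpline(times, values)(grid)
    resampled = sps.detrend(resampled, type="linear")
    nperseg = min(resampled.size, int(config.welch_segment_s * fs))
    freqs, psd = sps.welch(
        resampled, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    psd_ms2 = psd * 1e6  # s²/Hz → ms²/Hz

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        if np.count_nonzero(m) < 2:
            return 0.0
        return float(np.trapezoid(psd_ms2[m], freqs[m]))

    tp = band_power(*config.tp_band)
    lf = band_power(*config.lf_band)
    hf = band_power(*config.hf_band)
    lf_hf = lf / hf if hf > 0 else NAN
    return tp, lf, hf, lf_hf


def poincare(ipis: IPISeries | np.ndarray) -> tuple[float, float, float]:
    """(sd1_ms, sd2_ms, sd1/sd2) from the lag-1 scatter geometry."""
    x = _clean(ipis)
    if x.size < 3:
        return NAN, NAN, NAN
    diffs = _successive_diffs(ipis)
    if diffs.size < 2:
        return NAN, NAN, NAN
    var_d = float(np.var(diffs, ddof=1))
    sdnn = float(np.std(x, ddof=1))
    if sdnn < 1e-12:  # degenerate constant series
        return 0.0, 0.0, NAN
    sd1 = np.sqrt(0.5 * var_d)
    sd2_sq = max(2.0 * sdnn**2 - 0.5 * var_d, 0.0)
    sd2 = np.sqrt(sd2_sq)
    ratio = sd1 / sd2 if sd2 > 0 else NAN
    return 1000.0 * sd1, 1000.0 * sd2, ratio


def sample_entropy(
    ipis: IPISeries | np.ndarray, config: SampEnConfig = SampEnConfig()
) -> float:
    """SampEn = −ln(A/B), Chebyshev distance, self-matches excluded.

    Uses N−m templates for both window lengths; tolerance r = r_factor × sample
    SD.  Zero-variance series return 0 by convention; B=0 returns NaN.
    """
    x = _clean(ipis)
    if x.size < 50:
        return NAN
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    r = config.r_factor * sd
    m = config.m
    n = x.size
    n_templates = n - m
    # pairwise Chebyshev distances between length-m templates, i < j
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    db = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=-1)
    da = np.max(np.abs(tm1[:, None, :] - tm1[None, :, :]), axis=-1)
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(db[iu] <= r))
    a = int(np.count_nonzero(da[iu] <= r))
    if b == 0 or a == 0:
        return NAN
    return float(-np.log(a / b))


def dfa_alpha1(
    ipis: IPISeries | np.ndarray, config: DFAConfig = DFAConfig()
) -> float:
    """Short-term DFA exponent: order-1 detrending in non-overlapping 4–16-beat boxes."""
    if isinstance(ipis, IPISeries):
        _, x = ipis.interpolated_series()
    else:
        x = np.asarray(ipis, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 100:
        return NAN
    profile = np.cumsum(x - np.mean(x))
    sizes = np.arange(config.min_box, config.max_box + 1)
    log_n, log_f = [], []
    for n in sizes:
        n_boxes = profile.size // n
        if n_boxes < 2:
            return NAN
        segs = profile[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # least-squares line per box, vectorized
        t_mean = t.mean()
        s_mean = segs.mean(axis=1, keepdims=True)
        slope = ((t - t_mean) * (segs - s_mean)).sum(axis=1) / ((t - t_mean) ** 2).sum()
        resid = segs - (s_mean + slope[:, None] * (t - t_mean))
        f = np.sqrt(np.mean(resid**2))
        if f <= 0:
            return NAN
        log_n.append(np.log(n))
        log_f.append(np.log(f))
    slope, _ = np.polyfit(log_n, log_f, 1)
    return float(slope)


def compute_features(
    series: IPISeries,
    spectral: SpectralConfig = SpectralConfig(),
    sampen_cfg: SampEnConfig = SampEnConfig(),
    dfa_cfg: DFAConfig = DFAConfig(),
) -> HRVFeatures:
    """All 13 HR/HRV features of one segment."""
    hr, sdnn, rmssd, pnn50 = time_domain(series)
    tp, lf, hf, lf_hf = frequency_domain(series, spectral)
    sd1, sd2, sd1_sd2 = poincare(series)
    return HRVFeatures(
        hr=hr, sdnn=sdnn, rmssd=rmssd, pnn50=pnn50,
        tp=tp, lf=lf, hf=hf, lf_hf=lf_hf,
        sd1=sd1, sd2=sd2, sd1_sd2=sd1_sd2,
        sampen=sample_entropy(series, sampen_cfg),
        dfa_alpha1=dfa_alpha1(series, dfa_cfg),
    )
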