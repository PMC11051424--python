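import logging

import numpy as np
import pytest

from pulsekit import synth

logging.getLogger("pulsekit").setLevel(logging.ERROR)


@pytest.fixture
def template():
    return synth.PulseTemplate()


@pytest.fixture
def clean_recording():
    """300 s of clean PPG with LF+HF interval modulation and mild noise."""
    model = synth.BeatIntervalModel(
        mean_ipi=0.8, lf_amplitude=0.02, lf_freq=0.1,
        hf_amplitude=0.03, hf_freq=0.25, white_noise_sd=0.01, seed=7,
    )
    beats, ipis = synth.generate_beat_times(model, 300.0)
    rec = synth.render_ppg(beats, duration=300.0)
    return rec, beats, ipis


def template_pulse(tpl, fs=32.0, span=0.8):
    """One sampled pulse of the closed-form template, trough-to-trough."""
    n = int(span * fs) + 1
    t = np.arange(n) / fs
    return t, tpl.waveform(t)


def gaussian_d1(tpl, tau):
    """Analytic first derivative of the two-lobe template."""
    tau = np.asarray(tau, dtype=float)
    mu_s = tpl.systolic_peak_time
    mu_d = mu_s + tpl.diastolic_delay
    g_s = tpl.systolic_amplitude * np.exp(-0.5 * ((tau - mu_s) / tpl.systolic_width) ** 2)
    g_d = tpl.diastolic_amplitude * np.exp(-0.5 * ((tau - mu_d) / tpl.diastolic_width) ** 2)
    return -g_s * (tau - mu_s) / tpl.systolic_width**2 - g_d * (tau - mu_d) / tpl.diastolic_width**2


def gaussian_d2(tpl, tau):
    """Analytic second derivative of the two-lobe template."""
    tau = np.asarray(tau, dtype=float)
    mu_s = tpl.systolic_peak_time
    mu_d = mu_s + tpl.diastolic_delay
    g_s = tpl.systolic_amplitude * np.exp(-0.5 * ((tau - mu_s) / tpl.systolic_width) ** 2)
    g_d = tpl.diastolic_amplitude * np.exp(-0.5 * ((tau - mu_d) / tpl.diastolic_width) ** 2)
    w_s, w_d = tpl.systolic_width, tpl.diastolic_width
    out = g_s * ((tau - mu_s) ** 2 / w_s**4 - 1.0 / w_s**2)
    out += g_d * ((tau - mu_d) ** 2 / w_d**4 - 1.0 / w_d**2)
    return out
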