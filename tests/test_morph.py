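import numpy as np
import pytest
from scipy import signal as sps

from pulsekit import ipi, morph, synth
from pulsekit.io_segments import PPGRecording

from conftest import gaussian_d1, gaussian_d2, template_pulse


def dense_oracle(tpl, span, fso=4096.0):
    """Feature values from the closed-form template on a dense grid.

    Uses the analytic derivatives (conftest) — an independent route from the
    32 Hz spline pipeline.
    """
    to = np.arange(int(round(span * fso)) + 1) / fso
    y = tpl.waveform(to)
    d1 = gaussian_d1(tpl, to)
    d2 = gaussian_d2(tpl, to)
    sp_i = int(np.argmax(y))
    a1_i = int(np.argmax(d1[:sp_i]))
    b1_i = next(j for j in range(a1_i + 1, d1.size - 1) if d1[j - 1] > d1[j] <= d1[j + 1])
    a2_i = next(j for j in range(1, d2.size - 1) if d2[j - 1] < d2[j] >= d2[j + 1])
    b2_hi = min(y.size - 1, sp_i + int(0.25 * (y.size - 1)))
    b2_i = a2_i + 1 + int(np.argmin(d2[a2_i + 1: b2_hi + 1]))
    e2_hi = int(0.8 * (y.size - 1))
    pk, pr = sps.find_peaks(d2[b2_i: e2_hi + 1], prominence=0)
    e2_i = b2_i + int(pk[np.argmax(pr["prominences"])])
    o = {}
    o["pwd"] = to[-1]
    o["spd"] = to[sp_i]
    o["dpd"] = to[-1] - to[sp_i]
    o["pwa"] = y[sp_i] - y[0]
    o["t_a1"] = to[a1_i]
    o["t_a1b1"] = to[b1_i] - to[a1_i]
    o["t_a2b2"] = to[b2_i] - to[a2_i]
    o["t_b2e2"] = to[e2_i] - to[b2_i]
    base = y[0] + (y[-1] - y[0]) * to / to[-1]
    o["auc_total"] = np.trapezoid(y - base, to)
    o["auc1"] = np.trapezoid((y - base)[: sp_i + 1], to[: sp_i + 1])
    o["auc2"] = np.trapezoid((y - base)[sp_i:], to[sp_i:])
    o["mean_v"] = (y[-1] - y[0]) / to[-1]              # exact time-average
    o["idr_v"] = np.percentile(d1, 90) - np.percentile(d1, 10)
    o["mean_acc"] = (d1[-1] - d1[0]) / to[-1]          # exact time-average
    o["msv"] = d1[a1_i]
    o["sfv"] = d1[0]
    o["b2_amplitude"] = abs(d2[b2_i])
    o["b2_a2"] = abs(d2[b2_i]) / d2[a2_i]
    o["e2_a2"] = d2[e2_i] / d2[a2_i]
    for name, frac in morph.WIDTH_LEVELS.items():
        level = y[0] + frac * o["pwa"]
        jr = np.flatnonzero(y[:sp_i] < level)[-1]
        t_rise = to[jr] + (level - y[jr]) / (y[jr + 1] - y[jr]) / fso
        jf = sp_i + np.flatnonzero(y[sp_i:] < level)[0] - 1
        t_fall = to[jf] + (y[jf] - level) / (y[jf] - y[jf + 1]) / fso
        o[f"dw{name}_sw{name}"] = (t_fall - to[sp_i]) / (to[sp_i] - t_rise)
    o["t_s_pwd"] = (to[sp_i] - to[a1_i]) / o["pwd"]
    o["t_a1_pwd"] = o["t_a1"] / o["pwd"]
    o["t_a1b1_pwd"] = o["t_a1b1"] / o["pwd"]
    o["t_a2b2_pwd"] = o["t_a2b2"] / o["pwd"]
    o["t_b2e2_pwd"] = o["t_b2e2"] / o["pwd"]
    o["spd_pwd"] = o["spd"] / o["pwd"]
    o["sp_spd"] = o["pwa"] / o["spd"]
    o["pulsatility_index"] = (d1[a1_i] - d1[-1]) / o["mean_v"]
    o["slope_it_sp"] = (y[sp_i] - y[0]) / o["spd"]
    o["slope_sp_ft"] = (y[-1] - y[sp_i]) / o["dpd"]
    o["angle_alpha"] = np.degrees(np.arctan(1.0 / o["spd"]))
    o["angle_gamma"] = np.degrees(np.arctan(((y[-1] - y[sp_i]) / o["pwa"]) / o["dpd"]))
    return o


def assert_features_match_oracle(feats, oracle, fs, pwd):
    two_samples = 2.0 / fs
    time_like = {"pwd", "spd", "dpd", "t_a1", "t_a1b1", "t_a2b2", "t_b2e2"}
    time_ratio = {"t_s_pwd", "t_a1_pwd", "t_a1b1_pwd", "t_a2b2_pwd", "t_b2e2_pwd", "spd_pwd"}
    for key, expected in oracle.items():
        got = getattr(feats, key)
        assert np.isfinite(got), key
        if key in time_like:
            assert abs(got - expected) <= two_samples, key
        elif key in time_ratio:
            assert abs(got - expected) <= two_samples / pwd, key
        else:
            assert got == pytest.approx(expected, rel=0.02), key


@pytest.fixture
def sampled_pulse(template):
    t, pulse = template_pulse(template, fs=32.0, span=0.8)
    return pulse


class TestSegmentPulses:
    def _series(self, rec, beats):
        return ipi.extract_ipis(rec)

    def test_clean_trough_pairs_become_spans(self):
        beats = np.arange(41) * 0.75
        rec = synth.render_ppg(beats, duration=31.0)
        series = ipi.extract_ipis(rec)
        spans = morph.segment_pulses(rec, series)
        assert len(spans) == series.valid_mask.sum()

    def test_rejected_interval_excluded(self):
        beats = np.arange(41) * 0.75
        rec = synth.render_ppg(beats, duration=31.0)
        series = ipi.extract_ipis(rec)
        series.valid_mask[5] = False
        spans = morph.segment_pulses(rec, series)
        assert len(spans) == series.valid_mask.sum()

    def test_all_rejected_empty(self):
        beats = np.arange(41) * 0.75
        rec = synth.render_ppg(beats, duration=31.0)
        series = ipi.extract_ipis(rec)
        series.valid_mask[:] = False
        assert morph.segment_pulses(rec, series) == []


class TestLocateFiducials:
    def test_systolic_peak_within_one_sample(self, template, sampled_pulse):
        fid = morph.locate_fiducials(sampled_pulse, 32.0)
        assert fid.complete
        # analytic maximum of the closed form
        to = np.arange(0, 0.8, 1e-4)
        t_max = to[np.argmax(template.waveform(to))]
        assert abs(fid.sp - t_max) <= 1.0 / 32.0

    def test_derivative_fiducials_match_closed_form(self, template, sampled_pulse):
        fid = morph.locate_fiducials(sampled_pulse, 32.0)
        to = np.arange(0, 0.8, 1e-4)
        d1 = gaussian_d1(template, to)
        sp_i = np.argmax(template.waveform(to))
        t_a1 = to[np.argmax(d1[:sp_i])]
        assert abs(fid.a1 - t_a1) <= 1.0 / 32.0
        d2 = gaussian_d2(template, to)
        b2_region = (to > fid.a2) & (to < fid.sp + 0.25 * fid.ft)
        t_b2 = to[b2_region][np.argmin(d2[b2_region])]
        assert abs(fid.b2 - t_b2) <= 1.0 / 32.0

    def test_monotone_ramp_incomplete(self):
        fid = morph.locate_fiducials(np.linspace(0, 1, 30), 32.0)
        assert not fid.complete

    def test_ordering_invariants(self, sampled_pulse):
        fid = morph.locate_fiducials(sampled_pulse, 32.0)
        assert fid.it < fid.sp < fid.ft
        assert fid.it < fid.a1 < fid.sp
        assert fid.it < fid.a2 < fid.b2 < fid.e2 <= fid.ft

    def test_short_pulse_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            morph.locate_fiducials(np.zeros(5), 32.0)


class TestComputeFeatures:
    def test_symmetric_triangle(self):
        fs = 100.0
        n = 101
        pulse = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        fid = morph.PulseFiducials(it=0.0, sp=0.5, ft=1.0, complete=False)
        f = morph.compute_features(pulse, fid, fs)
        for name in morph.WIDTH_LEVELS:
            assert getattr(f, f"dw{name}_sw{name}") == pytest.approx(1.0, abs=0.02)
        assert f.spd_pwd == pytest.approx(0.5, abs=1e-6)
        assert f.slope_it_sp == pytest.approx(-f.slope_sp_ft, rel=1e-6)

    def test_asymmetric_triangle_geometry(self):
        # unit height, base 1 s, apex at 0.3 s
        fs = 1000.0
        t = np.arange(0, 1.0 + 1e-9, 1 / fs)
        pulse = np.where(t <= 0.3, t / 0.3, (1 - t) / 0.7)
        fid = morph.PulseFiducials(it=0.0, sp=0.3, ft=1.0, complete=False)
        f = morph.compute_features(pulse, fid, fs)
        assert f.auc_total == pytest.approx(0.5, rel=0.01)
        assert f.auc1 == pytest.approx(0.15, rel=0.01)
        assert f.auc2 == pytest.approx(0.35, rel=0.01)
        assert f.spd == pytest.approx(0.3, abs=1e-6)
        assert f.dpd == pytest.approx(0.7, abs=1e-6)

    def test_analytic_template_all_features(self, template, sampled_pulse):
        fid = morph.locate_fiducials(sampled_pulse, 32.0)
        feats = morph.compute_features(sampled_pulse, fid, 32.0)
        oracle = dense_oracle(template, span=(sampled_pulse.size - 1) / 32.0)
        assert_features_match_oracle(feats, oracle, 32.0, oracle["pwd"])

    def test_pwd_and_auc_identities(self, sampled_pulse):
        fid = morph.locate_fiducials(sampled_pulse, 32.0)
        f = morph.compute_features(sampled_pulse, fid, 32.0)
        assert f.pwd == pytest.approx(f.spd + f.dpd, abs=1e-12)
        assert f.auc_total == pytest.approx(f.auc1 + f.auc2, abs=1e-12)

    def test_amplitude_scaling_covariance(self, sampled_pulse):
        c = 0.5
        fid1 = morph.locate_fiducials(sampled_pulse, 32.0)
        fid2 = morph.locate_fiducials(c * sampled_pulse, 32.0)
        f1 = morph.compute_features(sampled_pulse, fid1, 32.0)
        f2 = morph.compute_features(c * sampled_pulse, fid2, 32.0)
        assert f2.pwa == pytest.approx(c * f1.pwa, rel=1e-9)
        assert f2.b2_amplitude == pytest.approx(c * f1.b2_amplitude, rel=1e-9)
        assert f2.auc_total == pytest.approx(c * f1.auc_total, rel=1e-9)
        assert f2.msv == pytest.approx(c * f1.msv, rel=1e-9)
        assert f2.slope_it_sp == pytest.approx(c * f1.slope_it_sp, rel=1e-9)
        # duration features and width ratios unchanged
        assert f2.pwd == f1.pwd and f2.spd == f1.spd
        assert f2.dw25_sw25 == pytest.approx(f1.dw25_sw25, rel=1e-9)
        # dimensionless second-derivative ratios unchanged
        assert f2.b2_a2 == pytest.approx(f1.b2_a2, rel=1e-9)

    def test_time_dilation_covariance(self, template):
        fs = 64.0
        t1, p1 = template_pulse(template, fs=fs, span=0.8)
        fid1 = morph.locate_fiducials(p1, fs)
        f1 = morph.compute_features(p1, fid1, fs)
        # the same samples played at half speed: durations double
        f2 = morph.compute_features(p1, morph.locate_fiducials(p1, fs / 2), fs / 2)
        assert f2.pwd == pytest.approx(2 * f1.pwd, rel=1e-9)
        assert f2.spd == pytest.approx(2 * f1.spd, rel=1e-9)
        # a1 is located on the internal fine grid: allow one fine-grid step
        assert f2.t_a1 == pytest.approx(2 * f1.t_a1, abs=1.1 / morph.UPSAMPLE_FS)
        assert f2.spd_pwd == pytest.approx(f1.spd_pwd, rel=1e-9)
        assert f2.dw25_sw25 == pytest.approx(f1.dw25_sw25, rel=1e-3)


class TestAggregate:
    def test_identical_pulses(self, sampled_pulse):
        fid = morph.locate_fiducials(sampled_pulse, 32.0)
        f = morph.compute_features(sampled_pulse, fid, 32.0)
        agg, n = morph.aggregate_segment([f, f, f])
        assert n == 3
        assert agg.pwa == f.pwa and agg.pwd == f.pwd

    def test_median_robust_to_outlier(self, sampled_pulse):
        fid = morph.locate_fiducials(sampled_pulse, 32.0)
        f = morph.compute_features(sampled_pulse, fid, 32.0)
        outlier = morph.compute_features(sampled_pulse * 10,
                                         morph.locate_fiducials(sampled_pulse * 10, 32.0), 32.0)
        agg, _ = morph.aggregate_segment([f] * 50 + [outlier])
        assert agg.pwa == f.pwa

    def test_mixed_pulses_equal_direct_median(self, template):
        feats = []
        for scale in (0.8, 1.0, 1.2, 1.4, 0.9):
            _, p = template_pulse(template)
            p = p * scale
            feats.append(morph.compute_features(p, morph.locate_fiducials(p, 32.0), 32.0))
        agg, _ = morph.aggregate_segment(feats)
        assert agg.pwa == pytest.approx(np.median([f.pwa for f in feats]), abs=1e-12)
        assert agg.msv == pytest.approx(np.median([f.msv for f in feats]), abs=1e-12)

    def test_empty_returns_none(self):
        agg, n = morph.aggregate_segment([])
        assert agg is None and n == 0


class TestEnsemble:
    def test_identical_pulses_reproduce_pulse(self, sampled_pulse):
        ens = morph.ensemble_average([sampled_pulse] * 5, day_index=0)
        expected = np.interp(ens.grid, np.linspace(0, 1, sampled_pulse.size), sampled_pulse)
        assert np.allclose(ens.waveform, expected)

    def test_single_pulse(self, sampled_pulse):
        ens = morph.ensemble_average([sampled_pulse], day_index=2)
        assert ens.n_pulses == 1

    def test_amplitude_preserved_not_normalized(self, sampled_pulse):
        e1 = morph.ensemble_average([sampled_pulse], day_index=0)
        e2 = morph.ensemble_average([0.5 * sampled_pulse], day_index=4)
        assert e2.waveform.max() == pytest.approx(0.5 * e1.waveform.max())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            morph.ensemble_average([], day_index=0)


class TestAnalyzeSegment:
    def test_clean_segment_yields_features(self):
        model = synth.BeatIntervalModel(mean_ipi=0.8, white_noise_sd=0.01, seed=4)
        beats, _ = synth.generate_beat_times(model, 120.0)
        rec = synth.render_ppg(beats, duration=120.0)
        series = ipi.extract_ipis(rec)
        agg, n, pulses = morph.analyze_segment(rec, series)
        assert agg is not None and n > 50
        assert len(pulses) == n
        assert agg.pwd == pytest.approx(agg.spd + agg.dpd, rel=0.05)

    def test_amplitude_attenuation_visible_in_features(self):
        model = synth.BeatIntervalModel(mean_ipi=0.8, white_noise_sd=0.005, seed=6)
        beats, _ = synth.generate_beat_times(model, 120.0)
        results = {}
        for scale in (1.0, 0.6):
            rec = synth.render_ppg(beats, duration=120.0, amplitude_scale=scale)
            series = ipi.extract_ipis(rec)
            agg, _, pulses = morph.analyze_segment(rec, series)
            ens = morph.ensemble_average(pulses, 0)
            results[scale] = (agg.pwa, agg.msv, ens.waveform.max())
        assert results[0.6][0] < results[1.0][0]
        assert results[0.6][1] < results[1.0][1]
        assert results[0.6][2] < results[1.0][2]
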