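# pulsekit

Analysis pipeline for wrist-worn photoplethysmography (PPG) recordings around
a multi-day medication schedule: from raw 32 Hz PPG to inter-pulse intervals,
heart-rate-variability (HRV) and pulse-wave-morphology features per study day,
and non-parametric day-wise comparisons with bootstrapped effect sizes.
Because clinical recordings of this kind are typically not shareable, the
package ships a first-class synthetic cohort generator with known ground
truth, so every stage is testable end to end.

## Modules

| Module | Purpose |
|---|---|
| `pulsekit.synth` | Synthetic PPG: sinusoidally modulated beat intervals (LF/HF bands), two-lobe pulse rendering, motion/detachment artifacts, multi-day cohorts with configurable day-wise effects (HR shift, HF suppression, amplitude attenuation) |
| `pulsekit.io_segments` | Recording/manifest CSV I/O, 5-minute analysis-window search (±4 h around the per-day target, 20% discarded-IPI quality gate), baseline assignment (day 0, else day 4) |
| `pulsekit.ipi` | Trough detection, inter-pulse intervals, physiological-range (0.4–2.0 s) and 20% successive-difference rejection, cubic-spline gap filling |
| `pulsekit.hrv` | HR, SDNN, RMSSD, pNN50; Welch-spectrum TP/LF/HF/LF-HF; Poincaré SD1/SD2; sample entropy (m=2, r=0.2·SD); DFA α1 over 4–16 beats |
| `pulsekit.morph` | Pulse segmentation, waveform/derivative fiducials (IT, SP, FT, a1, b1, EDV, a2, b2, e2), the full morphology feature catalogue, per-day ensemble-average pulses |
| `pulsekit.stats` | Friedman + Dunn (paired), Kruskal–Wallis + Dunn (unpaired), Bonferroni within each feature panel, bootstrap Cohen's d with percentile 95% CI |
| `pulsekit.pipeline` / `pulsekit.cli` | One-config orchestration: simulate → extract → features → compare → report |

## CLI

```bash
pulsekit run-all --seed 1 --out runs/demo        # full pipeline on a synthetic cohort
pulsekit simulate --config cfg.yaml --out cohort # cohort CSVs + manifest + truth table
pulsekit extract --manifest cohort/manifest.csv --tolerance-h 4 --out seg
pulsekit ipi --in cohort/P000_day1.csv --out ipis.csv
pulsekit features hrv --in ipis.csv
pulsekit compare --features hrv_features.csv --design paired --baseline baselines.csv --out results.csv
```

Configuration is one YAML file (seed, cohort design, day effects, window
tolerance, quality threshold, bootstrap iterations); a single root seed is
split into per-stage seeds so reruns are bit-for-bit reproducible.

## Output formats

All artifacts are plain CSV/markdown: per-recording `time_s,ppg` files, a
cohort manifest, a segment-selection report, feature tables (one row per
participant-day), tidy statistics results
(`feature, contrast, p_raw, p_adj, mean_d, ci_low, ci_high`), per-day
ensemble pulses, and a markdown comparison report.
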