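"""End-to-end orchestration: simulate → extract → features → compare → report."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import hrv, io_segments, ipi, morph, stats
from .config import RunConfig
from .report import render_report
from .synth import generate_cohort, write_cohort, _day_target_time

logger = logging.getLogger(__name__)


def extract_segments(
    manifest: pd.DataFrame,
    data_dir: Path,
    tolerance_h: float = 4.0,
    quality_threshold: float = io_segments.QUALITY_THRESHOLD,
) -> pd.DataFrame:
    """Select one 5-minute window per participant-day listed in the manifest."""
    rows = []
    for entry in manifest.itertuples():
        rec = io_segments.read_recording(data_dir / entry.file)
        injection1 = float(entry.injection1_time)
        injection2 = float(entry.injection2_time)
        day = int(entry.day)
        target = _day_target_time(day, injection1)
        cap = {0: injection1, 1: injection2}.get(day)
        candidates = io_segments.candidate_windows(
            rec, target, tolerance_h * 3600.0, cap_time=cap
        )
        window = io_segments.select_segment(
            candidates, rec, participant_id=entry.participant_id,
            day_index=day, threshold=quality_threshold,
        )
        rows.append(
            {
                "participant_id": entry.participant_id,
                "day": day,
                "file": entry.file,
                "start": window.start if window else np.nan,
                "discarded_fraction": window.discarded_ipi_fraction if window else np.nan,
                "accepted": bool(window.accepted) if window else False,
            }
        )
    return pd.DataFrame(rows)


def compute_cohort_features(
    segments: pd.DataFrame, data_dir: Path, smooth_window: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """HRV + morphology features for every accepted segment.

    Returns (hrv_table, morph_table, ensemble_table); tables are long-form with
    ``participant_id`` and ``day`` keys.
    """
    hrv_rows, morph_rows = [], []
    pulses_by_day: dict[int, list[np.ndarray]] = {}
    for entry in segments.itertuples():
        if not entry.accepted:
            continue
        rec = io_segments.read_recording(data_dir / entry.file)
        seg = rec.slice_time(float(entry.start), io_segments.SEGMENT_DURATION)
        try:
            series = ipi.extract_ipis(seg)
        except (ipi.SegmentQualityError, ValueError) as exc:
            logger.warning("segment %s day %s unusable: %s", entry.participant_id, entry.day, exc)
            continue
        feats = hrv.compute_features(series)
        hrv_rows.append(
            {"participant_id": entry.participant_id, "day": int(entry.day), **feats.as_row()}
        )
        agg, n_used, accepted_pulses = morph.analyze_segment(seg, series, smooth_window)
        if agg is not None:
            morph_rows.append(
                {
                    "participant_id": entry.participant_id,
                    "day": int(entry.day),
                    **agg.as_row(),
                    "n_pulses_used": n_used,
                }
            )
            pulses_by_day.setdefault(int(entry.day), []).extend(accepted_pulses)
    ens_rows = []
    for day in sorted(pulses_by_day):
        ens = morph.ensemble_average(pulses_by_day[day], day)
        for g, v in zip(ens.grid, ens.waveform):
            ens_rows.append({"day": day, "grid": g, "mean_ppg": v, "n_pulses": ens.n_pulses})
    return pd.DataFrame(hrv_rows), pd.DataFrame(morph_rows), pd.DataFrame(ens_rows)


def baseline_table(segments: pd.DataFrame) -> pd.DataFrame:
    """Baseline assignment per participant from accepted days."""
    rows = []
    for pid, sub in segments[segments["accepted"]].groupby("participant_id"):
        days = set(sub["day"].astype(int))
        assignment = io_segments.assign_baseline(pid, days)
        rows.append(
            {
                "participant_id": pid,
                "baseline_day": assignment.baseline_day if assignment else pd.NA,
                "source": assignment.source if assignment else "excluded",
                "paired_included": io_segments.paired_inclusion(days),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir: Optional[Path] = None) -> dict:
    """Run the full pipeline into a directory; deterministic under the config seed."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger().addHandler(handler)
    try:
        config.to_yaml(outdir / "config.yaml")
        logger.info("settings in effect: %s", dataclasses.asdict(config))

        cohort = generate_cohort(config.cohort_design())
        data_dir = write_cohort(cohort, outdir / "cohort")

        stage = "extract"
        segments = extract_segments(
            cohort.manifest, data_dir, config.tolerance_h, config.quality_threshold
        )
        segments.to_csv(outdir / "segments.csv", index=False)
        baselines = baseline_table(segments)
        baselines.to_csv(outdir / "baselines.csv", index=False)

        stage = "features"
        hrv_table, morph_table, ensembles = compute_cohort_features(segments, data_dir)
        hrv_table.to_csv(outdir / "hrv_features.csv", index=False)
        morph_table.to_csv(outdir / "morph_features.csv", index=False)
        ensembles.to_csv(outdir / "ensemble_pulses.csv", index=False)

        stage = "compare"
        included = baselines[baselines["paired_included"]]
        baseline_days = {
            r.participant_id: int(r.baseline_day) for r in included.itertuples()
        }
        if len(baseline_days) < 5:
            raise ValueError(
                f"only {len(baseline_days)} participants eligible for the paired analysis"
            )
        seed = config.stage_seed("compare")
        hrv_results = stats.run_paired_hrv_analysis(
            hrv_table, hrv.FEATURE_COLUMNS, baseline_days,
            n_boot=config.bootstrap_iterations, seed=seed,
        )
        morph_results = stats.run_unpaired_morph_analysis(
            morph_table, morph.FEATURE_NAMES,
            n_boot=config.bootstrap_iterations, seed=seed + 1,
        )
        stats.results_to_frame(hrv_results).to_csv(outdir / "hrv_results.csv", index=False)
        stats.results_to_frame(morph_results).to_csv(outdir / "morph_results.csv", index=False)
        (outdir / "report.md").write_text(render_report(hrv_results, morph_results))
        return {
            "outdir": outdir,
            "segments": segments,
            "baselines": baselines,
            "hrv_features": hrv_table,
            "morph_features": morph_table,
            "ensembles": ensembles,
            "hrv_results": hrv_results,
            "morph_results": morph_results,
        }
    except Exception:
        (outdir / "FAILED_STAGE").write_text(stage + "\n")
        logger.exception("pipeline failed during stage %s", stage)
        raise
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()
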