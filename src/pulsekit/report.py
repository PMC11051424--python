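"""Markdown report generation mimicking the per-feature figure annotation."""

from __future__ import annotations

from typing import Sequence

from .stats import ComparisonResult


def format_result(result: ComparisonResult, alpha: float = 0.05) -> str:
    lines = [f"### {result.feature}", ""]
    lines.append(
        f"Omnibus: statistic = {result.omnibus_stat:.3f}, p = {result.omnibus_p:.4g} "
        f"(n = {result.n})"
    )
    sig = [c for c in result.contrasts if c.p_adj < alpha]
    if sig:
        lines.append("")
        lines.append("Significant pairwise contrasts:")
        for c in sig:
            arrow = "↑" if c.z < 0 else "↓"  # second group relative to first
            d_txt = f", d = {c.mean_d:.2f} [{c.d_ci_low:.2f}, {c.d_ci_high:.2f}]" \
                if c.mean_d == c.mean_d else ""
            lines.append(
                f"- {c.group_a} → {c.group_b} {arrow}: p_adj = {c.p_adj:.4g}{d_txt}"
            )
    else:
        lines.append("No significant pairwise contrasts.")
    lines.append("")
    return "\n".join(lines)


def render_report(
    hrv_results: Sequence[ComparisonResult],
    morph_results: Sequence[ComparisonResult],
    alpha: float = 0.05,
) -> str:
    parts = ["# Comparison report", "", "## Paired HRV analysis", ""]
    for r in hrv_results:
        parts.append(format_result(r, alpha))
    parts += ["## Unpaired morphology analysis", ""]
    for r in morph_results:
        parts.append(format_result(r, alpha))
    return "\n".join(parts)
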