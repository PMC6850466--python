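"""Human-readable summaries of pipeline outputs.

Every number in the report is recomputed from the tables passed in (the
same tables the pipeline writes to CSV); the report performs no additional
modelling of its own.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .montecarlo import MEAN_PLOT_ID, METRICS

_UNITS = {"volume": "m3/ha", "carbon": "Mg C/ha"}


def collapse_effect_pct(estimates: pd.DataFrame, metric: str) -> float:
    """Mean % reduction from including collapse: (x_noCR - x_CR) / x_noCR."""
    col = "volume_m3_ha" if metric == "volume" else "carbon_MgC_ha"
    with_cr = estimates[col].mean()
    without_cr = estimates[f"{metric}_no_collapse"].mean()
    if without_cr == 0:
        return 0.0
    return float(100.0 * (without_cr - with_cr) / without_cr)


def hollow_effect_pct(estimates: pd.DataFrame, metric: str) -> float:
    """Mean % reduction from including hollowness."""
    col = "volume_m3_ha" if metric == "volume" else "carbon_MgC_ha"
    with_h = estimates[col].mean()
    without_h = estimates[f"{metric}_no_hollow"].mean()
    if without_h == 0:
        return 0.0
    return float(100.0 * (without_h - with_h) / without_h)


def summarize(
    results: pd.DataFrame,
    attribution: pd.DataFrame,
    baseline: Optional[pd.DataFrame] = None,
    estimates: Optional[pd.DataFrame] = None,
) -> str:
    """Markdown-ish run report: baseline means, interval widths, ranked
    per-source contributions, the quadrature cross-check, and the effect of
    the collapse/hollowness terms on the deterministic estimates."""
    lines = ["# Downed coarse woody debris uncertainty report", ""]
    for metric in METRICS:
        unit = _UNITS[metric]
        lines.append(f"## {metric} ({unit})")
        sub = results[
            (results["metric"] == metric) & (results["plot_id"] == MEAN_PLOT_ID)
        ]
        if baseline is not None:
            b = baseline[
                (baseline["metric"] == metric) & (baseline["plot_id"] == MEAN_PLOT_ID)
            ]
            if len(b):
                lines.append(f"- baseline mean (no uncertainty): "
                             f"{float(b['value'].iloc[0]):.3f} {unit}")
        all_rows = sub[sub["configuration"] == "all_sources"]
        if len(all_rows):
            r = all_rows.iloc[0]
            lines.append(
                f"- all-sources 95% CI: {r['ci95_width']:.3f} {unit} "
                f"(IQR {r['iqr']:.3f})"
            )
        att = attribution[attribution["metric"] == metric]
        single = att[~att["source"].isin(["all_sources", "quadrature"])]
        if len(single):
            lines.append("- per-source 95% CI, largest first:")
            for _, row in single.sort_values("ci95", ascending=False).iterrows():
                lines.append(f"    - {row['source']}: {row['ci95']:.3f} {unit}")
            quad = att[att["source"] == "quadrature"]
            allr = att[att["source"] == "all_sources"]
            if len(quad) and len(allr):
                q = float(quad["ci95"].iloc[0])
                a = float(allr["ci95"].iloc[0])
                rel = 100.0 * abs(q - a) / a if a else 0.0
                lines.append(
                    f"- quadrature vs Monte Carlo: {q:.3f} vs {a:.3f} {unit} "
                    f"({rel:.1f}% apart)"
                )
        if estimates is not None and f"{metric}_no_collapse" in estimates.columns:
            lines.append(
                f"- including collapse lowers the mean {metric} by "
                f"{collapse_effect_pct(estimates, metric):.1f}%"
            )
        if estimates is not None and f"{metric}_no_hollow" in estimates.columns:
            lines.append(
                f"- including hollowness lowers the mean {metric} by "
                f"{hollow_effect_pct(estimates, metric):.1f}%"
            )
        lines.append("")
    return "\n".join(lines)
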