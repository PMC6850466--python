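"""Model/Results interface over the propagation engine.

``UncertaintyModel`` bundles a plot inventory, transect designs, reference
tables and QA error models; ``fit()`` runs the Monte Carlo and returns an
``UncertaintyResults`` carrying per-plot distribution summaries, and
``attribute()`` returns an ``AttributionResults`` with one-source-at-a-time
interval widths and their quadrature combination.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimator import estimate_plots
from .montecarlo import (
    MEAN_PLOT_ID,
    METRICS,
    SOURCES,
    MCResult,
    SourceConfig,
    attribute_sources,
    run_mc,
)
from .pieces import DCWDPiece, PlotDesign, PlotEstimate
from .qa import ErrorModelSet
from .reference import ReferenceTables, default_tables

_UNITS = {"volume": "m3/ha", "carbon": "Mg C/ha"}


class UncertaintyModel:
    """Plot-level downed-wood uncertainty model.

    Parameters
    ----------
    plots
        Mapping of plot id to its tallied pieces.
    designs
        Mapping of plot id to transect geometry. Plots missing from the
        mapping get the default four-transect design.
    tables
        Density/collapse/carbon reference tables (defaults to the packaged
        synthetic tables).
    error_models
        Empirical QA error models; required for fitting.
    """

    def __init__(
        self,
        plots: Mapping[str, Sequence[DCWDPiece]],
        designs: Optional[Mapping[str, PlotDesign]] = None,
        tables: Optional[ReferenceTables] = None,
        error_models: Optional[ErrorModelSet] = None,
    ) -> None:
        self.plots = dict(plots)
        designs = dict(designs) if designs else {}
        for pid in self.plots:
            designs.setdefault(pid, PlotDesign(pid))
        self.designs = designs
        self.tables = tables if tables is not None else default_tables()
        self.error_models = error_models

    @classmethod
    def from_dataframe(
        cls,
        pieces: pd.DataFrame,
        paired: Optional[pd.DataFrame] = None,
        **kwargs,
    ) -> "UncertaintyModel":
        """Build from tidy DataFrames with the standard piece/paired columns."""
        from . import io as _io
        import io as _stdio

        buf = _stdio.StringIO()
        pieces.to_csv(buf, index=False)
        buf.seek(0)
        plots = _io.read_pieces(buf)
        error_models = kwargs.pop("error_models", None)
        if paired is not None and error_models is None:
            buf2 = _stdio.StringIO()
            paired.to_csv(buf2, index=False)
            buf2.seek(0)
            error_models = ErrorModelSet.from_pairs(_io.read_paired(buf2))
        return cls(plots, error_models=error_models, **kwargs)

    def estimate(self, use_collapse: bool = True, use_hollow: bool = True) -> List[PlotEstimate]:
        """Deterministic per-plot estimates (no uncertainty)."""
        return estimate_plots(
            self.plots, self.designs, self.tables,
            use_collapse=use_collapse, use_hollow=use_hollow,
        )

    def _require_errors(self) -> ErrorModelSet:
        if self.error_models is None:
            raise ValueError("error_models are required to fit the model")
        return self.error_models

    def fit(
        self,
        config: Optional[SourceConfig] = None,
        n_iterations: Optional[int] = None,
        seed: Optional[int] = None,
        keep_iterates: bool = True,
    ) -> "UncertaintyResults":
        """Run the Monte Carlo under ``config`` (default: all sources on)."""
        cfg = config if config is not None else SourceConfig()
        if n_iterations is not None:
            cfg = replace(cfg, n_iterations=n_iterations)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        result = run_mc(
            self.plots, self.designs, self.tables, self._require_errors(),
            cfg, keep_iterates=keep_iterates,
        )
        return UncertaintyResults(self, cfg, result)

    def attribute(
        self,
        config: Optional[SourceConfig] = None,
        sources: Sequence[str] = SOURCES,
        keep_iterates: bool = False,
    ) -> "AttributionResults":
        """All-sources run plus one run per single source, same seed policy."""
        cfg = config if config is not None else SourceConfig()
        result, attribution = attribute_sources(
            self.plots, self.designs, self.tables, self._require_errors(),
            cfg, sources=sources, keep_iterates=keep_iterates,
        )
        return AttributionResults(self, cfg, result, attribution)


class UncertaintyResults:
    """Monte Carlo distribution summaries for one source configuration."""

    def __init__(
        self, model: UncertaintyModel, config: SourceConfig, result: MCResult
    ) -> None:
        self.model = model
        self.config = config
        self.mc = result
        self.summaries = result.summaries
        self.baseline = result.baseline

    @property
    def configuration(self) -> str:
        return self.config.label

    def plot_ids(self) -> List[str]:
        return sorted(self.model.plots)

    def ci95(self, metric: str, plot_id: str = MEAN_PLOT_ID) -> float:
        return float(
            self.mc.summary_row(plot_id, self.configuration, metric)["ci95_width"]
        )

    def iterates(self, metric: str, plot_id: str = MEAN_PLOT_ID) -> np.ndarray:
        return self.mc.get_iterates(plot_id, self.configuration, metric)

    def summary(self) -> str:
        """Human-readable landscape-level summary table."""
        lines = [
            "Downed coarse woody debris uncertainty (Monte Carlo)",
            "=" * 64,
            f"plots: {len(self.model.plots)}   iterations: {self.config.n_iterations}"
            f"   seed: {self.config.seed}",
            f"active sources: {', '.join(self.config.active_sources()) or 'none'}",
            "-" * 64,
            f"{'metric':<10}{'baseline':>12}{'median':>12}{'IQR':>10}{'CI95':>10}",
        ]
        for metric in METRICS:
            try:
                row = self.mc.summary_row(MEAN_PLOT_ID, self.configuration, metric)
                base = self.mc.baseline_value(MEAN_PLOT_ID, metric)
            except (KeyError, IndexError):
                continue
            lines.append(
                f"{metric + ' (' + _UNITS[metric] + ')':<10}"
                f"{base:>12.2f}{row['median']:>12.2f}"
                f"{row['iqr']:>10.2f}{row['ci95_width']:>10.2f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<UncertaintyResults: {len(self.model.plots)} plots, "
            f"{self.config.n_iterations} iterations, '{self.configuration}'>"
        )


class AttributionResults(UncertaintyResults):
    """Per-source interval widths plus the quadrature comparison."""

    def __init__(
        self,
        model: UncertaintyModel,
        config: SourceConfig,
        result: MCResult,
        attribution: pd.DataFrame,
    ) -> None:
        super().__init__(model, replace(config, name="all_sources"), result)
        self.attribution = attribution

    def source_ci95(self, source: str, metric: str) -> float:
        df = self.attribution
        m = (df["source"] == source) & (df["metric"] == metric)
        return float(df.loc[m, "ci95"].iloc[0])

    def quadrature(self, metric: str) -> float:
        return self.source_ci95("quadrature", metric)

    def summary(self) -> str:
        lines = [super().summary(), "", "Source attribution (CI95 of the cross-plot mean)"]
        for metric in METRICS:
            df = self.attribution[self.attribution["metric"] == metric]
            single = df[~df["source"].isin(["all_sources", "quadrature"])]
            ranked = single.sort_values("ci95", ascending=False)
            lines.append(f"  {metric} ({_UNITS[metric]}):")
            for _, row in ranked.iterrows():
                lines.append(f"    {row['source']:<22}{row['ci95']:>10.3f}")
            lines.append(
                f"    {'quadrature combined':<22}{self.quadrature(metric):>10.3f}"
            )
            lines.append(
                f"    {'all-sources MC':<22}"
                f"{self.source_ci95('all_sources', metric):>10.3f}"
            )
        return "\n".join(lines)
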