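"""Monte Carlo propagation of measurement and conversion uncertainty.

Each iteration perturbs the field record of every piece through the active
uncertainty sources — diameter and cavity diameter via empirical difference
resampling, decay class and species via row-conditional confusion draws,
collapse ratio via uniform draws from decay-class pools, density reduction
and carbon concentration via truncated-normal draws — and recomputes the
plot estimator. Inactive sources keep their nominal values (the measured
value, the class-mean collapse ratio, the mean reduction factor, the mean
carbon fraction). Uncertainty is summarised as the width between the 2.5th
and 97.5th percentiles of the resulting distribution.

Randomness is stream-split: a root seed spawns one independent substream
per (plot, iteration), so plot order and parallelism cannot change results.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimator import qualifies_as_dcwd
from .pieces import MIN_TALLY_DIAMETER_CM, DCWDPiece, PlotDesign
from .qa import ConfusionModel, ContinuousErrorModel, ErrorModelSet, group_confusion_rows
from .reference import (
    GROUPS,
    ReferenceTables,
    ResolutionError,
    resolve_entry,
    truncnorm_positive,
)

SOURCES = (
    "diameter",
    "hollowness",
    "decay_class",
    "species",
    "collapse_ratio",
    "density_reduction",
    "carbon_concentration",
)
METRICS = ("volume", "carbon")

#: Pseudo plot id for the cross-plot mean distribution (the per-iteration
#: mean over all plots, the quantity behind landscape-level boxplots).
MEAN_PLOT_ID = "__mean__"


@dataclass(frozen=True)
class SourceConfig:
    """Which uncertainty sources are active, plus run-level settings."""

    diameter: bool = True
    hollowness: bool = True
    decay_class: bool = True
    species: bool = True
    collapse_ratio: bool = True
    density_reduction: bool = True
    carbon_concentration: bool = True
    n_iterations: int = 10_000
    seed: int = 0
    use_collapse: bool = True
    use_hollow: bool = True
    subthreshold_rule: str = "clamp"  # 'clamp' or 'drop'
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.subthreshold_rule not in ("clamp", "drop"):
            raise ValueError("subthreshold_rule must be 'clamp' or 'drop'")

    def active_sources(self) -> Tuple[str, ...]:
        return tuple(s for s in SOURCES if getattr(self, s))

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        active = self.active_sources()
        if len(active) == len(SOURCES):
            return "all_sources"
        if not active:
            return "none"
        if len(active) == 1:
            return active[0]
        return "+".join(active)

    @classmethod
    def all_off(cls, **kw) -> "SourceConfig":
        flags = {s: False for s in SOURCES}
        flags.update(kw)
        return cls(**flags)

    @classmethod
    def single(cls, source: str, **kw) -> "SourceConfig":
        if source not in SOURCES:
            raise ValueError(f"unknown source '{source}'")
        flags = {s: (s == source) for s in SOURCES}
        flags.update(kw)
        return cls(name=source, **flags)


# ---------------------------------------------------------------------------
# summaries


def ci95(iterates: Sequence[float]) -> float:
    """95% interval width: 97.5th minus 2.5th percentile (linear interp)."""
    arr = np.asarray(iterates, dtype=float)
    if arr.size < 2:
        raise ValueError("ci95 needs at least 2 iterates")
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return float(hi - lo)


def quadrature_combine(per_source_ci_widths: Sequence[float]) -> float:
    """Root-sum-of-squares combination of independent interval widths."""
    widths = np.asarray(per_source_ci_widths, dtype=float)
    if np.any(widths < 0):
        raise ValueError("interval widths must be non-negative")
    return float(np.sqrt(np.sum(widths**2)))


def _summarise(arr: np.ndarray) -> Dict[str, float]:
    p2_5, p25, p50, p75, p97_5 = np.percentile(arr, [2.5, 25, 50, 75, 97.5])
    return {
        "mean": float(np.mean(arr)),
        "median": float(p50),
        "p2_5": float(p2_5),
        "p25": float(p25),
        "p75": float(p75),
        "p97_5": float(p97_5),
        "iqr": float(p75 - p25),
        "ci95_width": float(p97_5 - p2_5),
    }


@dataclass
class MCResult:
    """Summaries (and retained iterates) of one or more propagation runs."""

    summaries: pd.DataFrame
    baseline: pd.DataFrame
    iterates: Dict[Tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def configurations(self) -> List[str]:
        return sorted(self.summaries["configuration"].unique())

    def get_iterates(self, plot_id: str, configuration: str, metric: str) -> np.ndarray:
        return self.iterates[(plot_id, configuration, metric)]

    def summary_row(self, plot_id: str, configuration: str, metric: str) -> pd.Series:
        df = self.summaries
        m = (
            (df["plot_id"] == plot_id)
            & (df["configuration"] == configuration)
            & (df["metric"] == metric)
        )
        sub = df[m]
        if len(sub) != 1:
            raise KeyError((plot_id, configuration, metric))
        return sub.iloc[0]

    def baseline_value(self, plot_id: str, metric: str) -> float:
        df = self.baseline
        m = (df["plot_id"] == plot_id) & (df["metric"] == metric)
        return float(df.loc[m, "value"].iloc[0])

    @classmethod
    def merge(cls, results: Sequence["MCResult"]) -> "MCResult":
        summaries = pd.concat([r.summaries for r in results], ignore_index=True)
        baseline = results[0].baseline
        iterates: Dict[Tuple[str, str, str], np.ndarray] = {}
        for r in results:
            iterates.update(r.iterates)
        return cls(summaries=summaries, baseline=baseline, iterates=iterates)


# ---------------------------------------------------------------------------
# compiled propagation context


@dataclass
class _Context:
    """Reference tables + error models compiled to flat arrays."""

    species_index: Dict[str, int]
    BD: np.ndarray          # (S,) initial density
    DRM: np.ndarray         # (S, 5) reduction means
    DRS: np.ndarray         # (S, 5) reduction SEs
    GRP: np.ndarray         # (S,) group index into CCM/CCS
    CCM: np.ndarray         # (3,) carbon means by group
    CCS: np.ndarray         # (3,) carbon SEs
    cr_pools: List[np.ndarray]   # index 0 unused; 1..5 class pools
    cr_means: np.ndarray         # (5,) class means (index class-1)
    diam_diffs: np.ndarray
    hollow_diffs: Optional[np.ndarray]
    decay_rows: Dict[int, np.ndarray]
    species_rows: Dict[int, np.ndarray]


@dataclass
class _PlotArrays:
    plot_id: str
    K: float                 # pi^2 / (8 L)
    di0: np.ndarray
    dh0: np.ndarray
    decay0: np.ndarray
    sp0: np.ndarray
    hollow_idx: np.ndarray   # indices of pieces recorded hollow
    decay_groups: List[Tuple[int, np.ndarray]]
    species_groups: List[Tuple[int, np.ndarray]]
    n: int


def _compile_context(
    plots: Mapping[str, Sequence[DCWDPiece]],
    tables: ReferenceTables,
    error_models: ErrorModelSet,
) -> _Context:
    # registry: species in the data plus any species a confusion draw can
    # introduce, plus confusion-row keys (fallback targets).
    codes: set[str] = set()
    for pieces in plots.values():
        codes.update(p.species_code for p in pieces)
    for prod, qa_vals in error_models.species.rows.items():
        codes.add(str(prod))
        codes.update(str(v) for v in qa_vals)
    order = sorted(codes)
    species_index = {c: i for i, c in enumerate(order)}

    S = len(order)
    BD = np.empty(S)
    DRM = np.empty((S, 5))
    DRS = np.empty((S, 5))
    GRP = np.empty(S, dtype=np.intp)
    group_idx = {g: i for i, g in enumerate(GROUPS)}
    for code, i in species_index.items():
        try:
            entry = resolve_entry(code, tables)
        except ResolutionError as exc:
            raise ResolutionError(
                f"cannot propagate: species '{code}' is unresolvable ({exc})"
            ) from exc
        BD[i] = entry.initial_density_g_cm3
        DRM[i] = entry.reduction_mean
        DRS[i] = entry.reduction_se
        GRP[i] = group_idx[entry.group]

    CCM = np.array([tables.carbon.params[g][0] for g in GROUPS])
    CCS = np.array([tables.carbon.params[g][1] for g in GROUPS])

    cr_pools: List[np.ndarray] = [np.empty(0)]
    cr_means = np.empty(5)
    for c in range(1, 6):
        pool = np.asarray(tables.collapse.values(c), dtype=float)
        cr_pools.append(pool)
        cr_means[c - 1] = np.mean(pool)

    decay_rows = {
        int(k): np.asarray(v, dtype=np.intp)
        for k, v in error_models.decay_class.rows.items()
    }

    # species rows in index space; fallback: group aggregate row, else identity
    grp_rows = group_confusion_rows(error_models.species, tables)
    species_rows: Dict[int, np.ndarray] = {}
    model_rows = {str(k): v for k, v in error_models.species.rows.items()}
    inv_groups = {i: g for g, i in group_idx.items()}
    for code, i in species_index.items():
        if code in model_rows:
            vals = model_rows[code]
        else:
            g = inv_groups[int(GRP[i])]
            vals = grp_rows.get(g, (code,))
        species_rows[i] = np.asarray(
            [species_index[str(v)] for v in vals if str(v) in species_index],
            dtype=np.intp,
        )
        if species_rows[i].size == 0:
            species_rows[i] = np.asarray([i], dtype=np.intp)

    return _Context(
        species_index=species_index,
        BD=BD, DRM=DRM, DRS=DRS, GRP=GRP, CCM=CCM, CCS=CCS,
        cr_pools=cr_pools, cr_means=cr_means,
        diam_diffs=np.asarray(error_models.diameter.difference_samples, dtype=float),
        hollow_diffs=(
            np.asarray(error_models.hollow_diameter.difference_samples, dtype=float)
            if error_models.hollow_diameter is not None
            else None
        ),
        decay_rows=decay_rows,
        species_rows=species_rows,
    )


def _compile_plot(
    plot_id: str,
    pieces: Sequence[DCWDPiece],
    design: PlotDesign,
    ctx: _Context,
) -> _PlotArrays:
    kept = [p for p in pieces if qualifies_as_dcwd(p)]
    n = len(kept)
    di0 = np.array([p.diameter_cm for p in kept], dtype=float)
    dh0 = np.array([p.hollow_diameter_cm for p in kept], dtype=float)
    decay0 = np.array([p.decay_class for p in kept], dtype=np.intp)
    sp0 = np.array([ctx.species_index[p.species_code] for p in kept], dtype=np.intp)
    hollow_idx = np.nonzero(dh0 > 0)[0]
    decay_groups = [
        (c, np.nonzero(decay0 == c)[0]) for c in sorted(set(decay0.tolist()))
    ]
    species_groups = [
        (s, np.nonzero(sp0 == s)[0]) for s in sorted(set(sp0.tolist()))
    ]
    return _PlotArrays(
        plot_id=plot_id,
        K=math.pi**2 / (8.0 * design.total_length_m),
        di0=di0, dh0=dh0, decay0=decay0, sp0=sp0,
        hollow_idx=hollow_idx,
        decay_groups=decay_groups,
        species_groups=species_groups,
        n=n,
    )


def _evaluate(
    pa: _PlotArrays,
    ctx: _Context,
    cfg: SourceConfig,
    rng: Optional[np.random.Generator],
) -> Tuple[float, float]:
    """One estimator evaluation under the active sources. rng=None => nominal."""
    if pa.n == 0:
        return 0.0, 0.0
    n = pa.n
    keep: Optional[np.ndarray] = None

    di = pa.di0
    if cfg.diameter and rng is not None:
        di = di + ctx.diam_diffs[rng.integers(0, ctx.diam_diffs.size, size=n)]
        if cfg.subthreshold_rule == "clamp":
            di = np.maximum(di, MIN_TALLY_DIAMETER_CM)
        else:
            keep = di > MIN_TALLY_DIAMETER_CM

    dh = pa.dh0
    if (
        cfg.hollowness
        and rng is not None
        and ctx.hollow_diffs is not None
        and pa.hollow_idx.size > 0
    ):
        dh = dh.copy()
        draws = ctx.hollow_diffs[
            rng.integers(0, ctx.hollow_diffs.size, size=pa.hollow_idx.size)
        ]
        dh[pa.hollow_idx] = dh[pa.hollow_idx] + draws
    if di is not pa.di0 or dh is not pa.dh0:
        dh = np.clip(dh, 0.0, di)

    decay = pa.decay0
    if cfg.decay_class and rng is not None:
        decay = decay.copy()
        for c, idx in pa.decay_groups:
            row = ctx.decay_rows.get(c)
            if row is None:
                continue  # identity fallback
            decay[idx] = row[rng.integers(0, row.size, size=idx.size)]

    sp = pa.sp0
    if cfg.species and rng is not None:
        sp = sp.copy()
        for s, idx in pa.species_groups:
            row = ctx.species_rows[s]
            sp[idx] = row[rng.integers(0, row.size, size=idx.size)]

    k = decay - 1
    if cfg.use_collapse:
        if cfg.collapse_ratio and rng is not None:
            cr = np.empty(n)
            for c in range(1, 6):
                idx = np.nonzero(decay == c)[0]
                if idx.size:
                    pool = ctx.cr_pools[c]
                    cr[idx] = pool[rng.integers(0, pool.size, size=idx.size)]
        else:
            cr = ctx.cr_means[k]
        term = (di * di - (dh * dh if cfg.use_hollow else 0.0)) * cr
    else:
        term = di * di - (dh * dh if cfg.use_hollow else 0.0)

    dr_mean = ctx.DRM[sp, k]
    if cfg.density_reduction and rng is not None:
        dr = truncnorm_positive(dr_mean, ctx.DRS[sp, k], rng)
    else:
        dr = dr_mean

    grp = ctx.GRP[sp]
    cc_mean = ctx.CCM[grp]
    if cfg.carbon_concentration and rng is not None:
        cc = truncnorm_positive(cc_mean, ctx.CCS[grp], rng)
    else:
        cc = cc_mean

    if keep is not None:
        term = np.where(keep, term, 0.0)
    volume = pa.K * float(np.sum(term))
    carbon = pa.K * float(np.sum(term * ctx.BD[sp] * dr * cc))
    return volume, carbon


# ---------------------------------------------------------------------------
# public engine


def run_mc(
    plots: Mapping[str, Sequence[DCWDPiece]],
    designs: Mapping[str, PlotDesign],
    tables: ReferenceTables,
    error_models: ErrorModelSet,
    config: SourceConfig,
    keep_iterates: bool = True,
) -> MCResult:
    """Propagate the active uncertainty sources through every plot.

    Returns per-plot iterate summaries for both metrics, the cross-plot mean
    distribution (pseudo-plot ``__mean__``), and the deterministic
    no-uncertainty baseline. Fully reproducible: substream ``[seed,
    plot_index, iteration]`` drives all draws for that plot-iteration.
    """
    ctx = _compile_context(plots, tables, error_models)
    plot_ids = sorted(plots)
    compiled = [
        _compile_plot(pid, plots[pid], designs[pid], ctx) for pid in plot_ids
    ]
    n_iter = config.n_iterations
    label = config.label

    vol = np.empty((len(compiled), n_iter))
    car = np.empty((len(compiled), n_iter))
    any_active = bool(config.active_sources())
    for p_idx, pa in enumerate(compiled):
        for it in range(n_iter):
            rng = (
                np.random.default_rng([config.seed, p_idx, it])
                if any_active
                else None
            )
            vol[p_idx, it], car[p_idx, it] = _evaluate(pa, ctx, config, rng)

    baseline_rows = []
    base_vals = {}
    for pa in compiled:
        bv, bc = _evaluate(pa, ctx, config, rng=None)
        base_vals[pa.plot_id] = (bv, bc)
        baseline_rows.append({"plot_id": pa.plot_id, "metric": "volume", "value": bv})
        baseline_rows.append({"plot_id": pa.plot_id, "metric": "carbon", "value": bc})
    if compiled:
        baseline_rows.append(
            {"plot_id": MEAN_PLOT_ID, "metric": "volume",
             "value": float(np.mean([v for v, _ in base_vals.values()]))}
        )
        baseline_rows.append(
            {"plot_id": MEAN_PLOT_ID, "metric": "carbon",
             "value": float(np.mean([c for _, c in base_vals.values()]))}
        )

    rows = []
    iterates: Dict[Tuple[str, str, str], np.ndarray] = {}
    metric_arrays = {"volume": vol, "carbon": car}
    for metric, arr in metric_arrays.items():
        for p_idx, pa in enumerate(compiled):
            s = _summarise(arr[p_idx])
            s.update(plot_id=pa.plot_id, configuration=label, metric=metric)
            rows.append(s)
            if keep_iterates:
                iterates[(pa.plot_id, label, metric)] = arr[p_idx].copy()
        if compiled:
            mean_iter = arr.mean(axis=0)
            s = _summarise(mean_iter)
            s.update(plot_id=MEAN_PLOT_ID, configuration=label, metric=metric)
            rows.append(s)
            if keep_iterates:
                iterates[(MEAN_PLOT_ID, label, metric)] = mean_iter

    columns = [
        "plot_id", "configuration", "metric",
        "mean", "median", "p2_5", "p25", "p75", "p97_5", "iqr", "ci95_width",
    ]
    summaries = pd.DataFrame(rows, columns=columns)
    baseline = pd.DataFrame(baseline_rows, columns=["plot_id", "metric", "value"])
    return MCResult(summaries=summaries, baseline=baseline, iterates=iterates)


def attribute_sources(
    plots: Mapping[str, Sequence[DCWDPiece]],
    designs: Mapping[str, PlotDesign],
    tables: ReferenceTables,
    error_models: ErrorModelSet,
    base_config: SourceConfig,
    sources: Sequence[str] = SOURCES,
    keep_iterates: bool = False,
) -> Tuple[MCResult, pd.DataFrame]:
    """One-source-at-a-time attribution plus quadrature comparison.

    Runs the engine with all of ``sources`` active, then once per single
    source (same seed policy each run), and tabulates the 95% interval width
    of the cross-plot mean per source, their root-sum-of-squares
    combination, and the all-sources Monte Carlo value.
    """
    runs: List[MCResult] = []
    all_cfg = replace(
        base_config,
        name="all_sources",
        **{s: (s in sources) for s in SOURCES},
    )
    runs.append(
        run_mc(plots, designs, tables, error_models, all_cfg, keep_iterates)
    )
    for s in sources:
        cfg = replace(
            base_config, name=s, **{t: (t == s) for t in SOURCES}
        )
        runs.append(run_mc(plots, designs, tables, error_models, cfg, keep_iterates))
    merged = MCResult.merge(runs)

    att_rows = []
    for metric in METRICS:
        widths = []
        for s in sources:
            row = merged.summary_row(MEAN_PLOT_ID, s, metric)
            widths.append(row["ci95_width"])
            att_rows.append(
                {"source": s, "metric": metric,
                 "ci95": row["ci95_width"], "iqr": row["iqr"]}
            )
        all_row = merged.summary_row(MEAN_PLOT_ID, "all_sources", metric)
        att_rows.append(
            {"source": "all_sources", "metric": metric,
             "ci95": all_row["ci95_width"], "iqr": all_row["iqr"]}
        )
        att_rows.append(
            {"source": "quadrature", "metric": metric,
             "ci95": quadrature_combine(widths), "iqr": float("nan")}
        )
    attribution = pd.DataFrame(att_rows, columns=["source", "metric", "ci95", "iqr"])
    return merged, attribution
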