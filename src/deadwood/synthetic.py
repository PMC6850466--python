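"""Synthetic landscape generator: noise-free truth plus two crews' records.

The generator emulates the statistical structure of a northeastern-US
downed-wood inventory: four 14.6 m transects per plot, ~6.5 tallied pieces
per plot, lognormal intersect diameters (mean ~14 cm), a decay-class mix
peaked at class 3, hollow pieces rare and concentrated in classes 3-4, and
crews that read diameters to the nearest inch (2.54 cm) so paired diameter
differences fall on a discrete grid. The QA crew is treated as the
reference (error-free before rounding) and the production crew carries the
configured error processes; both sides are configurable.

Because the truth record stores the realized collapse ratio, density
reduction, and carbon fraction of every piece, the propagation model can be
matched exactly to the generative process, which is what makes coverage
(parameter-recovery) testing meaningful.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimator import PieceFactors, plot_carbon, plot_volume
from .montecarlo import MCResult, MEAN_PLOT_ID
from .pieces import (
    SENTINEL_SPECIES,
    UNKNOWN,
    UNKNOWN_HARDWOOD,
    UNKNOWN_SOFTWOOD,
    DCWDPiece,
    PairedObservation,
    PlotDesign,
)
from .reference import (
    ReferenceTables,
    default_tables,
    resolve_entry,
    truncnorm_positive,
)


class ConfigError(ValueError):
    pass


#: Default decay-class confusion (row: true class, column: production call).
#: Diagonals follow observed production/QA agreement rates by class
#: (0.89/0.51/0.77/0.65/0.57) with off-diagonal mass biased toward class 3,
#: the pattern expected when crews hedge toward central classes.
DEFAULT_DECAY_CONFUSION = (
    (0.89, 0.10, 0.01, 0.00, 0.00),
    (0.07, 0.51, 0.40, 0.02, 0.00),
    (0.005, 0.10, 0.77, 0.12, 0.005),
    (0.00, 0.02, 0.28, 0.65, 0.05),
    (0.00, 0.00, 0.08, 0.35, 0.57),
)

IDENTITY_CONFUSION = tuple(
    tuple(1.0 if i == j else 0.0 for j in range(5)) for i in range(5)
)

#: Default species pool (code, relative frequency); ~73% hardwood incl.
#: sentinels, matching the regional hardwood share.
DEFAULT_SPECIES_POOL = (
    ("acer_rubrum", 0.14),
    ("acer_saccharum", 0.10),
    ("betula_papyrifera", 0.07),
    ("betula_alleghaniensis", 0.06),
    ("fagus_grandifolia", 0.08),
    ("quercus_rubra", 0.07),
    ("prunus_serotina", 0.05),
    ("populus_tremuloides", 0.05),
    (UNKNOWN_HARDWOOD, 0.10),
    (UNKNOWN, 0.01),
    ("picea_rubens", 0.06),
    ("picea_glauca", 0.03),
    ("pinus_strobus", 0.05),
    ("pinus_resinosa", 0.03),
    ("tsuga_canadensis", 0.05),
    ("abies_balsamea", 0.03),
    (UNKNOWN_SOFTWOOD, 0.02),
)


@dataclass(frozen=True)
class SpeciesErrorSpec:
    """Production-crew species identification behaviour.

    With probability ``p_correct`` the crew names the true species; with
    ``p_unknown_group`` it falls back to the unknown-hardwood/softwood
    sentinel of the true group; with ``p_wrong_species`` it names another
    pool species of the same group; the remainder goes to plain 'unknown'.
    Sentinel truths are kept as-is.
    """

    p_correct: float = 0.79
    p_unknown_group: float = 0.15
    p_wrong_species: float = 0.05

    def __post_init__(self) -> None:
        total = self.p_correct + self.p_unknown_group + self.p_wrong_species
        if not 0 <= total <= 1 + 1e-9:
            raise ConfigError("species error probabilities exceed 1")


@dataclass(frozen=True)
class CrewErrorSpec:
    """Error processes of one crew, applied in continuous space pre-rounding."""

    diameter_sd_cm: float = 1.3
    hollow_sd_cm: float = 1.5
    decay_confusion: Tuple[Tuple[float, ...], ...] = DEFAULT_DECAY_CONFUSION
    species: SpeciesErrorSpec = field(default_factory=SpeciesErrorSpec)

    def __post_init__(self) -> None:
        if self.diameter_sd_cm < 0 or self.hollow_sd_cm < 0:
            raise ConfigError("error SDs must be >= 0")
        for row in self.decay_confusion:
            if abs(sum(row) - 1.0) > 1e-9 or any(p < 0 for p in row):
                raise ConfigError("decay confusion rows must be probability vectors")


EXACT_CREW = CrewErrorSpec(
    diameter_sd_cm=0.0,
    hollow_sd_cm=0.0,
    decay_confusion=IDENTITY_CONFUSION,
    species=SpeciesErrorSpec(1.0, 0.0, 0.0),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Landscape and crew-error settings for the generator."""

    n_plots: int = 79
    mean_pieces_per_plot: float = 6.5
    diameter_lognorm_median_cm: float = 12.5
    diameter_lognorm_sigma: float = 0.45
    decay_probs: Tuple[float, ...] = (0.07, 0.17, 0.52, 0.22, 0.02)
    hollow_prob_by_class: Tuple[float, ...] = (0.0, 0.023, 0.037, 0.108, 0.0)
    hollow_ratio_range: Tuple[float, float] = (0.2, 0.6)
    species_pool: Tuple[Tuple[str, float], ...] = DEFAULT_SPECIES_POOL
    production: CrewErrorSpec = field(default_factory=CrewErrorSpec)
    qa: CrewErrorSpec = EXACT_CREW
    rounding_grid_cm: float = 2.54
    n_transects: int = 4
    transect_length_m: float = 14.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ConfigError("n_plots must be >= 1")
        for name, probs in (
            ("decay_probs", self.decay_probs),
            ("species_pool", tuple(f for _, f in self.species_pool)),
        ):
            if any(p < 0 for p in probs):
                raise ConfigError(f"{name} must be non-negative")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(probs)})")
        if len(self.decay_probs) != 5 or len(self.hollow_prob_by_class) != 5:
            raise ConfigError("decay/hollow vectors need 5 entries")
        if self.mean_pieces_per_plot <= 0 or self.diameter_lognorm_median_cm <= 0:
            raise ConfigError("scale parameters must be > 0")


@dataclass
class TruthRecord:
    """Noise-free plot: true pieces, realized multipliers, true estimates."""

    plot_id: str
    design: PlotDesign
    pieces: List[DCWDPiece]
    cr: np.ndarray
    dr: np.ndarray
    cc: np.ndarray
    true_volume_m3_ha: float
    true_carbon_MgC_ha: float


def _group_of(code: str, tables: ReferenceTables) -> str:
    gg = tables.genus_group_of(code)
    if gg is None:
        raise ConfigError(f"species '{code}' has no group metadata")
    return gg[1]


def generate_landscape(
    config: SyntheticConfig,
    tables: Optional[ReferenceTables] = None,
) -> Tuple[List[TruthRecord], Dict[str, PlotDesign]]:
    """Draw a landscape of noise-free plots.

    Piece counts are Poisson, diameters lognormal truncated above the tally
    threshold, decay classes and species multinomial; each piece receives a
    realized collapse ratio (uniform over its class pool), density-reduction
    factor and carbon fraction (truncated-normal). True volume and carbon
    are computed through the plot estimator with those realizations, so the
    stored truth is exactly what the estimator returns on the truth inputs.
    """
    tables = tables if tables is not None else default_tables()
    rng = np.random.default_rng([config.seed, 0])
    codes = [c for c, _ in config.species_pool]
    freqs = np.array([f for _, f in config.species_pool])
    decay_probs = np.array(config.decay_probs)

    truths: List[TruthRecord] = []
    designs: Dict[str, PlotDesign] = {}
    n_digits = len(str(config.n_plots))
    for p in range(config.n_plots):
        plot_id = f"P{p + 1:0{n_digits}d}"
        design = PlotDesign(plot_id, config.n_transects, config.transect_length_m)
        designs[plot_id] = design
        n = int(rng.poisson(config.mean_pieces_per_plot))
        pieces: List[DCWDPiece] = []
        cr_list: List[float] = []
        dr_list: List[float] = []
        cc_list: List[float] = []
        mu = math.log(config.diameter_lognorm_median_cm)
        for t in range(n):
            # rejection sampling above the 7.6 cm tally threshold
            while True:
                di = float(rng.lognormal(mu, config.diameter_lognorm_sigma))
                if di > 7.6:
                    break
            decay = int(rng.choice(5, p=decay_probs)) + 1
            code = codes[int(rng.choice(len(codes), p=freqs))]
            dh = 0.0
            if rng.random() < config.hollow_prob_by_class[decay - 1]:
                lo, hi = config.hollow_ratio_range
                dh = di * float(rng.uniform(lo, hi))
            piece = DCWDPiece(
                plot_id=plot_id,
                subplot_id=int(rng.integers(1, config.n_transects + 1)),
                position_m=float(rng.uniform(0.0, config.transect_length_m)),
                diameter_cm=di,
                hollow_diameter_cm=dh,
                species_code=code,
                decay_class=decay,
            )
            pieces.append(piece)
            pool = tables.collapse.values(decay)
            cr_list.append(float(pool[rng.integers(len(pool))]))
            entry = resolve_entry(code, tables)
            dr_list.append(
                float(truncnorm_positive(
                    entry.reduction_mean[decay - 1],
                    entry.reduction_se[decay - 1], rng, size=(),
                ))
            )
            cc_mean, cc_se = tables.carbon.params[entry.group]
            cc_list.append(float(truncnorm_positive(cc_mean, cc_se, rng, size=())))
        cr = np.array(cr_list)
        dr = np.array(dr_list)
        cc = np.array(cc_list)
        factors = PieceFactors(cr=cr, dr=dr, cc=cc)
        tv = plot_volume(pieces, design, cr_values=cr) if pieces else 0.0
        tc = plot_carbon(pieces, design, tables, factors=factors) if pieces else 0.0
        truths.append(TruthRecord(plot_id, design, pieces, cr, dr, cc, tv, tc))
    return truths, designs


def _round_grid(x: float, grid: float) -> float:
    return round(x / grid) * grid


def _observe_species(
    true_code: str,
    spec: SpeciesErrorSpec,
    pool_groups: Mapping[str, str],
    rng: np.random.Generator,
) -> str:
    if true_code in SENTINEL_SPECIES:
        return true_code
    u = rng.random()
    if u < spec.p_correct:
        return true_code
    group = pool_groups[true_code]
    if u < spec.p_correct + spec.p_unknown_group:
        return UNKNOWN_HARDWOOD if group == "hardwood" else UNKNOWN_SOFTWOOD
    if u < spec.p_correct + spec.p_unknown_group + spec.p_wrong_species:
        others = [
            c for c, g in pool_groups.items()
            if g == group and c != true_code and c not in SENTINEL_SPECIES
        ]
        if others:
            return others[int(rng.integers(len(others)))]
        return UNKNOWN_HARDWOOD if group == "hardwood" else UNKNOWN_SOFTWOOD
    return UNKNOWN


def _observe_piece(
    piece: DCWDPiece,
    spec: CrewErrorSpec,
    config: SyntheticConfig,
    pool_groups: Mapping[str, str],
    rng: np.random.Generator,
) -> DCWDPiece:
    grid = config.rounding_grid_cm
    di = piece.diameter_cm
    if spec.diameter_sd_cm > 0:
        di += rng.normal(0.0, spec.diameter_sd_cm)
    di = max(_round_grid(di, grid), 3 * grid)  # crews do not tally below 3 in
    dh = 0.0
    if piece.is_hollow:
        dh = piece.hollow_diameter_cm
        if spec.hollow_sd_cm > 0:
            dh += rng.normal(0.0, spec.hollow_sd_cm)
        dh = min(max(_round_grid(dh, grid), grid), di)
    row = np.array(spec.decay_confusion[piece.decay_class - 1])
    decay = int(rng.choice(5, p=row)) + 1
    code = _observe_species(piece.species_code, spec.species, pool_groups, rng)
    return DCWDPiece(
        plot_id=piece.plot_id,
        subplot_id=piece.subplot_id,
        position_m=piece.position_m,
        diameter_cm=di,
        hollow_diameter_cm=dh,
        species_code=code,
        decay_class=decay,
    )


def simulate_crews(
    truths: Sequence[TruthRecord],
    config: SyntheticConfig,
    tables: Optional[ReferenceTables] = None,
) -> Tuple[
    Dict[str, List[DCWDPiece]],
    Dict[str, List[DCWDPiece]],
    List[PairedObservation],
]:
    """Simulate production and QA crews observing the same truth.

    Each crew independently applies its continuous errors (pre-rounding),
    rounds diameters to the recording grid, and mis-calls decay class and
    species per its confusion settings. Matching is perfect by construction;
    the paired table links the two records of every piece.
    """
    tables = tables if tables is not None else default_tables()
    rng = np.random.default_rng([config.seed, 1])
    pool_groups = {
        c: _group_of(c, tables) for c, _ in config.species_pool
    }
    production: Dict[str, List[DCWDPiece]] = {}
    qa: Dict[str, List[DCWDPiece]] = {}
    pairs: List[PairedObservation] = []
    for truth in truths:
        production[truth.plot_id] = []
        qa[truth.plot_id] = []
        for t, piece in enumerate(truth.pieces):
            prod = _observe_piece(piece, config.production, config, pool_groups, rng)
            qap = _observe_piece(piece, config.qa, config, pool_groups, rng)
            production[truth.plot_id].append(prod)
            qa[truth.plot_id].append(qap)
            pairs.append(
                PairedObservation(
                    plot_id=truth.plot_id,
                    pair_id=f"{truth.plot_id}-{t + 1}",
                    production_diameter_cm=prod.diameter_cm,
                    qa_diameter_cm=qap.diameter_cm,
                    production_decay_class=prod.decay_class,
                    qa_decay_class=qap.decay_class,
                    production_species=prod.species_code,
                    qa_species=qap.species_code,
                    production_hollow_cm=(
                        prod.hollow_diameter_cm if prod.is_hollow else None
                    ),
                    qa_hollow_cm=qap.hollow_diameter_cm if qap.is_hollow else None,
                )
            )
    return production, qa, pairs


def recovery_report(
    truths: Sequence[TruthRecord],
    mc_result: MCResult,
    configuration: str = "all_sources",
) -> pd.DataFrame:
    """Coverage and bias of the Monte Carlo intervals against truth.

    Per metric: the fraction of plots whose [p2.5, p97.5] interval covers
    the true value (a zero-width interval covers iff it equals truth), and
    the mean signed bias of the Monte Carlo median relative to truth.
    """
    truth_map = {
        t.plot_id: {"volume": t.true_volume_m3_ha, "carbon": t.true_carbon_MgC_ha}
        for t in truths
    }
    df = mc_result.summaries
    df = df[(df["configuration"] == configuration) & (df["plot_id"] != MEAN_PLOT_ID)]
    plot_ids = set(df["plot_id"])
    if plot_ids != set(truth_map):
        raise ValueError("truth records and Monte Carlo result cover different plots")
    rows = []
    for metric in ("volume", "carbon"):
        sub = df[df["metric"] == metric]
        covered = 0
        biases = []
        for _, row in sub.iterrows():
            tv = truth_map[row["plot_id"]][metric]
            if row["p2_5"] <= tv <= row["p97_5"]:
                covered += 1
            biases.append(row["median"] - tv)
        rows.append(
            {
                "metric": metric,
                "n_plots": len(sub),
                "coverage": covered / len(sub),
                "mean_bias": float(np.mean(biases)),
            }
        )
    return pd.DataFrame(rows, columns=["metric", "n_plots", "coverage", "mean_bias"])
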