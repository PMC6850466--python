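"""Deterministic plot-level estimator for downed coarse woody debris.

Per plot, the line-intersect (Van Wagner) estimator gives

    volume (m3/ha) = pi^2 / (8 L) * sum_t (DI_t^2 - DH_t^2) * CR_t
    carbon (Mg C/ha) = pi^2 / (8 L) * sum_t (DI_t^2 - DH_t^2) * CR_t
                       * BD_t * DR_t * CC_t

with intersect diameters ``DI`` and cavity diameters ``DH`` in cm, total
transect length ``L`` in m, collapse ratio ``CR`` (dimensionless), initial
bulk density ``BD`` in g/cm3 (== Mg/m3), density-reduction factor ``DR`` and
carbon fraction ``CC`` dimensionless. With these units the constant
``pi^2/8`` yields per-hectare values directly; no hidden scale factor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .pieces import (
    MIN_CLASS5_HEIGHT_CM,
    MIN_CLASS5_LENGTH_CM,
    MIN_TALLY_DIAMETER_CM,
    MIN_TALLY_LENGTH_CM,
    DCWDPiece,
    PlotDesign,
    PlotEstimate,
)
from .reference import (
    CollapseTable,
    ReferenceTables,
    carbon_concentration,
    nominal_collapse_ratio,
    resolve_density,
    resolve_entry,
)


def qualifies_as_dcwd(piece: DCWDPiece) -> bool:
    """Tally rule: does a piece count as downed coarse woody debris?

    Decay classes 1-4 require intersect diameter strictly greater than
    7.6 cm and (when length is recorded) length greater than 15 cm. Class-5
    pieces no longer hold a round cross-section; they qualify by extent
    instead: length over 152 cm with at least 13 cm exposed above the floor.
    Absent optional fields are treated as satisfied (the field crew already
    applied the rule when tallying).
    """
    if piece.decay_class == 5:
        if piece.length_cm is not None and not piece.length_cm > MIN_CLASS5_LENGTH_CM:
            return False
        if (
            piece.exposed_height_cm is not None
            and not piece.exposed_height_cm >= MIN_CLASS5_HEIGHT_CM
        ):
            return False
        return True
    if not piece.diameter_cm > MIN_TALLY_DIAMETER_CM:
        return False
    if piece.length_cm is not None and not piece.length_cm > MIN_TALLY_LENGTH_CM:
        return False
    return True


def piece_term(
    piece: DCWDPiece, collapse_ratio: float, use_hollow: bool = True
) -> float:
    """Squared-diameter contribution (cm^2) of one piece: (DI^2 - DH^2) CR."""
    dh2 = piece.hollow_diameter_cm**2 if use_hollow else 0.0
    return (piece.diameter_cm**2 - dh2) * collapse_ratio


@dataclass(frozen=True)
class PieceFactors:
    """Per-piece multiplier draws for one estimator evaluation."""

    cr: Sequence[float]
    dr: Sequence[float]
    cc: Sequence[float]


def _nominal_cr(piece: DCWDPiece, collapse: CollapseTable) -> float:
    return nominal_collapse_ratio(piece.decay_class, collapse)


def plot_volume(
    pieces: Iterable[DCWDPiece],
    design: PlotDesign,
    collapse: Optional[CollapseTable] = None,
    cr_values: Optional[Sequence[float]] = None,
    use_collapse: bool = True,
    use_hollow: bool = True,
) -> float:
    """Volume in m3/ha for one plot.

    Collapse ratios come from ``cr_values`` (aligned with the qualifying
    pieces) if given, else the class-mean of ``collapse``; with
    ``use_collapse=False`` CR is forced to 1 (the pre-collapse convention).
    Non-qualifying pieces are excluded, not errors.
    """
    kept = [p for p in pieces if qualifies_as_dcwd(p)]
    if not kept:
        return 0.0
    if use_collapse:
        if cr_values is not None:
            crs = list(cr_values)
            if len(crs) != len(kept):
                raise ValueError(
                    f"cr_values has {len(crs)} entries for {len(kept)} qualifying pieces"
                )
        elif collapse is not None:
            crs = [_nominal_cr(p, collapse) for p in kept]
        else:
            raise ValueError("use_collapse=True requires collapse table or cr_values")
    else:
        crs = [1.0] * len(kept)
    total = sum(piece_term(p, cr, use_hollow) for p, cr in zip(kept, crs))
    return math.pi**2 / (8.0 * design.total_length_m) * total


def plot_carbon(
    pieces: Iterable[DCWDPiece],
    design: PlotDesign,
    tables: ReferenceTables,
    factors: Optional[PieceFactors] = None,
    use_collapse: bool = True,
    use_hollow: bool = True,
) -> float:
    """Carbon storage in Mg C/ha for one plot.

    With ``factors=None`` every multiplier takes its nominal value:
    class-mean CR, mean DR for the resolved species x class, mean CC for the
    species group. Density resolution failures propagate.
    """
    kept = [p for p in pieces if qualifies_as_dcwd(p)]
    if not kept:
        return 0.0
    if factors is None:
        crs = (
            [_nominal_cr(p, tables.collapse) for p in kept]
            if use_collapse
            else [1.0] * len(kept)
        )
        drs, ccs, bds = [], [], []
        for p in kept:
            bd, dr_mean, _, _ = resolve_density(p.species_code, p.decay_class, tables)
            entry = resolve_entry(p.species_code, tables)
            cc_mean, _ = carbon_concentration(entry.group, tables.carbon)
            bds.append(bd)
            drs.append(dr_mean)
            ccs.append(cc_mean)
    else:
        crs = list(factors.cr) if use_collapse else [1.0] * len(kept)
        drs = list(factors.dr)
        ccs = list(factors.cc)
        bds = [
            resolve_entry(p.species_code, tables).initial_density_g_cm3 for p in kept
        ]
        if not (len(crs) == len(drs) == len(ccs) == len(kept)):
            raise ValueError("factor lengths must match qualifying piece count")
    total = sum(
        piece_term(p, cr, use_hollow) * bd * dr * cc
        for p, cr, bd, dr, cc in zip(kept, crs, bds, drs, ccs)
    )
    return math.pi**2 / (8.0 * design.total_length_m) * total


def estimate_plots(
    plots: Mapping[str, Sequence[DCWDPiece]],
    designs: Mapping[str, PlotDesign],
    tables: ReferenceTables,
    use_collapse: bool = True,
    use_hollow: bool = True,
) -> list[PlotEstimate]:
    """Deterministic volume/carbon estimates for a set of plots."""
    out = []
    for plot_id in sorted(plots):
        design = designs[plot_id]
        pieces = plots[plot_id]
        out.append(
            PlotEstimate(
                plot_id,
                plot_volume(
                    pieces, design, collapse=tables.collapse,
                    use_collapse=use_collapse, use_hollow=use_hollow,
                ),
                plot_carbon(
                    pieces, design, tables,
                    use_collapse=use_collapse, use_hollow=use_hollow,
                ),
            )
        )
    return out
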