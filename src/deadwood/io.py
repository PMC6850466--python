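"""CSV readers/writers for piece tables, paired-observation tables, and
Monte Carlo result summaries.

All files are UTF-8, comma-separated, '.' decimal. Diameters are stored in
cm and transect geometry in m throughout; recording precision (field crews
read diameters to the nearest inch) is a property of data collection, not
of these tables.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .pieces import DCWDPiece, PairedObservation, PlotDesign, ValidationError

PIECE_COLUMNS = [
    "plot_id",
    "subplot_id",
    "position_m",
    "diameter_cm",
    "hollow_diameter_cm",
    "species_code",
    "decay_class",
]
OPTIONAL_PIECE_COLUMNS = ["length_cm", "exposed_height_cm"]

RESULT_COLUMNS = [
    "plot_id",
    "configuration",
    "metric",
    "mean",
    "median",
    "p2_5",
    "p25",
    "p75",
    "p97_5",
    "iqr",
    "ci95_width",
]


class FormatError(ValueError):
    """The file does not have the expected columns/shape."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_pieces(
    path: str | Path,
    designs: Optional[Mapping[str, PlotDesign]] = None,
) -> Dict[str, List[DCWDPiece]]:
    """Read a piece inventory CSV, grouped by plot.

    Blank hollow diameters mean solid (0). When a design lookup is supplied,
    positions are checked against the plot's transect length. Invalid rows
    raise with their (1-based, data) row number.
    """
    df = pd.read_csv(path)
    _require_columns(df, PIECE_COLUMNS, path)
    out: Dict[str, List[DCWDPiece]] = {}
    for idx, row in df.iterrows():
        rownum = idx + 1
        plot_id = str(row["plot_id"])
        try:
            hollow = _opt_float(row["hollow_diameter_cm"])
            piece = DCWDPiece(
                plot_id=plot_id,
                subplot_id=int(row["subplot_id"]),
                position_m=float(row["position_m"]),
                diameter_cm=float(row["diameter_cm"]),
                hollow_diameter_cm=0.0 if hollow is None else hollow,
                species_code=str(row["species_code"]),
                decay_class=int(row["decay_class"]),
                length_cm=_opt_float(row.get("length_cm")),
                exposed_height_cm=_opt_float(row.get("exposed_height_cm")),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from exc
        if designs is not None and plot_id in designs:
            if piece.position_m > designs[plot_id].transect_length_m:
                raise ValidationError(
                    f"{path} row {rownum}: position {piece.position_m} m exceeds "
                    f"transect length {designs[plot_id].transect_length_m} m"
                )
        out.setdefault(plot_id, []).append(piece)
    return out


def write_pieces(plots: Mapping[str, Sequence[DCWDPiece]], path: str | Path) -> None:
    rows = []
    for plot_id in sorted(plots):
        for p in plots[plot_id]:
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "subplot_id": p.subplot_id,
                    "position_m": p.position_m,
                    "diameter_cm": p.diameter_cm,
                    "hollow_diameter_cm": p.hollow_diameter_cm,
                    "species_code": p.species_code,
                    "decay_class": p.decay_class,
                    "length_cm": p.length_cm,
                    "exposed_height_cm": p.exposed_height_cm,
                }
            )
    pd.DataFrame(rows, columns=PIECE_COLUMNS + OPTIONAL_PIECE_COLUMNS).to_csv(
        path, index=False
    )


PAIRED_COLUMNS = [
    "plot_id",
    "pair_id",
    "production_diameter_cm",
    "qa_diameter_cm",
    "production_decay_class",
    "qa_decay_class",
    "production_species",
    "qa_species",
]
OPTIONAL_PAIRED_COLUMNS = ["production_hollow_cm", "qa_hollow_cm"]


def read_paired(path: str | Path) -> List[PairedObservation]:
    """Read a paired production/QA remeasurement table."""
    df = pd.read_csv(path)
    _require_columns(df, PAIRED_COLUMNS, path)
    pairs: List[PairedObservation] = []
    for idx, row in df.iterrows():
        rownum = idx + 1
        try:
            pairs.append(
                PairedObservation(
                    plot_id=str(row["plot_id"]),
                    pair_id=str(row["pair_id"]),
                    production_diameter_cm=float(row["production_diameter_cm"]),
                    qa_diameter_cm=float(row["qa_diameter_cm"]),
                    production_decay_class=int(row["production_decay_class"]),
                    qa_decay_class=int(row["qa_decay_class"]),
                    production_species=str(row["production_species"]),
                    qa_species=str(row["qa_species"]),
                    production_hollow_cm=_opt_float(row.get("production_hollow_cm")),
                    qa_hollow_cm=_opt_float(row.get("qa_hollow_cm")),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}") from exc
    return pairs


def write_paired(pairs: Sequence[PairedObservation], path: str | Path) -> None:
    rows = [
        {
            "plot_id": p.plot_id,
            "pair_id": p.pair_id,
            "production_diameter_cm": p.production_diameter_cm,
            "qa_diameter_cm": p.qa_diameter_cm,
            "production_decay_class": p.production_decay_class,
            "qa_decay_class": p.qa_decay_class,
            "production_species": p.production_species,
            "qa_species": p.qa_species,
            "production_hollow_cm": p.production_hollow_cm,
            "qa_hollow_cm": p.qa_hollow_cm,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIRED_COLUMNS + OPTIONAL_PAIRED_COLUMNS).to_csv(
        path, index=False
    )


def pair_counts(pairs: Sequence[PairedObservation]) -> Dict[str, int]:
    """How many pairs contribute to each error model."""
    return {
        "diameter": len(pairs),
        "decay": len(pairs),
        "species": len(pairs),
        "hollow": sum(
            1
            for p in pairs
            if p.production_hollow_cm is not None and p.qa_hollow_cm is not None
        ),
    }


def write_results(result, path: str | Path) -> None:
    """Write Monte Carlo summaries, one row per (plot, configuration, metric).

    Rows are ordered by plot_id, then configuration, then metric, with fixed
    float formatting, so identical runs produce byte-identical files.
    """
    df = result.summaries.copy()
    df = df.sort_values(["plot_id", "configuration", "metric"]).reset_index(drop=True)
    df = df[RESULT_COLUMNS]
    df.to_csv(path, index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RESULT_COLUMNS, path)
    return df
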