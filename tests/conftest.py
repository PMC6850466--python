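"""Shared fixtures: reference tables, degenerate setups, tiny landscapes."""
from __future__ import annotations

import pytest

from deadwood import (
    CarbonTable,
    CollapseTable,
    DCWDPiece,
    DensityEntry,
    ErrorModelSet,
    PlotDesign,
    ReferenceTables,
    default_tables,
)
from deadwood.qa import ConfusionModel, ContinuousErrorModel


@pytest.fixture(scope="session")
def tables() -> ReferenceTables:
    return default_tables()


def make_degenerate_tables(species_code: str = "sp") -> ReferenceTables:
    """Tables with zero spread everywhere: singleton CR pools, zero SEs."""
    entry = DensityEntry(
        species_code, "Genus", "hardwood", 0.5,
        (1.0, 0.8, 0.6, 0.4, 0.3), (0.0, 0.0, 0.0, 0.0, 0.0),
    )
    return ReferenceTables(
        density={species_code: entry},
        collapse=CollapseTable(tuple((1.0,) for _ in range(5))),
        carbon=CarbonTable(
            {"hardwood": (0.49, 0.0), "softwood": (0.52, 0.0), "unknown": (0.51, 0.0)}
        ),
    )


@pytest.fixture
def degenerate_tables() -> ReferenceTables:
    return make_degenerate_tables()


def identity_error_models(
    species_codes=("sp",), diameter_diffs=(0.0,), hollow_diffs=(0.0,)
) -> ErrorModelSet:
    """Error models whose every perturbation returns the input unchanged
    (unless non-zero difference atoms are supplied)."""
    return ErrorModelSet(
        diameter=ContinuousErrorModel("diameter", tuple(diameter_diffs)),
        hollow_diameter=ContinuousErrorModel("hollow_diameter", tuple(hollow_diffs)),
        decay_class=ConfusionModel("decay_class", {c: (c,) for c in range(1, 6)}),
        species=ConfusionModel("species", {s: (s,) for s in species_codes}),
    )


def solid_piece(
    plot_id="A", diameter=10.0, decay=3, species="sp", position=1.0, **kw
) -> DCWDPiece:
    return DCWDPiece(
        plot_id=plot_id, subplot_id=1, position_m=position,
        diameter_cm=diameter, hollow_diameter_cm=kw.pop("hollow", 0.0),
        species_code=species, decay_class=decay, **kw,
    )


@pytest.fixture
def single_plot_setup(degenerate_tables):
    """One solid 10 cm piece on the standard 58.4 m design."""
    piece = solid_piece()
    design = PlotDesign("A")
    return {"A": [piece]}, {"A": design}, degenerate_tables
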