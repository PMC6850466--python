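"""Deterministic estimator: tally rule, per-piece terms, plot aggregation."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deadwood import (
    DCWDPiece,
    PlotDesign,
    piece_term,
    plot_carbon,
    plot_volume,
    qualifies_as_dcwd,
)
from deadwood.estimator import PieceFactors

from conftest import make_degenerate_tables, solid_piece


def van_wagner(diameters_cm, total_length_m):
    """Independent closed-form oracle: pi^2 sum(d^2) / (8 L)."""
    return math.pi**2 * sum(d * d for d in diameters_cm) / (8.0 * total_length_m)


class TestQualification:
    def test_diameter_threshold_is_strict(self):
        assert not qualifies_as_dcwd(solid_piece(diameter=7.6))
        assert qualifies_as_dcwd(solid_piece(diameter=7.61))

    def test_length_rule_classes_1_to_4(self):
        assert qualifies_as_dcwd(solid_piece(diameter=10.2, decay=2, length_cm=20.0))
        assert not qualifies_as_dcwd(solid_piece(diameter=10.2, decay=2, length_cm=10.0))
        # absent length treated as already screened in the field
        assert qualifies_as_dcwd(solid_piece(diameter=10.2, decay=2))

    def test_class5_extent_rule(self):
        ok = solid_piece(diameter=10.0, decay=5, length_cm=160.0,
                         exposed_height_cm=14.0)
        assert qualifies_as_dcwd(ok)
        assert not qualifies_as_dcwd(
            solid_piece(diameter=10.0, decay=5, length_cm=100.0,
                        exposed_height_cm=14.0)
        )
        assert not qualifies_as_dcwd(
            solid_piece(diameter=10.0, decay=5, length_cm=160.0,
                        exposed_height_cm=12.0)
        )
        # the exposed-height bound is inclusive ("at least 13 cm")
        assert qualifies_as_dcwd(
            solid_piece(diameter=10.0, decay=5, length_cm=160.0,
                        exposed_height_cm=13.0)
        )

    def test_class5_ignores_diameter_threshold(self):
        assert qualifies_as_dcwd(solid_piece(diameter=5.0, decay=5))


class TestPieceTerm:
    def test_solid_piece_full_circle(self):
        assert piece_term(solid_piece(diameter=10.0), 1.0) == pytest.approx(100.0)

    def test_fully_hollow_piece_contributes_nothing(self):
        p = solid_piece(diameter=10.0, hollow=10.0)
        assert piece_term(p, 1.0, use_hollow=True) == pytest.approx(0.0)

    def test_hollow_and_collapse_combine(self):
        p = solid_piece(diameter=10.0, hollow=6.0)
        assert piece_term(p, 0.5, use_hollow=True) == pytest.approx(32.0)

    def test_hollow_toggle_restores_gross_term(self):
        p = solid_piece(diameter=10.0, hollow=6.0)
        assert piece_term(p, 1.0, use_hollow=False) == pytest.approx(100.0)


class TestPlotVolume:
    def test_no_pieces_gives_zero(self):
        assert plot_volume([], PlotDesign("A"), use_collapse=False) == 0.0

    def test_single_piece_closed_form(self):
        v = plot_volume([solid_piece(diameter=10.0)], PlotDesign("A"),
                        use_collapse=False)
        assert v == pytest.approx(van_wagner([10.0], 58.4), rel=1e-14)
        assert v == pytest.approx(2.1125, abs=1e-6)

    def test_two_piece_additivity(self):
        pieces = [solid_piece(diameter=10.0), solid_piece(diameter=20.0)]
        v = plot_volume(pieces, PlotDesign("A"), use_collapse=False)
        assert v == pytest.approx(van_wagner([10.0, 20.0], 58.4), rel=1e-14)
        assert v == pytest.approx(10.5626, abs=1e-3)

    def test_nonqualifying_pieces_excluded_not_errored(self):
        pieces = [solid_piece(diameter=10.0), solid_piece(diameter=7.0)]
        v = plot_volume(pieces, PlotDesign("A"), use_collapse=False)
        assert v == pytest.approx(van_wagner([10.0], 58.4))

    def test_explicit_cr_values(self):
        v = plot_volume([solid_piece(diameter=10.0)], PlotDesign("A"),
                        cr_values=[0.5])
        assert v == pytest.approx(0.5 * van_wagner([10.0], 58.4))

    def test_cr_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plot_volume([solid_piece()], PlotDesign("A"), cr_values=[0.5, 0.6])


class TestPlotCarbon:
    def test_hand_product(self, degenerate_tables):
        # volume 2.1125 x BD 0.5 x DR 0.6 (class 3) x CC 0.49
        c = plot_carbon([solid_piece(diameter=10.0)], PlotDesign("A"),
                        degenerate_tables)
        expected = van_wagner([10.0], 58.4) * 0.5 * 0.6 * 0.49
        assert c == pytest.approx(expected, rel=1e-12)

    def test_explicit_factor_draws(self, degenerate_tables):
        factors = PieceFactors(cr=[1.0], dr=[0.8], cc=[0.49])
        c = plot_carbon([solid_piece(diameter=10.0)], PlotDesign("A"),
                        degenerate_tables, factors=factors)
        assert c == pytest.approx(van_wagner([10.0], 58.4) * 0.5 * 0.8 * 0.49)
        assert c == pytest.approx(0.41405, abs=1e-5)

    def test_zero_carbon_fraction_zeroes_result(self, degenerate_tables):
        factors = PieceFactors(cr=[1.0], dr=[0.8], cc=[0.0])
        assert plot_carbon([solid_piece()], PlotDesign("A"), degenerate_tables,
                           factors=factors) == 0.0

    def test_identity_factors_reduce_to_volume(self, degenerate_tables):
        # BD=1 requires a custom table; piggyback on factors with BD=0.5
        # by rescaling: carbon / (BD*DR*CC) == volume
        pieces = [solid_piece(diameter=14.0), solid_piece(diameter=24.0)]
        factors = PieceFactors(cr=[1.0, 1.0], dr=[1.0, 1.0], cc=[1.0, 1.0])
        c = plot_carbon(pieces, PlotDesign("A"), degenerate_tables, factors=factors)
        v = plot_volume(pieces, PlotDesign("A"), use_collapse=False)
        assert c == pytest.approx(v * 0.5, rel=1e-12)

    def test_empty_plot_zero_carbon(self, degenerate_tables):
        assert plot_carbon([], PlotDesign("A"), degenerate_tables) == 0.0


diameters = st.lists(
    st.floats(min_value=7.61, max_value=60.0, allow_nan=False), min_size=1,
    max_size=12,
)


class TestProperties:
    @given(ds=diameters)
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_on_random_plots(self, ds):
        pieces = [solid_piece(diameter=d) for d in ds]
        v = plot_volume(pieces, PlotDesign("A"), use_collapse=False)
        assert v == pytest.approx(van_wagner(ds, 58.4), rel=1e-12)

    @given(ds=diameters, bump=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_diameter(self, ds, bump):
        pieces = [solid_piece(diameter=d) for d in ds]
        bigger = [solid_piece(diameter=ds[0] + bump)] + pieces[1:]
        v0 = plot_volume(pieces, PlotDesign("A"), use_collapse=False)
        v1 = plot_volume(bigger, PlotDesign("A"), use_collapse=False)
        assert v1 >= v0

    @given(ds=diameters)
    @settings(max_examples=40, deadline=None)
    def test_doubling_length_halves_estimate(self, ds):
        pieces = [solid_piece(diameter=d) for d in ds]
        v1 = plot_volume(pieces, PlotDesign("A"), use_collapse=False)
        v2 = plot_volume(pieces, PlotDesign("A", n_transects=8), use_collapse=False)
        assert v2 == pytest.approx(v1 / 2.0, rel=1e-12)

    @given(ds=diameters, frac=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=40, deadline=None)
    def test_hollowness_and_collapse_never_increase(self, ds, frac):
        tables = make_degenerate_tables()
        hollow = [solid_piece(diameter=d, hollow=frac * d) for d in ds]
        v_with = plot_volume(hollow, PlotDesign("A"), use_collapse=False,
                             use_hollow=True)
        v_without = plot_volume(hollow, PlotDesign("A"), use_collapse=False,
                                use_hollow=False)
        assert v_with <= v_without + 1e-12
        cr = [0.7] * len(ds)
        v_cr = plot_volume(hollow, PlotDesign("A"), cr_values=cr)
        assert v_cr <= v_with * 0.7 + 1e-9
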