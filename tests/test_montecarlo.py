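"""Propagation engine: summaries, degenerate identities, attribution."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from deadwood import (
    MEAN_PLOT_ID,
    PlotDesign,
    SOURCES,
    SourceConfig,
    attribute_sources,
    ci95,
    quadrature_combine,
    run_mc,
)

from conftest import identity_error_models, make_degenerate_tables, solid_piece


class TestCi95:
    def test_constant_list_zero_width(self):
        assert ci95([3.0] * 50) == 0.0

    def test_interpolated_quantiles_by_hand(self):
        assert ci95(list(range(101))) == pytest.approx(95.0)

    def test_standard_normal_width(self):
        rng = np.random.default_rng(12345)
        draws = rng.standard_normal(100_000)
        assert ci95(draws) == pytest.approx(2 * 1.959964, abs=0.05)

    def test_too_few_iterates_error(self):
        with pytest.raises(ValueError):
            ci95([1.0])


class TestQuadrature:
    def test_three_four_five(self):
        assert quadrature_combine([3.0, 4.0]) == pytest.approx(5.0)

    def test_single_source_passthrough(self):
        assert quadrature_combine([7.0]) == 7.0

    def test_all_zero(self):
        assert quadrature_combine([0.0, 0.0, 0.0]) == 0.0

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            quadrature_combine([3.0, -1.0])


@pytest.fixture
def degenerate_setup(single_plot_setup):
    plots, designs, tables = single_plot_setup
    return plots, designs, tables, identity_error_models()


class TestDegenerateIdentities:
    def test_all_sources_off_equals_baseline(self, degenerate_setup):
        plots, designs, tables, models = degenerate_setup
        cfg = SourceConfig.all_off(n_iterations=100, seed=1)
        res = run_mc(plots, designs, tables, models, cfg)
        for metric in ("volume", "carbon"):
            row = res.summary_row("A", "none", metric)
            assert row["ci95_width"] == 0.0
            base = res.baseline_value("A", metric)
            assert np.all(res.get_iterates("A", "none", metric) == base)

    def test_degenerate_models_give_exact_baseline(self, degenerate_setup):
        """With identity error models, singleton CR pools and zero SEs, every
        all-sources iterate must equal the deterministic baseline bitwise."""
        plots, designs, tables, models = degenerate_setup
        cfg = SourceConfig(n_iterations=500, seed=2)
        res = run_mc(plots, designs, tables, models, cfg)
        for metric in ("volume", "carbon"):
            base = res.baseline_value("A", metric)
            iters = res.get_iterates("A", "all_sources", metric)
            assert np.all(iters == base)
            assert res.summary_row("A", "all_sources", metric)["ci95_width"] == 0.0


class TestAtomEnumeration:
    def test_three_atom_diameter_error(self, degenerate_tables):
        plots = {"A": [solid_piece(diameter=15.24)]}
        designs = {"A": PlotDesign("A")}
        models = identity_error_models(diameter_diffs=(-2.54, 0.0, 2.54))
        cfg = SourceConfig.single("diameter", n_iterations=3000, seed=4)
        res = run_mc(plots, designs, degenerate_tables, models, cfg)
        iters = res.get_iterates("A", "diameter", "volume")
        atoms = sorted({round(v, 12) for v in iters})
        expected = sorted(
            math.pi**2 * d * d / (8 * 58.4) for d in (12.70, 15.24, 17.78)
        )
        assert atoms == pytest.approx(expected)
        n = len(iters)
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        for atom in expected:
            freq = np.mean(np.isclose(iters, atom))
            assert abs(freq - 1 / 3) <= 3 * se


class TestReproducibility:
    def test_identical_inputs_identical_result(self, degenerate_setup):
        plots, designs, tables, _ = degenerate_setup
        models = identity_error_models(diameter_diffs=(-2.54, 0.0, 2.54))
        cfg = SourceConfig(n_iterations=200, seed=11)
        r1 = run_mc(plots, designs, tables, models, cfg)
        r2 = run_mc(plots, designs, tables, models, cfg)
        pd.testing.assert_frame_equal(r1.summaries, r2.summaries)
        for key in r1.iterates:
            assert np.array_equal(r1.iterates[key], r2.iterates[key])

    def test_different_seed_different_draws(self, degenerate_setup):
        plots, designs, tables, _ = degenerate_setup
        models = identity_error_models(diameter_diffs=(-2.54, 0.0, 2.54))
        r1 = run_mc(plots, designs, tables, models,
                    SourceConfig(n_iterations=100, seed=1))
        r2 = run_mc(plots, designs, tables, models,
                    SourceConfig(n_iterations=100, seed=2))
        assert not np.array_equal(
            r1.get_iterates("A", "all_sources", "volume"),
            r2.get_iterates("A", "all_sources", "volume"),
        )


class TestSummaries:
    def test_percentile_ordering_invariant(self, degenerate_setup):
        plots, designs, tables, _ = degenerate_setup
        models = identity_error_models(diameter_diffs=(-5.0, -2.54, 0.0, 2.54, 5.0))
        cfg = SourceConfig(n_iterations=400, seed=3)
        res = run_mc(plots, designs, tables, models, cfg)
        for _, row in res.summaries.iterrows():
            assert (row["p2_5"] <= row["p25"] <= row["median"]
                    <= row["p75"] <= row["p97_5"])
            assert row["ci95_width"] >= 0.0

    def test_mean_plot_is_cross_plot_mean(self, degenerate_tables):
        plots = {
            "A": [solid_piece(plot_id="A", diameter=10.0)],
            "B": [solid_piece(plot_id="B", diameter=20.0)],
        }
        designs = {p: PlotDesign(p) for p in plots}
        models = identity_error_models(diameter_diffs=(-2.54, 0.0, 2.54))
        cfg = SourceConfig(n_iterations=100, seed=5)
        res = run_mc(plots, designs, degenerate_tables, models, cfg)
        mean_iter = res.get_iterates(MEAN_PLOT_ID, "all_sources", "volume")
        manual = 0.5 * (res.get_iterates("A", "all_sources", "volume")
                        + res.get_iterates("B", "all_sources", "volume"))
        assert np.array_equal(mean_iter, manual)

    def test_clamped_diameters_never_negative_terms(self, degenerate_tables):
        plots = {"A": [solid_piece(diameter=8.0)]}
        designs = {"A": PlotDesign("A")}
        models = identity_error_models(diameter_diffs=(-20.0, 0.0))
        cfg = SourceConfig.single("diameter", n_iterations=500, seed=6)
        res = run_mc(plots, designs, degenerate_tables, models, cfg)
        assert np.all(res.get_iterates("A", "diameter", "volume") >= 0.0)

    def test_drop_rule_removes_subthreshold_pieces(self, degenerate_tables):
        plots = {"A": [solid_piece(diameter=8.0)]}
        designs = {"A": PlotDesign("A")}
        models = identity_error_models(diameter_diffs=(-20.0,))
        cfg = SourceConfig.single("diameter", n_iterations=50, seed=6,
                                  subthreshold_rule="drop")
        res = run_mc(plots, designs, degenerate_tables, models, cfg)
        assert np.all(res.get_iterates("A", "diameter", "volume") == 0.0)


class TestAttribution:
    def test_table_shape_and_degenerate_sources(self, degenerate_setup):
        plots, designs, tables, _ = degenerate_setup
        models = identity_error_models(diameter_diffs=(-2.54, 0.0, 2.54))
        cfg = SourceConfig(n_iterations=300, seed=7)
        merged, att = attribute_sources(
            plots, designs, tables, models, cfg,
            sources=("diameter", "decay_class"),
        )
        # per metric: 2 sources + all_sources + quadrature
        assert len(att) == 2 * 4
        decay_rows = att[(att["source"] == "decay_class")]
        assert (decay_rows["ci95"] == 0.0).all()  # identity confusion
        for metric in ("volume", "carbon"):
            sub = att[att["metric"] == metric].set_index("source")["ci95"]
            assert sub["quadrature"] == pytest.approx(
                math.hypot(sub["diameter"], sub["decay_class"])
            )

    def test_single_source_never_exceeds_all_sources_much(self, degenerate_setup):
        plots, designs, tables, _ = degenerate_setup
        models = identity_error_models(diameter_diffs=(-2.54, 0.0, 2.54))
        cfg = SourceConfig(n_iterations=2000, seed=8)
        merged, att = attribute_sources(plots, designs, tables, models, cfg)
        for metric in ("volume", "carbon"):
            sub = att[att["metric"] == metric].set_index("source")["ci95"]
            all_w = sub["all_sources"]
            for s in SOURCES:
                assert sub[s] <= all_w * 1.10 + 1e-9
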