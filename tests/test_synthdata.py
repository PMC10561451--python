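"""Generator contracts: determinism, dose law, expression heterogeneity."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

import fociscreen as fs
from fociscreen.synthdata import PlacementError, build_screen_layout


class TestFociDoseModel:
    def test_mean_matches_formula(self):
        m = fs.FociDoseModel(lambda0=0.5, lambda_max=12.0, ec50_dose=0.3)
        delta = (12.0 - 0.5) * 0.5 / (0.5 + 0.3)
        assert m.mean_foci(0.5) == pytest.approx(0.5 + delta)
        assert m.mean_foci(0.5, effect=1.0) == pytest.approx(0.5)
        assert m.mean_foci(0.0) == pytest.approx(0.5)

    def test_dose_monotone_and_effect_antitone(self):
        m = fs.FociDoseModel()
        doses = [0.0, 0.05, 0.5, 5.0]
        means = [m.mean_foci(d) for d in doses]
        assert all(a <= b for a, b in zip(means, means[1:]))
        effects = [0.0, 0.3, 0.8, 1.0]
        rescued = [m.mean_foci(0.5, effect=e) for e in effects]
        assert all(a >= b for a, b in zip(rescued, rescued[1:]))

    def test_duration_factor_applies_to_long_treatments(self):
        m = fs.FociDoseModel(duration_factor=1.4)
        short = m.mean_foci(0.5, duration_h=1.0)
        long = m.mean_foci(0.5, duration_h=24.0)
        assert long > short

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            fs.FociDoseModel(lambda0=5.0, lambda_max=1.0)
        with pytest.raises(ValueError):
            fs.FociDoseModel().mean_foci(0.5, effect=1.5)


class TestGenerateField:
    def test_empty_field_is_background_only(self, small_config):
        img, truth = fs.generate_field(
            small_config, fs.Treatment(), seed=0, n_cells=0
        )
        assert truth.cells == []
        # nothing but background + noise: no pixel near a nucleus intensity
        assert img.nuclear.max() < small_config.background_level * 3

    def test_fixed_seed_bit_identical(self, small_config):
        a_img, a_truth = fs.generate_field(small_config, fs.Treatment(dose_uM=0.5), seed=7)
        b_img, b_truth = fs.generate_field(small_config, fs.Treatment(dose_uM=0.5), seed=7)
        np.testing.assert_array_equal(a_img.nuclear, b_img.nuclear)
        np.testing.assert_array_equal(a_img.green, b_img.green)
        assert a_truth.to_frame().equals(b_truth.to_frame())

    def test_mean_true_foci_within_3se_of_law(self):
        # 200 planted cells at dose 0.5: sample mean vs the Poisson mean
        cfg = fs.SimConfig(image_size=(2048, 2048), cells_per_field=200)
        model = fs.FociDoseModel()
        img, truth = fs.generate_field(
            cfg, fs.Treatment(dose_uM=0.5), seed=5, model=model, n_cells=200
        )
        counts = np.array([c.foci_count for c in truth.cells])
        mu = model.mean_foci(0.5)
        se = np.sqrt(mu / len(counts))
        assert abs(counts.mean() - mu) <= 3 * se

    def test_nonsignaling_cells_render_no_green(self, small_config):
        cfg = dataclasses.replace(
            small_config, p_nonsignal=1.0, photon_noise=False, read_noise_sd=0.0
        )
        img, truth = fs.generate_field(cfg, fs.Treatment(dose_uM=5.0), seed=3, n_cells=5)
        assert all(c.expression_gain == 0.0 for c in truth.cells)
        assert any(c.foci_count > 0 for c in truth.cells)  # bookkeeping kept
        assert img.green.max() == pytest.approx(cfg.background_level, abs=1)

    def test_nonsignal_fraction_in_binomial_interval(self):
        cfg = fs.SimConfig(image_size=(2048, 2048), cells_per_field=400, p_nonsignal=0.1)
        _, truth = fs.generate_field(cfg, fs.Treatment(), seed=9, n_cells=400)
        n_zero = sum(c.expression_gain == 0 for c in truth.cells)
        lo, hi = binom.interval(0.99, 400, 0.1)
        assert lo <= n_zero <= hi

    def test_overcrowded_field_raises_naming_density(self, small_config):
        cfg = dataclasses.replace(small_config, cells_per_field=2000.0)
        with pytest.raises(PlacementError, match="cells_per_field"):
            fs.generate_field(cfg, fs.Treatment(), seed=1, n_cells=500)


class TestGenerateWell:
    def test_singleton_and_determinism(self, small_config):
        one = fs.generate_well(small_config, fs.Treatment(), n_fields=1, seed=4)
        assert len(one) == 1
        again = fs.generate_well(small_config, fs.Treatment(), n_fields=1, seed=4)
        np.testing.assert_array_equal(one[0][0].green, again[0][0].green)

    def test_fields_are_distinct(self, small_config):
        fields = fs.generate_well(small_config, fs.Treatment(dose_uM=0.5), n_fields=4, seed=4)
        assert len(fields) == 4
        assert len({f.field for f, _ in fields}) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.array_equal(fields[i][0].green, fields[j][0].green)

    def test_zero_fields_rejected(self, small_config):
        with pytest.raises(ValueError):
            fs.generate_well(small_config, fs.Treatment(), n_fields=0, seed=1)


class TestSimulateScreen:
    def test_layout_roles_and_effects(self):
        design = fs.ScreenDesign(
            n_compounds=10, n_replicates=2, wells_per_plate=12,
            controls_per_plate=2, dox_per_plate=2, true_effects={"C05": 0.7},
        )
        layout = build_screen_layout(design)
        for plate, grp in layout.groupby("plate"):
            assert (grp["role"] == "control").sum() >= 1
            assert (grp["role"] == "dox").sum() >= 1
        comp = layout[layout.role == "compound"]
        assert set(comp.compound_id) == set(design.compound_ids)
        assert comp.loc[comp.compound_id == "C05", "effect_e"].eq(0.7).all()

    def test_unknown_compound_in_effects_rejected(self):
        with pytest.raises(ValueError, match="unknown compound"):
            build_screen_layout(
                fs.ScreenDesign(n_compounds=5, true_effects={"NOPE": 0.5})
            )

    def test_fast_mode_effect_contrasts(self, small_config):
        # e=0: compound wells match DOX wells; e=1: match control wells
        design = fs.ScreenDesign(
            n_compounds=3, n_replicates=1, wells_per_plate=20,
            controls_per_plate=4, dox_per_plate=4, cells_per_well=400,
            true_effects={"C3": 1.0},
        )
        layout, cells, effects, prov = fs.simulate_screen(
            design, small_config, fs.FociDoseModel(), seed=11, mode="fast"
        )
        assert prov["mode"] == "fast"
        by = cells.groupby("role")["foci_count"].mean()
        inert = cells[(cells.role == "compound") & (cells.compound_id != "C3")]
        rescued = cells[cells.compound_id == "C3"]
        mu_dox = by["dox"]
        se = np.sqrt(mu_dox / len(inert))
        assert abs(inert["foci_count"].mean() - mu_dox) < 4 * se
        mu_ctrl = by["control"]
        se_c = np.sqrt(max(mu_ctrl, 0.1) / len(rescued))
        assert abs(rescued["foci_count"].mean() - mu_ctrl) < 4 * se_c

    def test_fast_mode_deterministic(self, small_config):
        design = fs.ScreenDesign(n_compounds=4, n_replicates=1, wells_per_plate=8,
                                 controls_per_plate=2, dox_per_plate=2)
        a = fs.simulate_screen(design, small_config, fs.FociDoseModel(), seed=2, mode="fast")
        b = fs.simulate_screen(design, small_config, fs.FociDoseModel(), seed=2, mode="fast")
        assert a[1].equals(b[1])
        assert a[2].equals(b[2])
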