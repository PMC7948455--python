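"""Synthetic plate generator: determinism, decay statistics, effect model,
titration and dose-series behavior."""

import numpy as np
import pandas as pd
import pytest

from fltscreen.decay import fit_plate
from fltscreen.layout import make_uniform_layout
from fltscreen.simulate import (
    CompoundEffect,
    TitrationModel,
    effective_fret,
    half_log_concentrations,
    hill_fraction,
    simulate_decay,
    simulate_dose_series,
    simulate_plate,
    simulate_titration,
    time_ramp,
)


class TestSimulateDecay:
    def test_seed_determinism(self, sim_config):
        a = simulate_decay(2.6, 1e5, sim_config, seed=5)
        b = simulate_decay(2.6, 1e5, sim_config, seed=5)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_decay(2.6, 1e5, sim_config, seed=6)
        assert not np.array_equal(a.counts, c.counts)

    def test_noiseless_tail_log_slope_matches_lifetime(self, sim_config):
        wf = simulate_decay(2.6, 1e5, sim_config, noiseless=True)
        sel = (wf.times > 10.0) & (wf.times < 20.0)
        slope, _ = np.polyfit(wf.times[sel], np.log(wf.counts[sel]), 1)
        assert slope == pytest.approx(-1.0 / 2.6, abs=1e-6)

    def test_total_counts_within_poisson_error(self, sim_config):
        wf = simulate_decay(2.6, 1e5, sim_config, seed=7)
        assert abs(wf.total_counts - 1e5) < 4 * np.sqrt(1e5)

    @pytest.mark.parametrize("lifetime,counts", [(-1.0, 1e5), (0.0, 1e5), (2.6, 0.0)])
    def test_nonpositive_inputs_rejected(self, sim_config, lifetime, counts):
        with pytest.raises(ValueError):
            simulate_decay(lifetime, counts, sim_config)


class TestEffectModel:
    def test_inert_requires_zero_magnitudes(self):
        with pytest.raises(ValueError, match="inert"):
            CompoundEffect(effect_class="inert", viability_loss=0.5)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="effect class"):
            CompoundEffect(effect_class="mystery")

    def test_hill_fraction_midpoint_and_limits(self):
        assert hill_fraction(1.0, 1.0, 1.0) == pytest.approx(0.5)
        assert hill_fraction(0.0, 1.0, 1.0) == 0.0
        assert hill_fraction(1e6, 1.0, 1.0) == pytest.approx(1.0, abs=1e-5)

    def test_time_ramp_saturates(self):
        assert time_ramp(120.0, 0.0) == 1.0
        assert time_ramp(300.0, 60.0) == pytest.approx(1 - np.exp(-5))

    def test_full_viability_loss_abolishes_both_fret_components(self):
        eff = CompoundEffect(effect_class="cytotoxic", viability_loss=1.0)
        e_s, e_n = effective_fret(eff, 10.0, 120.0, 0.064, 0.059)
        assert e_s == pytest.approx(0.0, abs=1e-12)
        assert e_n == pytest.approx(0.0, abs=1e-12)

    def test_saturating_modulator_removes_specific_fret_only(self):
        eff = CompoundEffect(effect_class="modulator", max_fret_change=1.0, ec50=0.1)
        e_s, e_n = effective_fret(eff, 100 * 0.1, 120.0, 0.064, 0.059)
        assert e_s == pytest.approx(0.064 / 101, rel=1e-6)  # Hill(100x ec50) = 100/101
        assert e_n == 0.059


@pytest.fixture(scope="module")
def layout():
    return make_uniform_layout(96, dmso_columns=(1, 2, 3))


class TestSimulatePlate:
    def test_byte_identical_on_same_seed(self, layout, sim_config):
        effects = {cid: CompoundEffect() for cid in layout.compound_ids()}
        a = simulate_plate(layout, effects, sim_config, seed=9)
        b = simulate_plate(layout, effects, sim_config, seed=9)
        assert np.array_equal(a.waveforms.counts, b.waveforms.counts)
        pd.testing.assert_frame_equal(a.spectra, b.spectra)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_missing_effect_entry_names_compounds(self, layout, sim_config):
        with pytest.raises(ValueError, match="C0001"):
            simulate_plate(layout, {}, sim_config)

    def test_all_inert_plate_compound_mean_matches_dmso(self, layout, sim_config, irf):
        effects = {cid: CompoundEffect() for cid in layout.compound_ids()}
        sim = simulate_plate(layout, effects, sim_config, seed=11)
        fits = fit_plate(sim.waveforms, irf).set_index("well")
        dmso = fits.loc[[w.label for w in layout.dmso_wells], "tau_ns"]
        cpd = fits.loc[[w.label for w in layout.compound_wells], "tau_ns"]
        sem = np.sqrt(dmso.var() / len(dmso) + cpd.var() / len(cpd))
        assert abs(cpd.mean() - dmso.mean()) < 3 * sem

    def test_cytotoxic_well_truth_fret_near_zero(self, layout, sim_config):
        effects = {cid: CompoundEffect() for cid in layout.compound_ids()}
        effects["C0001"] = CompoundEffect(effect_class="cytotoxic", viability_loss=1.0)
        sim = simulate_plate(layout, effects, sim_config, seed=12)
        row = sim.truth.set_index("compound_id").loc["C0001"]
        assert row["E_specific"] == pytest.approx(0.0, abs=1e-12)
        assert row["E_nonspecific"] == pytest.approx(0.0, abs=1e-12)
        assert np.all(sim.waveforms.counts >= 0)

    def test_saturated_modulator_truth_equals_nonspecific_baseline(
        self, layout, sim_config
    ):
        effects = {cid: CompoundEffect() for cid in layout.compound_ids()}
        effects["C0002"] = CompoundEffect(
            effect_class="modulator",
            max_fret_change=1.0,
            ec50=0.1,
            effect_time_constant=10.0,
        )
        sim = simulate_plate(layout, effects, sim_config, timepoint_min=120.0, seed=13)
        row = sim.truth.set_index("compound_id").loc["C0002"]
        # 100x EC50 and 12 time constants: specific FRET is gone
        assert row["E_total"] == pytest.approx(
            sim_config.baseline_nonspecific_fret, abs=1e-3
        )

    def test_interferer_shifts_donor_lifetime_and_spectrum(self, layout, sim_config):
        effects = {cid: CompoundEffect() for cid in layout.compound_ids()}
        effects["C0003"] = CompoundEffect(
            effect_class="interferer",
            donor_lifetime_shift=0.2,
            spectral_contaminant_fraction=0.4,
        )
        sim = simulate_plate(layout, effects, sim_config, assay="donor_only", seed=14)
        truth = sim.truth.set_index("compound_id")
        assert truth.loc["C0003", "tau_donor_ns"] == pytest.approx(2.8)
        well = truth.loc["C0003", "well"]
        spec = sim.spectra.set_index(["well", "band"])["intensity"]
        clean_contam = sim.spectra.query(
            "band == 'contaminant_560' and well != @well"
        )["intensity"].mean()
        assert spec[(well, "contaminant_560")] > 3 * clean_contam

    def test_unknown_assay_rejected(self, layout, sim_config):
        effects = {cid: CompoundEffect() for cid in layout.compound_ids()}
        with pytest.raises(ValueError, match="assay"):
            simulate_plate(layout, effects, sim_config, assay="tertiary")


class TestTitration:
    def test_zero_level_gives_zero_fret(self):
        df = simulate_titration([0.0], TitrationModel(nonspecific_slope=0.01))
        assert df["total_fret"].iloc[0] == 0.0

    def test_plateau_at_e_max(self):
        df = simulate_titration([1e3], TitrationModel(e_max=0.12, rate=1.0))
        assert df["total_fret"].iloc[0] == pytest.approx(0.12)

    def test_nonspecific_component_is_linear(self):
        m = TitrationModel(e_max=0.12, rate=2.0, nonspecific_slope=0.01)
        df = simulate_titration([1.0, 2.0], m)
        assert df["nonspecific_fret"].iloc[1] == 2 * df["nonspecific_fret"].iloc[0]

    def test_total_monotone_and_specific_bounded(self):
        m = TitrationModel(e_max=0.12, rate=0.7, nonspecific_slope=0.005)
        df = simulate_titration(np.linspace(0, 50, 200), m)
        assert (df["total_fret"].diff().dropna() >= -1e-12).all()
        assert (df["specific_fret"] <= 0.12 + 1e-12).all()

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration([-1.0], TitrationModel())


class TestDoseSeries:
    def test_midpoint_reduction_at_ec50(self, sim_config):
        eff = CompoundEffect(effect_class="modulator", max_fret_change=0.8, ec50=0.5)
        df = simulate_dose_series(eff, [0.005, 0.05, 0.5, 5.0, 50.0], 1, sim_config)
        at_ec50 = df.loc[df["concentration_uM"] == 0.5, "fret"].iloc[0]
        expected = sim_config.specific_fret * (1 - 0.4) + sim_config.baseline_nonspecific_fret
        assert at_ec50 == pytest.approx(expected)

    def test_zero_noise_replicates_identical(self, sim_config):
        eff = CompoundEffect(effect_class="modulator", max_fret_change=1.0, ec50=0.3)
        df = simulate_dose_series(eff, half_log_concentrations(), 3, sim_config)
        assert (df.groupby("concentration_uM")["fret"].nunique() == 1).all()

    def test_too_few_concentrations_rejected(self, sim_config):
        with pytest.raises(ValueError, match="4"):
            simulate_dose_series(CompoundEffect(), [0.1, 1.0, 10.0], 1, sim_config)

    def test_half_log_grid_spans_screening_range(self):
        grid = half_log_concentrations()
        assert grid.size == 12
        assert grid[0] == pytest.approx(0.01)
        assert grid[-1] == pytest.approx(30.0)
        steps = np.diff(np.log10(grid))
        assert np.allclose(steps, steps[0])
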