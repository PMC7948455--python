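"""Screening decision layer: interference flagging, hit calling, hit
reproducibility, Z'-factor and counter-screen triage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fltscreen.config import ScreenConfig
from fltscreen.layout import make_lopac_layout, make_uniform_layout
from fltscreen.screen import (
    call_hits,
    call_hits_from_table,
    flag_interference,
    hit_reproducibility,
    mean_sem,
    screen_timecourse,
    spectral_deviation_scores,
    triage_with_counter,
    z_prime,
)
from fltscreen.simulate import simulate_fitted_tau_plate

TAU0, SIGMA = 2.28, 0.008


def _donor_fits(layout, rng, shifts=None):
    """Gaussian donor-only fit table on a layout, with planted tau shifts."""
    df = layout.to_frame()[["well", "compound_id"]]
    tau = TAU0 + SIGMA * rng.standard_normal(len(df))
    if shifts:
        by_id = dict(zip(df["compound_id"], df.index))
        for cid, shift in shifts.items():
            tau[by_id[cid]] += shift
    return pd.DataFrame({"well": df["well"], "tau_ns": tau, "converged": True})


class TestInterference:
    @pytest.fixture()
    def layout(self):
        return make_uniform_layout(96, dmso_columns=(1, 2, 3))

    def test_large_donor_shift_flagged(self, layout, rng):
        fits = _donor_fits(layout, rng, shifts={"C0005": 10 * SIGMA})
        flags = flag_interference(fits, None, layout).set_index("compound_id")
        assert flags.loc["C0005", "lifetime_flag"]
        assert flags.loc["C0005", "flagged"]

    def test_compound_identical_to_dmso_not_flagged(self, layout):
        fits = pd.DataFrame(
            {
                "well": [w.label for w in layout.wells],
                "tau_ns": TAU0,
                "converged": True,
            }
        )
        # give controls a touch of scatter so the SD is defined
        fits.loc[:3, "tau_ns"] += [0.001, -0.001, 0.0005, -0.0005]
        flags = flag_interference(fits, None, layout)
        assert not flags["flagged"].any()

    def test_missing_donor_data_is_an_error(self, layout):
        with pytest.raises(ValueError, match="mandatory"):
            flag_interference(pd.DataFrame(), None, layout)

    def test_contaminated_spectrum_flagged(self, layout, rng):
        fits = _donor_fits(layout, rng)
        rows = []
        for w in layout.wells:
            base = np.array([1.0, 0.05, 0.08])
            if w.compound_id == "C0007":
                base = 0.6 * base + 0.4 * np.array([0.3, 0.5, 0.2])
            noisy = base * (1 + 0.02 * rng.standard_normal(3))
            for band, inten in zip(["donor_510", "contaminant_560", "acceptor_600"], noisy):
                rows.append({"well": w.label, "band": band, "intensity": inten})
        flags = flag_interference(fits, pd.DataFrame(rows), layout).set_index("compound_id")
        assert flags.loc["C0007", "spectral_flag"]
        assert flags.drop("C0007")["spectral_flag"].sum() == 0

    def test_null_lifetime_flag_rate_matches_monte_carlo_oracle(self):
        """On all-inert plates the lifetime-flag fraction matches a
        brute-force simulation of the same mean+3SD rule."""
        layout = make_lopac_layout()
        rng = np.random.default_rng(77)
        n_plates, n_cpd, n_dmso = 8, 1280, 256
        flagged = 0
        for _ in range(n_plates):
            fits = _donor_fits(layout, rng)
            flags = flag_interference(fits, None, layout)
            flagged += int(flags["flagged"].sum())
        obs_rate = flagged / (n_plates * n_cpd)

        # vectorized oracle: same rule, fresh draws
        oracle_rng = np.random.default_rng(78)
        reps = 400
        dmso = oracle_rng.standard_normal((reps, n_dmso))
        cpd = oracle_rng.standard_normal((reps, n_cpd))
        mu = dmso.mean(axis=1, keepdims=True)
        sd = dmso.std(axis=1, ddof=1, keepdims=True)
        oracle_rate = float(np.mean(np.abs(cpd - mu) > 3 * sd))
        n = n_plates * n_cpd
        se = np.sqrt(oracle_rate * (1 - oracle_rate) * (1 / n + 1 / (reps * n_cpd)))
        assert abs(obs_rate - oracle_rate) < 4 * se

    def test_spectral_scores_zero_for_matching_shape(self):
        spectra = pd.DataFrame(
            {
                "well": ["A01", "A01", "A02", "A02"],
                "band": ["b1", "b2", "b1", "b2"],
                "intensity": [1.0, 0.5, 2.0, 1.0],  # same shape, double brightness
            }
        )
        scores = spectral_deviation_scores(spectra, {"A01"})
        assert scores["A02"] == scores["A01"]  # brightness-invariant


class TestCallHits:
    @pytest.fixture()
    def layout(self):
        return make_uniform_layout(96, dmso_columns=(1, 2))

    def _fits(self, layout, rng, shifts=None):
        return _donor_fits(layout, rng, shifts)

    def test_all_identical_wells_give_zero_hits(self, layout):
        fits = pd.DataFrame(
            {"well": [w.label for w in layout.wells], "tau_ns": TAU0, "converged": True}
        )
        res = call_hits(fits, layout)
        assert res.n_hits == 0

    def test_planted_ten_sigma_shift_is_hit_with_direction(self, layout, rng):
        fits = self._fits(layout, rng, shifts={"C0010": 10 * SIGMA})
        res = call_hits(fits, layout)
        row = res.compounds.set_index("compound_id").loc["C0010"]
        assert row["is_hit"]
        assert row["direction"] == "increase"  # tau_DA up = FRET down

    def test_flagged_compound_excluded_from_hits(self, layout, rng):
        fits = self._fits(layout, rng, shifts={"C0010": 10 * SIGMA})
        flags = pd.DataFrame({"compound_id": ["C0010"], "flagged": [True]})
        res = call_hits(fits, layout, flags)
        row = res.compounds.set_index("compound_id").loc["C0010"]
        assert row["interference_flagged"] and not row["is_hit"]

    def test_too_few_dmso_wells_rejected(self, rng):
        layout = make_uniform_layout(96, dmso_columns=())
        fits = self._fits(layout, rng)
        with pytest.raises(ValueError, match="DMSO"):
            call_hits(fits, layout)

    def test_threshold_monotonicity(self):
        tab = simulate_fitted_tau_plate(5000, 500, TAU0, SIGMA, seed=5)
        hits = {
            k: call_hits_from_table(tab, config=ScreenConfig(hit_threshold_sd=k)).hit_ids
            for k in (3, 4, 5)
        }
        assert hits[5] <= hits[4] <= hits[3]

    def test_one_sided_calling_drops_tau_decreases(self):
        tab = simulate_fitted_tau_plate(
            100, 100, TAU0, SIGMA, seed=6, compound_shifts={0: 10 * SIGMA, 1: -10 * SIGMA}
        )
        res = call_hits_from_table(tab, config=ScreenConfig(two_sided=False))
        hits = res.compounds.set_index("compound_id")
        assert hits.loc["C0000000", "is_hit"]
        assert not hits.loc["C0000001", "is_hit"]

    def test_planted_truth_recovery_with_interferers_excluded(self):
        """Modulator-like shifts >= 8 sigma are all recovered and planted
        interferers are all excluded."""
        modulators = {i: 8 * SIGMA for i in range(5)}
        tab = simulate_fitted_tau_plate(
            400, 100, TAU0, SIGMA, seed=9, compound_shifts=modulators
        )
        interferer_ids = [f"C{i:07d}" for i in range(5, 8)]
        flags = pd.DataFrame({"compound_id": interferer_ids, "flagged": True})
        res = call_hits_from_table(tab, flags=flags)
        mod_ids = {f"C{i:07d}" for i in modulators}
        assert mod_ids <= res.hit_ids
        assert not (set(interferer_ids) & res.hit_ids)


class TestReproducibility:
    def test_identical_hit_sets_are_fully_reproducible(self):
        sets = [{"a", "b", "c"}] * 4
        res = hit_reproducibility(sets)
        assert (res.per_plate["pct_repeated"] == 100.0).all()

    def test_three_plate_enumeration_example(self):
        res = hit_reproducibility([{1, 2, 3}, {1, 2}, {1}], levels=(2, 3))
        per = res.per_plate.set_index(["plate", "level"])["pct_repeated"]
        assert per[(1, 2)] == pytest.approx(100 * 2 / 3)
        assert per[(1, 3)] == pytest.approx(100 * 1 / 3)
        assert per[(2, 2)] == pytest.approx(100.0)
        assert per[(3, 2)] == pytest.approx(100.0)

    def test_zero_hit_plate_reported_missing(self):
        res = hit_reproducibility([{1}, set()], levels=(2,))
        per = res.per_plate.set_index("plate")["pct_repeated"]
        assert np.isnan(per[2])

    def test_levels_monotone_nonincreasing(self):
        rng = np.random.default_rng(12)
        sets = [set(rng.choice(100, size=30, replace=False)) for _ in range(4)]
        res = hit_reproducibility(sets, levels=(2, 3, 4))
        for _, grp in res.per_plate.groupby("plate"):
            vals = grp.sort_values("level")["pct_repeated"].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()

    def test_mean_sem_of_printed_percentages(self):
        m, s = mean_sem([88.5, 79.4, 75.6, 84.4])
        assert m == pytest.approx(82.0, abs=0.05)
        assert s == pytest.approx(2.8, abs=0.05)


class TestZPrime:
    def test_zero_variance_perfect_assay(self):
        res = z_prime([1.0, 1.0], [0.5, 0.5])
        assert res.z_prime == 1.0

    def test_hand_computed_value(self):
        rng = np.random.default_rng(3)
        d = 1.0 + 0.05 * rng.standard_normal(500)
        t = 0.5 + 0.05 * rng.standard_normal(500)
        res = z_prime(d, t)
        by_hand = 1 - 3 * (d.std(ddof=1) + t.std(ddof=1)) / abs(d.mean() - t.mean())
        assert res.z_prime == pytest.approx(by_hand, abs=1e-12)
        assert res.z_prime == pytest.approx(0.4, abs=0.05)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError, match="window"):
            z_prime([1.0, 1.1], [1.0, 1.1])

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        d = np.array([2.28, 2.29, 2.27, 2.285])
        t = np.array([2.45, 2.44, 2.46, 2.455])
        z0 = z_prime(d, t).z_prime
        z1 = z_prime(a * d + b, a * t + b).z_prime
        assert z1 == pytest.approx(z0, rel=1e-9)

    def test_nine_sigma_separation_gives_one_third(self):
        rng = np.random.default_rng(15)
        d = TAU0 + 0.01 * rng.standard_normal(768)
        t = TAU0 + 0.09 + 0.01 * rng.standard_normal(768)
        assert z_prime(d, t).z_prime == pytest.approx(1 - 6 / 9, abs=0.04)


class TestTimecourse:
    @pytest.fixture()
    def layout(self):
        return make_uniform_layout(96, dmso_columns=(1, 2))

    def _fits_at(self, layout, ramp, rng_seed=21, shift=6 * SIGMA):
        rng = np.random.default_rng(rng_seed)
        return _donor_fits(layout, rng, shifts={"C0020": shift * ramp / SIGMA * SIGMA})

    def test_slow_effects_grow_between_reads(self, layout):
        ramps = {20.0: 1 - np.exp(-20 / 60), 120.0: 1 - np.exp(-120 / 60)}
        fits = {tp: self._fits_at(layout, ramp) for tp, ramp in ramps.items()}
        res = screen_timecourse(fits, layout)
        n20 = res.results[20.0].n_hits
        n120 = res.results[120.0].n_hits
        assert n120 >= n20
        assert res.best_timepoint == 120.0

    def test_instant_effects_identical_across_timepoints(self, layout):
        fits = self._fits_at(layout, ramp=1.0)
        res = screen_timecourse({20.0: fits, 120.0: fits, 180.0: fits}, layout)
        sets = [r.hit_ids for r in res.results.values()]
        assert sets[0] == sets[1] == sets[2]

    def test_mismatched_layouts_rejected(self, layout):
        fits = self._fits_at(layout, ramp=1.0)
        with pytest.raises(ValueError, match="mismatch"):
            screen_timecourse({20.0: fits, 120.0: fits.iloc[:-1]}, layout)


class TestTriage:
    def _result(self, shifts, seed):
        tab = simulate_fitted_tau_plate(
            50, 100, TAU0, SIGMA, seed=seed, compound_shifts=shifts
        )
        return call_hits_from_table(tab)

    def test_specific_modulator_is_candidate(self):
        """A compound shifting only the primary (tethered) readout keeps the
        counter screen quiet: the desired mode of action."""
        primary = self._result({0: 12 * SIGMA}, seed=31)
        counter = self._result({}, seed=32)
        triage = triage_with_counter(primary, counter).set_index("compound_id")
        assert triage.loc["C0000000", "classification"] == "candidate"

    def test_cytotoxic_like_hit_is_undesired(self):
        primary = self._result({1: 12 * SIGMA}, seed=33)
        counter = self._result({1: 12 * SIGMA}, seed=34)
        triage = triage_with_counter(primary, counter).set_index("compound_id")
        assert triage.loc["C0000001", "classification"] == "undesired"
        assert triage.loc["C0000001", "reason"] == "counter-active"

    def test_inert_compound_not_classified(self):
        primary = self._result({}, seed=35)
        counter = self._result({}, seed=36)
        triage = triage_with_counter(primary, counter)
        assert "C0000002" not in set(triage["compound_id"])

    def test_compound_missing_from_counter_is_unclassified(self):
        primary = self._result({3: 12 * SIGMA}, seed=37)
        counter = self._result({}, seed=38)
        counter.compounds = counter.compounds[
            counter.compounds["compound_id"] != "C0000003"
        ]
        triage = triage_with_counter(primary, counter).set_index("compound_id")
        assert triage.loc["C0000003", "classification"] == "unclassified"
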