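"""Tests of the fermentation simulator, pure-component library, forward model
and titration bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ramanferm as rf
from ramanferm.synthetic import (MW_GLUCOSE, ReferenceAssay, TITRATION_DESIGNS,
                                 add_stock, extinction_profile, titration_targets)


# ---------------------------------------------------------------------------
# Process trajectories
# ---------------------------------------------------------------------------

class TestBatchSimulation:
    def test_zero_inoculum_rejected(self):
        with pytest.raises(ValueError, match="inoculum"):
            rf.simulate_batch(inoculum=0.0)

    def test_negative_kinetic_parameter_rejected(self):
        with pytest.raises(ValueError):
            rf.simulate_batch(params=rf.KineticParams(qs_max=-1.0))

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_stoichiometric_identity_is_exact(self, seed):
        """Ethanol equals the yield times consumed glucose at every sample, bitwise."""
        traj = rf.simulate_batch(seed=seed)
        p = traj.params
        expected = p["yield_ethanol"] * (p["initial_glucose"] - traj.glucose)
        assert np.array_equal(traj.ethanol, expected)

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_biomass_is_affine_in_glucose(self, seed):
        traj = rf.simulate_batch(seed=seed)
        p = traj.params
        expected = p["inoculum"] + p["yield_biomass"] * MW_GLUCOSE * (
            p["initial_glucose"] - traj.glucose)
        assert np.allclose(traj.biomass, expected, rtol=1e-12)

    def test_depletion_time_matches_fine_step_euler_oracle(self):
        """Independent explicit-Euler integration (dt=1e-3 h) of the same ODE."""
        traj = rf.simulate_batch(seed=3)
        p = traj.params
        dt = 1e-3
        s, t = p["initial_glucose"], 0.0
        while s > p["depletion_threshold"]:
            x = p["inoculum"] + p["yield_biomass"] * MW_GLUCOSE * (p["initial_glucose"] - s)
            s += dt * (-p["qs_max"] * s / (p["ks"] + s) * x)
            t += dt
            assert t < 100.0, "oracle diverged"
        assert abs(t - traj.depletion_time) < p["sampling_interval"]

    def test_trajectory_terminates_at_depletion(self):
        traj = rf.simulate_batch(seed=11)
        assert traj.glucose[-1] <= traj.params["depletion_threshold"] + 1e-6
        assert traj.glucose[0] > 100.0
        # endpoint concentrations land in the usual batch calibration ranges
        assert traj.ethanol.max() <= 175.0
        assert traj.biomass.max() <= 3.6

    def test_hourly_sampling(self):
        traj = rf.simulate_batch(seed=11)
        assert np.allclose(np.diff(traj.time), 1.0)

    def test_reproducible_per_seed(self):
        a = rf.simulate_batch(seed=9)
        b = rf.simulate_batch(seed=9)
        assert np.array_equal(a.glucose, b.glucose)
        assert np.array_equal(a.biomass, b.biomass)


class TestFedBatchSimulation:
    def test_zero_feeds_reduces_to_batch(self):
        batch = rf.simulate_batch(seed=4)
        fed = rf.simulate_fedbatch(n_feeds=0, seed=4)
        assert np.array_equal(batch.glucose, fed.glucose)
        assert np.array_equal(batch.ethanol, fed.ethanol)
        assert np.array_equal(batch.biomass, fed.biomass)

    def test_three_feeds_three_upward_steps(self):
        fed = rf.simulate_fedbatch(seed=4)
        assert len(fed.feed_events) == 3
        assert int(np.sum(np.diff(fed.glucose) > 0)) == 3
        assert np.all(np.diff(fed.biomass) >= -1e-9)

    def test_fedbatch_forces_extrapolation_beyond_batch_range(self):
        """Final fed-batch ethanol exceeds the batch calibration maximum."""
        batch_max = max(rf.simulate_batch(seed=s).ethanol.max() for s in (1, 2, 3))
        fed = rf.simulate_fedbatch(seed=4)
        assert fed.ethanol.max() > batch_max

    def test_trigger_threshold_above_initial_glucose_rejected(self):
        params = rf.KineticParams(depletion_threshold=200.0)
        with pytest.raises(ValueError, match="threshold"):
            rf.simulate_fedbatch(params=params, initial_glucose=111.0, seed=1)


# ---------------------------------------------------------------------------
# Pure component library
# ---------------------------------------------------------------------------

class TestPureLibrary:
    def test_empty_peak_list_gives_zero_spectrum(self, grid):
        lib = rf.build_pure_library({"glucose": ()}, grid=grid, broad_terms={})
        assert np.all(lib.spectrum("glucose").intensity == 0.0)

    def test_fwhm_definition(self, grid):
        peak = rf.PeakSpec(center=879.0, fwhm=12.0, height=1.0)
        profile = peak.render(grid)
        assert profile[grid.index_of(879.0)] == pytest.approx(1.0)
        assert profile[grid.index_of(879.0 - 6.0)] == pytest.approx(0.5)
        assert profile[grid.index_of(879.0 + 6.0)] == pytest.approx(0.5)

    def test_lorentzian_fwhm_definition(self, grid):
        peak = rf.PeakSpec(center=879.0, fwhm=12.0, height=1.0, shape="lorentzian")
        profile = peak.render(grid)
        assert profile[grid.index_of(879.0)] == pytest.approx(1.0)
        assert profile[grid.index_of(873.0)] == pytest.approx(0.5)

    def test_ethanol_argmax_at_879(self, library, grid):
        eth = library.spectrum("ethanol").intensity
        window = grid.mask(850.0, 900.0)
        assert grid.values[window][np.argmax(eth[window])] == 879.0

    @pytest.mark.parametrize("center", [517.0, 1125.0])
    def test_glucose_band_is_local_maximum(self, library, grid, center):
        glc = library.spectrum("glucose").intensity
        i = grid.index_of(center)
        assert glc[i] > glc[i - 5] and glc[i] > glc[i + 5]
        window = grid.mask(center - 25.0, center + 25.0)
        assert grid.values[window][np.argmax(glc[window])] == center

    @pytest.mark.parametrize("window", [(1000.0, 1150.0), (1400.0, 1500.0)])
    def test_glucose_and_ethanol_overlap_windows(self, library, window):
        lo, hi = window
        for comp in ("glucose", "ethanol"):
            centers = [p.center for p in library.spectrum(comp).peaks]
            assert any(lo <= c <= hi for c in centers), f"{comp} lacks a band in {window}"

    def test_879_band_is_free_of_glucose_and_biomass(self, library):
        for comp in ("glucose", "biomass"):
            for p in library.spectrum(comp).peaks:
                assert abs(p.center - 879.0) > 3 * p.fwhm

    def test_peak_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="outside"):
            rf.build_pure_library({"glucose": (rf.PeakSpec(5000.0, 10.0, 1.0),)}, grid=grid)

    def test_biomass_broad_term_ascends_over_fingerprint(self, library, grid):
        broad = library.spectrum("biomass").broad
        i1200, i1600 = grid.index_of(1200.0), grid.index_of(1600.0)
        assert broad[i1600] > broad[i1200] > broad[grid.index_of(450.0)]
        assert np.all(library.spectrum("biomass").intensity >= 0.0)


# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------

def _samples(*rows):
    return pd.DataFrame(rows, columns=["glucose_mM", "ethanol_mM", "biomass_gL"])


class TestRenderSpectra:
    def test_zero_concentrations_zero_noise_gives_baseline(self, library):
        noise = rf.NoiseModel(baseline_amplitude=50.0, baseline_decay_constant=400.0,
                              drift_coefficients=(0, 0, 0), multiplicative_gain_sd=0.0,
                              additive_noise_sd=0.0, seed=0)
        ds = rf.render_spectra(_samples([0.0, 0.0, 0.0]), library, noise=noise)
        assert np.allclose(ds.intensities[0], noise.baseline(library.grid), rtol=0, atol=0)

    def test_linearity_in_each_analyte(self, library):
        noise = rf.NoiseModel.none()
        lo = rf.render_spectra(_samples([30.0, 50.0, 1.0]), library, noise=noise,
                               biomass_mode="suspension_baseline").intensities[0]
        hi = rf.render_spectra(_samples([60.0, 50.0, 1.0]), library, noise=noise,
                               biomass_mode="suspension_baseline").intensities[0]
        ref = rf.render_spectra(_samples([0.0, 50.0, 1.0]), library, noise=noise,
                                biomass_mode="suspension_baseline").intensities[0]
        assert np.allclose(hi - ref, 2.0 * (lo - ref), rtol=1e-12, atol=1e-12)

    def test_nnls_recovers_concentrations_from_noiseless_mixture(self, library):
        """Non-negative least squares against the pure library is the oracle."""
        from scipy.optimize import nnls
        truth = np.array([80.0, 120.0, 2.5])
        ds = rf.render_spectra(_samples(list(truth)), library, noise=rf.NoiseModel.none(),
                               biomass_mode="suspension_baseline")
        recovered, _ = nnls(library.matrix(suspension=True).T, ds.intensities[0])
        assert np.allclose(recovered, truth, rtol=1e-8)

    def test_extinction_attenuates_in_fermentation_mode(self, library):
        noise = rf.NoiseModel.none()
        sus = rf.render_spectra(_samples([50.0, 50.0, 3.0]), library, noise=noise,
                                biomass_mode="suspension_baseline").intensities[0]
        ferm = rf.render_spectra(_samples([50.0, 50.0, 3.0]), library, noise=noise,
                                 biomass_mode="fermentation_extinction").intensities[0]
        broad = library.spectrum("biomass").broad * 3.0
        # suspension keeps the ascending cell baseline; fermentation attenuates instead
        signal = sus - broad
        assert np.all(ferm <= signal + 1e-9)
        assert ferm.sum() < signal.sum()

    def test_grid_mismatch_rejected(self, library):
        other = rf.WavenumberGrid.default(step=2.0)
        with pytest.raises(ValueError, match="grid"):
            rf.render_spectra(_samples([1.0, 1.0, 1.0]), library, grid=other)

    def test_negative_concentration_rejected(self, library):
        with pytest.raises(ValueError, match="non-negative"):
            rf.render_spectra(_samples([-1.0, 0.0, 0.0]), library)

    def test_bitwise_reproducible_under_fixed_seed(self, library):
        noise = rf.NoiseModel(seed=123)
        a = rf.render_spectra(_samples([10.0, 20.0, 1.0]), library, noise=noise)
        b = rf.render_spectra(_samples([10.0, 20.0, 1.0]), library, noise=noise)
        assert np.array_equal(a.intensities, b.intensities)

    def test_replicate_average_noise_shrinks_as_sqrt_k(self, library):
        """SD of the mean of k=10 replicates is ~1/sqrt(10) of a single spectrum."""
        n = 400
        conc = _samples(*[[50.0, 0.0, 0.0]] * n)
        ds = rf.render_spectra(conc, library, noise=rf.NoiseModel(seed=5),
                               biomass_mode="suspension_baseline")
        channel = ds.intensities[:, library.grid.index_of(1125.0)]
        sd_single = channel.std()
        means = channel.reshape(n // 10, 10).mean(axis=1)
        ratio = means.std() / sd_single
        assert 0.32 / 1.6 < ratio < 0.32 * 1.6


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

class TestTitration:
    def test_single_addition_dilution_arithmetic(self):
        """0 mM in 1 L plus 10 mL of 2000 mM -> 2000*0.010/1.010 = 19.80 mM."""
        c = add_stock(0.0, 1.000, 2000.0, 0.010)
        assert c == pytest.approx(19.80, abs=0.005)

    def test_stock_equal_to_current_leaves_concentration_unchanged(self):
        assert add_stock(50.0, 1.0, 50.0, 0.01) == pytest.approx(50.0, rel=1e-12)

    def test_stock_below_current_rejected(self):
        with pytest.raises(ValueError, match="stock"):
            add_stock(100.0, 1.0, 50.0, 0.01)

    @given(st.floats(0.0, 500.0), st.floats(0.0, 2000.0), st.floats(0.001, 0.1))
    def test_dilution_mass_balance(self, c, extra, v_add):
        """Mass in = mass out for any addition (sequential mass-balance oracle)."""
        v = 1.0
        c_stock = c + extra
        c_new = add_stock(c, v, c_stock, v_add)
        assert c_new * (v + v_add) == pytest.approx(c * v + c_stock * v_add, rel=1e-12)
        assert c_new >= c - 1e-12

    @pytest.mark.parametrize("component", ["glucose", "ethanol", "biomass"])
    def test_achieved_levels_match_closed_form_schedule(self, component, library):
        """Sequential add-then-sample bookkeeping lands on the target schedule."""
        series = rf.simulate_titration(component, library=library, seed=1, replicate_count=2)
        d = TITRATION_DESIGNS[component]
        targets = titration_targets(d["spacing"], d["n_additions"], d["target_max"],
                                    d["growth"], d["step_size"])
        assert np.allclose(series.concentrations, targets, rtol=1e-12)
        assert np.all(np.diff(series.levels) > 0)

    def test_default_ranges_cover_the_measured_spans(self, library):
        glc = rf.simulate_titration("glucose", library=library, seed=1, replicate_count=1)
        eth = rf.simulate_titration("ethanol", library=library, seed=1, replicate_count=1)
        bio = rf.simulate_titration("biomass", library=library, seed=1, replicate_count=1)
        assert glc.concentrations.max() == pytest.approx(247.08, abs=1e-6)
        assert 480.0 <= eth.concentrations.max() <= 500.68
        assert bio.concentrations.max() >= 4.9

    def test_ethanol_linear_steps_of_20mM(self, library):
        eth = rf.simulate_titration("ethanol", library=library, seed=1, replicate_count=1)
        assert np.allclose(np.diff(eth.concentrations), 20.0, atol=1e-9)
        assert eth.concentrations.size == 25

    def test_infeasible_step_rejected(self, library):
        with pytest.raises(ValueError, match="stock"):
            rf.simulate_titration("glucose", stock_concentration=100.0, library=library,
                                  seed=1, replicate_count=1)

    def test_replicates_share_level_and_role(self, library):
        series = rf.simulate_titration("ethanol", library=library, seed=2, replicate_count=3)
        refs = series.dataset.reference("ethanol")
        assert series.dataset.n_samples == 3 * (25 + 1)
        assert np.array_equal(refs[:3], np.zeros(3))
        assert set(series.dataset.roles) == {"single_compound"}


# ---------------------------------------------------------------------------
# Scenario-level properties
# ---------------------------------------------------------------------------

class TestScenario:
    def test_cross_correlation_premise(self):
        """Pooled 3-batch reference trajectories correlate above |r| = 0.98."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            seeds = rng.integers(0, 2**31 - 1, size=3)
            refs = pd.concat([rf.simulate_batch(seed=int(s)).to_frame() for s in seeds])
            corr = rf.pearson_matrix(refs[["glucose_mM", "ethanol_mM", "biomass_gL"]])
            assert corr.min_abs_offdiagonal() >= 0.98

    def test_scenario_reproducible(self):
        a = rf.generate_transfer_scenario(seed=5)
        b = rf.generate_transfer_scenario(seed=5)
        assert np.array_equal(a.base_calibration.intensities, b.base_calibration.intensities)
        assert a.base_calibration.meta.equals(b.base_calibration.meta)

    def test_scenario_sample_counts_match_study_design(self, scenario0):
        sc = scenario0
        assert 34 <= sc.base_calibration.n_samples <= 44      # ~38 over three batches
        assert 11 <= sc.validation_batch.n_samples <= 16      # ~13
        assert len(set(sc.base_calibration.meta.role)) == 1
        assert set(sc.fed_batch.meta.role) == {"fed_batch"}

    def test_assay_noise_leaves_trajectory_truth_intact(self, scenario0):
        traj = scenario0.trajectories["batch1"]
        p = traj.params
        assert np.array_equal(traj.ethanol,
                              p["yield_ethanol"] * (p["initial_glucose"] - traj.glucose))

    def test_assay_readings_are_per_titration_level(self, scenario0):
        series = scenario0.titrations["glucose"]
        refs = series.dataset.reference("glucose")
        reps = series.replicate_count
        grouped = refs.reshape(-1, reps)
        assert np.all(grouped == grouped[:, :1])
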