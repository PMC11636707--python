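"""Tracer-transport simulator, incubation generator and fixture factory."""

import numpy as np
import pytest

import bioturbflux as bt
from bioturbflux.sim import SimConfig, IncubationSimConfig, crank_oracle_profile


class TestSimulateProfile:
    def test_zero_diffusion_keeps_tracer_in_initial_layer(self):
        prof = bt.simulate_profile(SimConfig(db_true=0.0, jump_prob=0.0,
                                             n_particles=1000, seed=2))
        in_layer = prof.x < SimConfig().layer_thickness
        assert prof.counts[~in_layer].sum() == 0
        assert prof.counts.sum() == 1000

    def test_mass_conservation_with_absorbing_cap(self):
        cfg = SimConfig(db_true=300.0, depth_max=2.0, n_particles=5000, seed=3)
        prof = bt.simulate_profile(cfg)
        assert prof.n_capped > 0  # strong mixing in a shallow domain caps some
        assert prof.counts.sum() + prof.n_capped == cfg.n_particles

    def test_profile_matches_closed_form_crank_curve(self):
        """Diffusive-only histogram converges on the half-Gaussian oracle."""
        cfg = SimConfig(db_true=50.0, n_particles=30_000, layer_thickness=0.05,
                        seed=5)
        prof = bt.simulate_profile(cfg)
        edges = np.arange(0, cfg.depth_max + cfg.bin_width / 2, cfg.bin_width)
        oracle = crank_oracle_profile(cfg.db_true, cfg.t_days / 365, edges)
        mad = np.mean(np.abs(prof.concentration - oracle))
        from scipy.stats import halfnorm
        mass = np.diff(halfnorm.cdf(edges, scale=np.sqrt(2 * 50.0 * 10 / 365)))
        bound = np.mean(np.sqrt(cfg.n_particles * mass * (1 - mass))) \
            * cfg.n_input / (cfg.n_particles * cfg.bin_width)
        assert mad < 3 * bound

    def test_crank_fit_recovers_true_db(self):
        prof = bt.simulate_profile(SimConfig(db_true=100.0, jump_prob=0.0,
                                             n_particles=50_000, seed=1))
        db, _ = bt.fit_db(prof)
        assert db == pytest.approx(100.0, rel=0.05)

    def test_fitted_db_monotone_in_true_db(self):
        fitted = []
        for db_true in (10.0, 50.0, 100.0, 300.0):
            prof = bt.simulate_profile(SimConfig(db_true=db_true,
                                                 n_particles=20_000, seed=9))
            fitted.append(bt.fit_db(prof)[0])
        assert all(a < b for a, b in zip(fitted, fitted[1:]))

    def test_jump_injection_raises_nli(self):
        """Non-local downward events must inflate the non-locality index."""
        def run(jump_prob):
            prof = bt.simulate_profile(SimConfig(
                db_true=50.0, n_particles=30_000, jump_prob=jump_prob,
                jump_depth_mean=8.0, seed=42))
            db, _ = bt.fit_db(prof)
            db_log, _ = bt.fit_db_log(prof)
            return bt.nli(db, db_log)

        assert run(0.05) > run(0.0)

    @pytest.mark.parametrize("bad", [
        dict(db_true=-1.0), dict(t_days=0.0), dict(dt_days=0.0),
        dict(jump_prob=1.5), dict(bin_width=0.0), dict(n_particles=0),
        dict(db_true=float("nan")),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            bt.simulate_profile(SimConfig(**bad))


class TestRenderImage:
    def test_render_extract_round_trip_is_identity(self):
        prof = bt.simulate_profile(SimConfig(db_true=30.0, n_particles=3000,
                                             seed=4))
        img = bt.render_spi_image(prof, px_per_cm=20.0, image_width_px=150,
                                  water_height_px=30, seed=1)
        back = bt.profile_image(img, px_per_cm=20.0, bin_width_cm=0.25,
                                smooth_window=1)
        np.testing.assert_array_equal(back.counts[:len(prof.counts)],
                                      prof.counts)

    def test_empty_profile_renders_no_luminophore_pixels(self):
        prof = bt.DepthProfile(x=[0.125, 0.375], counts=[0, 0], bin_width=0.25)
        img = bt.render_spi_image(prof, px_per_cm=20.0, image_width_px=50,
                                  water_height_px=10)
        lum = (img == np.array(bt.sim.LUM_RGB, np.uint8)).all(axis=2)
        assert lum.sum() == 0

    def test_pixel_count_lands_in_bin_row_band(self):
        counts = [0, 0, 0, 37, 0]
        prof = bt.DepthProfile(x=np.arange(5) * 0.25 + 0.125, counts=counts,
                               bin_width=0.25)
        img = bt.render_spi_image(prof, px_per_cm=20.0, image_width_px=60,
                                  water_height_px=12, seed=0)
        lum = (img == np.array(bt.sim.LUM_RGB, np.uint8)).all(axis=2)
        band = lum[12 + 3 * 5: 12 + 4 * 5, :]
        assert band.sum() == 37 and lum.sum() == 37

    def test_overfull_bin_rejected_with_message(self):
        prof = bt.DepthProfile(x=[0.125], counts=[10_000], bin_width=0.25)
        with pytest.raises(ValueError, match="row band"):
            bt.render_spi_image(prof, px_per_cm=20.0, image_width_px=10,
                                water_height_px=5)


class TestSimulateIncubation:
    def test_no_flux_no_noise_gives_constant_concentration(self):
        s = bt.simulate_incubation(IncubationSimConfig(
            j_true=0.0, noise_sd=0.0, c0=12.0, c_tank=12.0))
        np.testing.assert_allclose(s.conc, 12.0)

    def test_sampled_slope_equals_ja_over_v(self):
        s = bt.simulate_incubation(IncubationSimConfig(
            j_true=100.0, v_liters=1.0, area_m2=0.00785, noise_sd=0.0,
            sample_volume_ml=0.0))
        r, _ = bt.regress_slope(s.times_h, s.conc)
        assert r == pytest.approx(0.785)

    def test_dilution_biases_raw_slope_but_correction_recovers_flux(self):
        cfg = IncubationSimConfig(j_true=100.0, c0=5.0, c_tank=20.0,
                                  noise_sd=0.0, sample_volume_ml=20.0)
        s = bt.simulate_incubation(cfg)
        raw_slope, _ = bt.regress_slope(s.times_h, s.conc)
        j_uncorrected = bt.net_flux(raw_slope, cfg.v_liters, cfg.area_m2)
        assert j_uncorrected != pytest.approx(100.0, rel=0.001)
        j = bt.compute_flux(s).j_raw
        assert j == pytest.approx(100.0, rel=0.01)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            bt.simulate_incubation(IncubationSimConfig(v_liters=0.0))
        with pytest.raises(ValueError):
            bt.simulate_incubation(IncubationSimConfig(sample_times_h=(2.0, 1.0)))


class TestExperimentFixture:
    def test_design_counts(self, experiment):
        assert len(experiment.metadata) == 72
        assert (experiment.metadata.species == "control").sum() == 24
        assert experiment.metadata.tank.nunique() == 12
        temps = experiment.metadata.groupby("temperature_c").tank.nunique()
        assert temps[15.0] == 6 and temps[20.0] == 6

    def test_fixture_is_deterministic(self, experiment):
        import pandas as pd
        again = bt.make_experiment_fixture(11, n_particles=2000)
        pd.testing.assert_frame_equal(experiment.metadata, again.metadata)
        pd.testing.assert_frame_equal(experiment.profiles, again.profiles)
        pd.testing.assert_frame_equal(experiment.incubations, again.incubations)
        pd.testing.assert_frame_equal(experiment.truth, again.truth)

    def test_noiseless_truth_reproduces_preset_q10(self, experiment):
        from bioturbflux.sim import SPECIES_PRESETS
        truth = experiment.truth[experiment.truth.species != "control"]
        q = bt.q10_from_groups(truth.rename(columns={"db_true": "rate"}))
        for _, row in q.iterrows():
            assert row.q10 == pytest.approx(
                SPECIES_PRESETS[row.species]["q10_bioturb"])
        qo = bt.q10_from_groups(truth.rename(columns={"o2_flux_true": "rate"}),
                                magnitude=True)
        for _, row in qo.iterrows():
            assert row.q10 == pytest.approx(SPECIES_PRESETS[row.species]["q10_o2"])

    def test_warm_presets_exceed_cold_for_responsive_species(self, experiment):
        truth = experiment.truth[experiment.truth.species == "A. marina"]
        warm = truth[truth.temperature_c == 20.0].db_true.mean()
        cold = truth[truth.temperature_c == 15.0].db_true.mean()
        assert warm > cold
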