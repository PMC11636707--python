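"""Crank-model fitting, the non-locality index, and burial-depth metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bioturbflux as bt

T10 = 10 / 365  # the study's 10-day incubation, in years


class TestCrankConcentration:
    def test_surface_value(self):
        # C(0) = N / sqrt(pi * db * t)
        assert bt.crank_concentration(0.0, T10, 100.0, 0.94) == pytest.approx(
            0.94 / np.sqrt(np.pi * 100.0 * T10))
        assert bt.crank_concentration(0.0, T10, 100.0, 0.94) == pytest.approx(
            0.3204, abs=2e-4)

    def test_strictly_decreasing_in_depth(self):
        x = np.linspace(0, 10, 50)
        c = bt.crank_concentration(x, T10, 100.0, 0.94)
        assert np.all(np.diff(c) < 0)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            bt.crank_concentration(1.0, 0.0, 100.0, 0.94)
        with pytest.raises(ValueError):
            bt.crank_concentration(1.0, T10, 0.0, 0.94)


class TestFitDb:
    def test_exact_profile_recovered_to_machine_precision(self, crank_profile):
        db, rss = bt.fit_db(crank_profile)
        assert db == pytest.approx(50.0, rel=1e-6)
        assert rss < 1e-12

    def test_log_fit_agrees_on_exact_profile(self, crank_profile):
        db_log, _ = bt.fit_db_log(crank_profile)
        assert db_log == pytest.approx(50.0, rel=1e-6)

    def test_deeper_spread_gives_larger_db(self):
        fitted = []
        for db_true in (10.0, 40.0, 160.0):
            x = np.arange(0.125, 15.0, 0.25)
            conc = bt.crank_concentration(x, T10, db_true, 0.94)
            p = bt.DepthProfile(x=x, counts=conc, bin_width=0.25, t_yr=T10,
                                concentration=conc)
            fitted.append(bt.fit_db(p)[0])
        assert fitted[0] < fitted[1] < fitted[2]

    def test_scale_consistency(self, crank_profile):
        db_ref, _ = bt.fit_db(crank_profile)
        scaled = bt.DepthProfile(
            x=crank_profile.x, counts=crank_profile.counts * 7,
            bin_width=crank_profile.bin_width, t_yr=crank_profile.t_yr,
            n_input=crank_profile.n_input * 7,
            concentration=crank_profile.concentration * 7)
        db_scaled, _ = bt.fit_db(scaled)
        assert db_scaled == pytest.approx(db_ref, rel=1e-6)

    def test_deep_pulse_inflates_log_fit_only(self):
        """Low-concentration mass at depth dominates in log space."""
        x = np.arange(0.125, 12.0, 0.25)
        conc = bt.crank_concentration(x, T10, 20.0, 0.94)
        conc[np.argmin(np.abs(x - 10.0))] += 1e-4  # faint deep tracer pulse
        p = bt.DepthProfile(x=x, counts=conc, bin_width=0.25, t_yr=T10,
                            concentration=conc)
        db, _ = bt.fit_db(p)
        db_log, _ = bt.fit_db_log(p)
        assert db_log > db
        assert db == pytest.approx(20.0, rel=0.01)

    def test_zero_bins_dropped_without_changing_exact_fit(self, crank_profile):
        conc = crank_profile.concentration.copy()
        conc[-5:] = 0.0
        p = bt.DepthProfile(x=crank_profile.x, counts=conc, bin_width=0.25,
                            t_yr=T10, concentration=conc)
        db_log, _ = bt.fit_db_log(p)
        assert db_log == pytest.approx(50.0, rel=1e-4)

    def test_too_few_nonzero_bins_rejected(self):
        p = bt.DepthProfile(x=[0.5, 1.5, 2.5], counts=[1.0, 1.0, 0.0],
                            bin_width=1.0, t_yr=T10,
                            concentration=np.array([0.3, 0.1, 0.0]))
        with pytest.raises(ValueError, match="non-zero"):
            bt.fit_db(p)

    def test_unnormalized_profile_rejected(self):
        p = bt.DepthProfile(x=[0.5, 1.5, 2.5], counts=[3, 2, 1],
                            bin_width=1.0, t_yr=T10)
        with pytest.raises(ValueError, match="normalized"):
            bt.fit_db(p)


class TestNli:
    def test_equal_rates_give_zero(self):
        assert bt.nli(37.2, 37.2) == 0.0

    def test_hand_value(self):
        assert bt.nli(1.0, 4.0) == pytest.approx(1.5)

    @given(a=st.floats(0.01, 1e4), b=st.floats(0.01, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_nonnegative(self, a, b):
        assert bt.nli(a, b) == pytest.approx(bt.nli(b, a))
        assert bt.nli(a, b) >= 0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            bt.nli(0.0, 1.0)


class TestBurialDepths:
    def test_point_mass_mean_depth(self):
        p = bt.DepthProfile(x=[1.0, 2.0, 3.0], counts=[0, 5, 0], bin_width=1.0)
        assert bt.mean_weighted_depth(p) == pytest.approx(2.0)

    def test_equal_mass_at_two_depths_averages(self):
        p = bt.DepthProfile(x=[1.0, 2.0, 3.0], counts=[4, 0, 4], bin_width=1.0)
        assert bt.mean_weighted_depth(p) == pytest.approx(2.0)

    def test_mean_depth_increases_with_db(self):
        means = []
        for db in (10.0, 100.0, 400.0):
            x = np.arange(0.05, 30.0, 0.1)
            conc = bt.crank_concentration(x, T10, db, 0.94)
            p = bt.DepthProfile(x=x, counts=conc, bin_width=0.1,
                                concentration=conc)
            means.append(bt.mean_weighted_depth(p))
        assert means[0] < means[1] < means[2]
        # half-normal mean = sqrt(4*db*t/pi) on an unbounded domain
        assert means[1] == pytest.approx(np.sqrt(4 * 100.0 * T10 / np.pi),
                                         rel=0.01)

    def test_max_depth_examples(self):
        shallow = bt.DepthProfile(x=[0.25, 0.75, 1.25], counts=[5, 3, 0],
                                  bin_width=0.5)
        assert bt.max_depth(shallow) <= 1.0
        deep = bt.DepthProfile(x=[0.5, 17.24], counts=[0, 1], bin_width=1.0)
        assert bt.max_depth(deep) == pytest.approx(17.24)

    def test_empty_profile_max_depth_zero_with_flag(self):
        p = bt.DepthProfile(x=[0.5, 1.5], counts=[0, 0], bin_width=1.0)
        assert bt.max_depth(p) == 0.0
        assert p.flags.get("empty") is True

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_mean_never_exceeds_max(self, counts):
        counts = np.asarray(counts)
        if counts.sum() == 0:
            return
        p = bt.DepthProfile(x=np.arange(len(counts)) + 0.5, counts=counts,
                            bin_width=1.0)
        assert bt.mean_weighted_depth(p) <= bt.max_depth(p) + 1e-12


class TestControlCorrect:
    def _tables(self, raw, ctrl_values):
        import pandas as pd
        rows = [dict(core_id="s1", db=raw)]
        meta = [dict(core_id="s1", species="A. marina", site="Uthoern",
                     temperature_c=15.0)]
        for i, v in enumerate(ctrl_values):
            rows.append(dict(core_id=f"c{i}", db=v))
            meta.append(dict(core_id=f"c{i}", species="control",
                             site="Uthoern", temperature_c=15.0))
        return pd.DataFrame(rows), pd.DataFrame(meta)

    def test_zero_controls_identity(self):
        res, meta = self._tables(10.0, [0.0, 0.0])
        out = bt.control_correct(res, meta, value_cols=("db",))
        assert out.loc[out.core_id == "s1", "db_corrected"].iloc[0] == 10.0

    def test_mean_control_subtracted(self):
        res, meta = self._tables(10.0, [2.0, 4.0])
        out = bt.control_correct(res, meta, value_cols=("db",))
        assert out.loc[out.core_id == "s1", "db_corrected"].iloc[0] == 7.0

    def test_negative_corrected_floored_with_flag(self):
        res, meta = self._tables(1.0, [2.0, 2.0])
        out = bt.control_correct(res, meta, value_cols=("db",))
        row = out[out.core_id == "s1"].iloc[0]
        assert row.db_corrected == 0.0
        assert bool(row.db_floored)

    def test_missing_control_group_rejected_naming_group(self):
        import pandas as pd
        res = pd.DataFrame([dict(core_id="s1", db=5.0)])
        meta = pd.DataFrame([dict(core_id="s1", species="L. conchilega",
                                  site="Reef", temperature_c=20.0)])
        with pytest.raises(ValueError, match="Reef"):
            bt.control_correct(res, meta, value_cols=("db",))
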