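"""Velocity/PSV derivation, behavioural outlier filtering, and the
pupil cleaning chain."""

import numpy as np
import pandas as pd
import pytest

from loomdyn import preprocess as pp
from loomdyn.synth import PupilTrace


def _design_velocities():
    return [pp.compute_velocity(1280, w0, a)
            for w0 in (256.0, 384.0) for a in (3.0, 3.5, 4.0, 4.5, 5.0)]


class TestVelocity:
    def test_design_extremes(self):
        vs = _design_velocities()
        assert min(vs) == pytest.approx(179.2, abs=0.05)
        assert max(vs) == pytest.approx(341.3, abs=0.05)

    def test_zero_expansion(self):
        assert pp.compute_velocity(1280, 1280, 4.0) == 0.0

    def test_invalid_attc(self):
        with pytest.raises(ValueError):
            pp.compute_velocity(1280, 256, 0.0)

    def test_distinct_velocities_in_default_design(self):
        # 10 design cells, but (1280-256)/4 == (1280-384)/3.5 == 256 px/s,
        # so 9 distinct velocities exist
        vs = np.round(_design_velocities(), 9)
        assert len(np.unique(vs)) == 9
        assert min(vs) == pytest.approx((1280 - 0.3 * 1280) / 5, abs=1e-9)
        assert max(vs) == pytest.approx((1280 - 0.2 * 1280) / 3, abs=1e-9)


class TestPSV:
    def test_printed_boundaries(self):
        edges = pp.psv_edges(_design_velocities())
        # V1/V2 boundaries match the published values at one decimal
        printed = np.floor(edges * 10 + 1e-9) / 10
        assert printed[1] == 211.6
        assert printed[2] == 244.0
        # all six edges sit within one printed decimal of the published list
        np.testing.assert_allclose(
            edges, [179.2, 211.6, 244.0, 276.4, 308.8, 341.3], atol=0.11)

    @pytest.mark.parametrize("v,expected", [
        (179.2, 1),      # range minimum opens V1
        (250.0, 3),      # falls in [244.0, 276.4)
        (341.3333333333333, 5),  # maximum, right-closed
    ])
    def test_assignment(self, v, expected):
        edges = pp.psv_edges(_design_velocities())
        assert pp.assign_psv(v, edges) == expected

    def test_shared_boundary_goes_to_upper_bin(self):
        edges = pp.psv_edges(_design_velocities())
        assert pp.assign_psv(float(edges[1]), edges) == 2

    def test_out_of_range_reported(self):
        edges = pp.psv_edges(_design_velocities())
        with pytest.raises(ValueError, match="100"):
            pp.assign_psv(100.0, edges)

    def test_add_velocity_bins_consistency(self, tiny_config):
        from loomdyn import synth
        d = synth.generate_design(tiny_config)
        out = pp.add_velocity_bins(d)
        edges = pp.psv_edges(out["velocity"])
        for _, r in out.sample(20, random_state=0).iterrows():
            w0 = r["initial_frac"] * 1280
            assert r["velocity"] == (1280 - w0) / r["attc"]
            assert r["psv_bin"] == pp.assign_psv(r["velocity"], edges)


class TestJttcFilter:
    @staticmethod
    def _table(values):
        return pd.DataFrame({"subject_id": "s1",
                             "jttc": np.asarray(values, dtype=float)})

    def test_small_deviation_survives(self):
        # with ordinary trial-to-trial spread, a 0.1 s deviation is far
        # inside the 5 SD bound
        rng = np.random.default_rng(7)
        t = self._table(list(rng.normal(4.0, 0.2, 100)) + [4.1])
        out = pp.filter_jttc_outliers(t)
        assert out["included"].all()

    def test_six_sd_outlier_flagged(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(4.0, 0.2, 200)
        mu, sd = vals.mean(), vals.std(ddof=1)
        vals = np.append(vals, mu + 6 * sd)
        out = pp.filter_jttc_outliers(self._table(vals))
        # recompute with the outlier in the pool, as the filter does
        mu2 = vals.mean()
        sd2 = vals.std(ddof=1)
        expect = np.abs(vals - mu2) > 5 * sd2
        np.testing.assert_array_equal(~out["included"].to_numpy(), expect)
        assert not out["included"].iloc[-1]

    def test_identical_values_all_kept(self):
        out = pp.filter_jttc_outliers(self._table([4.0] * 50))
        assert out["included"].all()

    def test_technical_stage_runs_first(self):
        t = self._table([4.0, 4.1, -1.0, np.nan])
        out = pp.filter_jttc_outliers(t)
        assert list(out["exclude_reason"]) == ["", "", "technical",
                                               "technical"]


class TestConversion:
    def test_zero_area_zero_diameter(self):
        assert pp.convert_area_to_diameter([0.0])[0] == 0.0

    def test_sqrt_scaling(self):
        d1 = pp.convert_area_to_diameter([100.0])[0]
        d4 = pp.convert_area_to_diameter([400.0])[0]
        assert d4 == pytest.approx(2 * d1)

    def test_diameter_passthrough(self):
        out = pp.convert_area_to_diameter([3.2], units_in="diameter_mm")
        assert out[0] == 3.2

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pp.convert_area_to_diameter([-1.0])


def _trace(t, d, valid=None):
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    valid = np.ones(len(t), bool) if valid is None else np.asarray(valid)
    return PupilTrace(trial_id="x", t=t, d=d, valid=valid)


class TestCleanTrace:
    def test_clean_constant_unchanged(self):
        tr = _trace(np.arange(0, 1000, 10), np.full(100, 4.0))
        out = pp.clean_trace(tr)
        np.testing.assert_array_equal(out.d, tr.d)
        assert out.meta["frac_interpolated"] == 0.0

    def test_gap_in_ramp_interpolated_exactly(self):
        t = np.arange(0, 2000, 10.0)
        d = 3.0 + 0.001 * t
        valid = np.ones(len(t), bool)
        gap = (t >= 1000) & (t < 1100)
        valid[gap] = False
        out = pp.clean_trace(_trace(t, d.copy(), valid))
        np.testing.assert_allclose(out.d, 3.0 + 0.001 * t, atol=1e-12)

    def test_spike_removed(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 3000, 10.0)
        d = 4.0 + rng.normal(0, 0.05, len(t))
        mu, sd = d.mean(), d.std(ddof=1)
        d[150] = mu + 6 * sd
        out = pp.clean_trace(_trace(t, d), pad_ms=0)
        assert out.d.max() < d.max()

    def test_sample_count_preserved_and_quality_flag(self):
        t = np.arange(0, 1000, 10.0)
        d = np.full(len(t), 4.0)
        valid = np.ones(len(t), bool)
        valid[:50] = False  # 50% bad
        out = pp.clean_trace(_trace(t, d, valid))
        assert len(out.d) == len(t)
        assert out.excluded and out.exclude_reason == "low_quality"


class TestDownsample:
    def test_constant_2khz(self):
        t = np.arange(0, 100, 0.5)  # 2,000 Hz
        out = pp.downsample(_trace(t, np.full(len(t), 4.0)))
        np.testing.assert_allclose(out.d, 4.0)
        assert out.dt == 10.0

    def test_alternating_mean(self):
        t = np.arange(0, 100, 0.5)
        d = np.where(np.arange(len(t)) % 2 == 0, 3.0, 5.0)
        out = pp.downsample(_trace(t, d))
        np.testing.assert_allclose(out.d, 4.0)

    def test_ramp_bins_hit_midpoints(self):
        t = np.arange(0, 100, 0.5)
        out = pp.downsample(_trace(t, t.copy()))
        expect = out.t + np.mean(np.arange(20) * 0.5)  # mean offset in bin
        np.testing.assert_allclose(out.d, expect, atol=1e-9)

    def test_global_mean_preserved(self, rng):
        t = np.arange(0, 500, 0.5)
        d = rng.normal(4, 0.3, len(t))
        out = pp.downsample(_trace(t, d))
        assert out.d.mean() == pytest.approx(d.mean(), abs=1e-9)

    def test_empty_bin_flagged_invalid(self):
        t = np.arange(0, 40, 0.5)
        valid = ~((t >= 10) & (t < 20))
        out = pp.downsample(_trace(t, np.full(len(t), 4.0), valid))
        assert not out.valid[1]
        assert out.valid[[0, 2, 3]].all()


class TestBaseline:
    def test_constant_trace_zeroed(self):
        t = np.arange(0, 2000, 10.0)
        out = pp.baseline_correct(_trace(t, np.full(len(t), 3.5)))
        np.testing.assert_allclose(out.d, 0.0)
        assert out.baseline_mean == 3.5
        assert out.corrected

    def test_idempotent(self):
        t = np.arange(0, 2000, 10.0)
        d = 4 + np.sin(t / 300)
        once = pp.baseline_correct(_trace(t, d))
        twice = pp.baseline_correct(once)
        np.testing.assert_allclose(once.d, twice.d, atol=1e-12)

    def test_shift_invariance(self):
        t = np.arange(0, 2000, 10.0)
        d = 4 + np.sin(t / 300)
        a = pp.baseline_correct(_trace(t, d))
        b = pp.baseline_correct(_trace(t, d + 1.7))
        np.testing.assert_allclose(a.d, b.d, atol=1e-12)

    def test_no_baseline_samples_excludes(self):
        t = np.arange(0, 2000, 10.0)
        valid = t >= 300
        out = pp.baseline_correct(_trace(t, np.full(len(t), 4.0), valid))
        assert out.excluded and out.exclude_reason == "no_baseline"


class TestPhaseWindows:
    def test_window_definitions(self):
        wins = pp.phase_windows(3.0)  # key press at 3,300 ms
        assert wins["stimulus"] == (300.0, 1300.0)
        assert wins["early_imagination"] == (1300.0, 1800.0)
        assert wins["late_imagination"] == (2800.0, 3300.0)

    def test_boundary_trial_abuts_early_window(self):
        wins = pp.phase_windows(2.0)  # key press at exactly 2,300 ms
        assert wins["late_imagination"] == (1800.0, 2300.0)

    def test_short_trial_excluded(self):
        with pytest.raises(ValueError, match="short"):
            pp.phase_windows(1.95)  # key press at 2,250 ms

    def test_phase_means_on_step_trace(self):
        t = np.arange(0, 3300, 10.0)
        d = np.where(t < 1300, 1.0, 2.0)
        means = pp.phase_means(_trace(t, d), 3.0)
        assert means["stimulus"] == 1.0
        assert means["early_imagination"] == 2.0
        assert means["late_imagination"] == 2.0
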