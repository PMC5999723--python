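"""Preprocessing chain: filtering, onset and impact detection, features."""

import math

import numpy as np
import pytest
from scipy.signal import butter, freqz

import gripswitch as gs
from gripswitch.design import FieldParams
from gripswitch.filters import central_difference, zero_phase_lowpass
from gripswitch.preprocess import (
    ImpactNotFoundError,
    OnsetNotFoundError,
    catch_neighbor_diffs,
    derive_and_filter,
    extract_features,
    impact_time,
    movement_onset,
)
from gripswitch.simulate import TrialMeta, TrialSeries

FS = 500.0


def _series(t, y=None, f_load=None, f_grip=None, fp=None, **meta_kw):
    n = len(t)
    fp = fp or FieldParams(k=100.0, y0=0.05)
    meta = TrialMeta(participant=1, block=1, trial=meta_kw.pop("trial", 1),
                     condition="ascending", field=fp, regime="soft",
                     vp_target=0.5, truth_lag_ms=math.nan,
                     t_impact_true=math.nan)
    zeros = np.zeros(n)
    return TrialSeries(t=t, y=zeros if y is None else y, v=zeros.copy(),
                       a=zeros.copy(),
                       f_load=zeros if f_load is None else f_load,
                       f_grip=np.ones(n) if f_grip is None else f_grip,
                       meta=meta)


class TestDeriveAndFilter:
    def test_linear_ramp_derivative_is_constant(self):
        t = np.arange(0, 2, 1 / FS)
        c = 0.037
        v = central_difference(c * t, FS)
        assert np.allclose(v[1:-1], c, atol=1e-9)

    def test_passband_sine_unchanged(self):
        # 2 Hz is deep in the 20 Hz passband: unit gain, zero peak shift
        t = np.arange(0, 4, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = zero_phase_lowpass(x, FS, 20.0)
        core = slice(200, -200)
        assert np.abs(y[core] - x[core]).max() < 0.01
        # zero net phase shift: cross-correlation peaks at zero lag
        xc = np.correlate(y[core], x[core], "full")
        assert np.argmax(xc) == len(x[core]) - 1

    def test_stopband_attenuation_matches_design(self):
        # oracle: squared magnitude of the designed 4th-order response
        t = np.arange(0, 4, 1 / FS)
        f0 = 100.0
        x = np.sin(2 * np.pi * f0 * t)
        y = zero_phase_lowpass(x, FS, 20.0)
        b, a = butter(4, 20.0 / (FS / 2.0))
        _, h = freqz(b, a, worN=[2 * np.pi * f0 / FS])
        expected_gain = np.abs(h[0]) ** 2  # two passes
        measured = y[500:-500].std() / x[500:-500].std()
        assert measured == pytest.approx(expected_gain, rel=0.05, abs=1e-6)

    def test_zero_phase_preserves_symmetric_pulse_argmax(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.exp(-((t - 1.0) ** 2) / (2 * 0.05**2))
        y = zero_phase_lowpass(x, FS, 20.0)
        assert np.argmax(y) == np.argmax(x)

    def test_nonuniform_time_base_rejected(self):
        t = np.array([0.0, 0.002, 0.005, 0.006])
        s = _series(t)
        with pytest.raises(ValueError):
            derive_and_filter(s)

    def test_output_lengths_match(self, small_noisy_cohort):
        s = small_noisy_cohort[0]
        v, a, gfr = derive_and_filter(s)
        assert len(v) == len(a) == len(gfr) == len(s.t)


class TestMovementOnset:
    def test_step_onset_found_at_step(self):
        v = np.zeros(1000)
        v[100:] = 0.10
        assert movement_onset(v, FS) == 100  # direct-scan oracle

    def test_constant_zero_raises(self):
        with pytest.raises(OnsetNotFoundError):
            movement_onset(np.zeros(1000), FS)

    def test_short_blip_ignored(self):
        # 50 ms supra-threshold blip then silence, sustained crossing at 300
        v = np.zeros(1000)
        v[100:125] = 0.10
        v[300:] = 0.10
        assert movement_onset(v, FS) == 300

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        v = np.clip(rng.normal(0.0, 0.005, 800), None, 0.02)
        v[400:] = 0.08
        base = movement_onset(v, FS)
        shifted = movement_onset(np.concatenate([np.zeros(500), v]), FS)
        assert shifted == base + 500


class TestImpactTime:
    def test_monotone_rise_fall_argmax(self):
        t = np.arange(0, 2, 1 / FS)
        f_load = np.maximum(0.0, 1.0 - np.abs(t - 1.2) / 0.3)
        s = _series(t, f_load=f_load)
        i, t_imp, peak = impact_time(s)
        assert t_imp == pytest.approx(1.2, abs=1 / FS)
        assert peak == pytest.approx(1.0)

    def test_tie_broken_to_earliest(self):
        t = np.arange(0, 1, 1 / FS)
        f_load = np.zeros_like(t)
        f_load[200:211] = 2.0  # flat plateau
        s = _series(t, f_load=f_load)
        i, _, _ = impact_time(s)
        assert i == 200

    def test_catch_with_same_kinematics_matches_real(self):
        # same position track through the same (expected) field -> same impact
        t = np.arange(0, 2, 1 / FS)
        y = 0.15 * np.sin(np.pi * np.clip(t - 0.2, 0, 1.2) / 1.2) ** 2
        fp_real = FieldParams(k=200.0, y0=0.08)
        fp_catch = FieldParams(k=0.0, y0=0.0, is_catch=True,
                               expected_k=200.0, expected_y0=0.08)
        f_load = gs.elastic_force(y, fp_real)
        real = _series(t, y=y, f_load=f_load, fp=fp_real)
        catch = _series(t, y=y, f_load=np.zeros_like(t), fp=fp_catch)
        ir, tr_, pr = impact_time(real)
        ic, tc_, pc = impact_time(catch)
        assert ir == ic and pr == pytest.approx(pc)

    def test_never_entering_field_raises(self):
        t = np.arange(0, 1, 1 / FS)
        s = _series(t, y=np.full_like(t, 0.01))
        with pytest.raises(ImpactNotFoundError):
            impact_time(s)


class TestExtractFeatures:
    def test_constructed_40ms_shift_recovered(self):
        # grip equals the load profile shifted +40 ms -> lag_impact = 40
        t = np.arange(0, 3, 1 / FS)
        y = 0.15 * np.sin(np.pi * np.clip(t - 0.5, 0, 1.4) / 1.4) ** 2
        fp = FieldParams(k=200.0, y0=0.08)
        f_load = gs.elastic_force(y, fp)
        shift = int(0.040 * FS)
        f_grip = 2.0 + np.roll(f_load, shift)
        f_grip[:shift] = 2.0
        s = _series(t, y=y, f_load=f_load, f_grip=f_grip, fp=fp)
        feat = extract_features(s)
        assert feat.lag_impact == pytest.approx(40.0, abs=2.0)

    def test_zero_noise_recovery_within_one_sample(self, zero_noise_features,
                                                   zero_noise_truth):
        m = zero_noise_features.merge(
            zero_noise_truth, on=["participant", "block", "trial"])
        err = (m["lag_impact"] - m["truth_lag_ms"]).abs()
        assert err.max() <= 2.0  # one sample at 500 Hz

    def test_zero_noise_inertial_lag_near_zero(self, zero_noise_features):
        li = zero_noise_features["lag_inertial"].dropna()
        assert abs(li.mean()) < 2.0
        assert li.abs().quantile(0.95) <= 6.0

    def test_onset_precedes_impact(self, zero_noise_features):
        assert (zero_noise_features["t_onset"]
                < zero_noise_features["t_impact"]).all()

    def test_mini_block_assignment(self, zero_noise_features):
        mb = zero_noise_features.groupby("mini_block")["trial"].count()
        n_blocks = zero_noise_features.groupby(["participant", "block"]).ngroups
        assert list(mb / n_blocks) == [10, 5, 5, 5, 5, 5, 10]


class TestCatchNeighborDiffs:
    def test_identical_rates_give_zero_diffs(self, zero_noise_features):
        block = zero_noise_features.query("participant == 1 and block == 1").copy()
        block["gfr_at_onset"] = 7.0
        d = catch_neighbor_diffs(block)
        assert len(d) == 6
        assert np.allclose(d[["diff_prev", "diff_next"]].dropna(), 0.0)

    def test_arithmetic(self, zero_noise_features):
        block = zero_noise_features.query("participant == 1 and block == 1").copy()
        block["gfr_at_onset"] = np.where(block["is_catch"], 12.0, 10.0)
        d = catch_neighbor_diffs(block)
        vals = d[["diff_prev", "diff_next"]].to_numpy()
        assert np.allclose(vals[np.isfinite(vals)], 2.0)

    def test_simulated_catch_real_symmetry_soft_fields(self, small_noisy_cohort):
        # catch and real grip profiles are built identically, so where the
        # anticipatory bump is still far from force onset (the soft half of
        # the stiffness range) the neighbour differences centre on zero
        feats = gs.features_table(small_noisy_cohort)
        feats["stiff_group"] = np.where(feats["condition"] == "ascending",
                                        feats["mini_block"],
                                        8 - feats["mini_block"])
        diffs = []
        for (_, _), block in feats.groupby(["participant", "block"]):
            d = catch_neighbor_diffs(block)
            d = d.merge(feats[["participant", "block", "trial", "stiff_group"]],
                        on=["participant", "block", "trial"])
            d = d[d["stiff_group"] <= 3]
            diffs.extend(d["diff_prev"].dropna())
            diffs.extend(d["diff_next"].dropna())
        diffs = np.array(diffs)
        scale = np.abs(feats["gfr_at_onset"]).mean()
        assert len(diffs) >= 10
        assert abs(diffs.mean()) < 0.25 * scale


class TestFixtures:
    def test_no_movement_has_no_onset(self, fixtures_bundle):
        with pytest.raises(OnsetNotFoundError):
            extract_features(fixtures_bundle["no_movement"])

    def test_never_enters_field_has_no_impact(self, fixtures_bundle):
        with pytest.raises(ImpactNotFoundError):
            extract_features(fixtures_bundle["never_enters_field"])

    def test_double_peaked_grip_takes_first_local_peak(self, fixtures_bundle):
        s = fixtures_bundle["double_peaked_grip"]
        base = extract_features(
            next(x for x in fixtures_bundle["zero_noise"]
                 if x.meta.participant == s.meta.participant
                 and x.meta.block == s.meta.block
                 and x.meta.trial == s.meta.trial))
        feat = extract_features(s)
        # the injected earlier bump is picked as the first local maximum
        assert feat.t_gf_first_peak < base.t_gf_first_peak

    def test_features_table_skip_mode_counts_failures(self, fixtures_bundle):
        trials = [fixtures_bundle["no_movement"],
                  fixtures_bundle["never_enters_field"],
                  fixtures_bundle["zero_noise"][0]]
        df = gs.features_table(trials, on_error="skip")
        assert len(df) == 1 and df.attrs["n_failed"] == 2
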