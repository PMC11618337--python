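import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachkin.kinematics import (
    DerivativeStack,
    ExtractionOptions,
    FilterSpec,
    NoMovementError,
    count_zero_crossings,
    detect_onset,
    differentiate,
    extract_features,
    movement_units,
    summary_features,
)
from reachkin.trajectory_io import Group, Trial
from tests.conftest import build_reach_trial

NONE = ExtractionOptions(smoothing=FilterSpec(kind="none"))


def sign_scan_crossings(series):
    """Brute-force oracle: count sign alternations, zeros resolving to the
    next signed sample."""
    signs = [1 if v > 0 else -1 for v in series if v != 0]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def _const_trial(n=100, value=0.5):
    disp = np.tile([value, value, value], (n, 1))
    return Trial("s", Group.TD, 1, disp)


class TestDifferentiate:
    def test_constant_position_zero_derivatives(self):
        stack = differentiate(_const_trial(), FilterSpec(kind="none"))
        assert np.all(stack.velocity == 0.0)
        assert np.all(stack.acceleration == 0.0)
        assert np.all(stack.jerk == 0.0)

    def test_linear_position_exact_velocity(self):
        t = np.arange(200) / 100.0
        disp = np.column_stack([0.2 * t, np.zeros(200), np.zeros(200)])
        stack = differentiate(Trial("s", Group.TD, 1, disp), FilterSpec(kind="none"))
        np.testing.assert_allclose(stack.velocity[1:-1, 0], 0.2, atol=1e-9)
        np.testing.assert_allclose(stack.acceleration[2:-2, 0], 0.0, atol=1e-9)

    def test_sinusoid_acceleration_matches_analytic(self):
        t = np.arange(300) / 100.0
        disp = np.column_stack([np.sin(2 * np.pi * t), np.zeros(300), np.zeros(300)])
        stack = differentiate(Trial("s", Group.TD, 1, disp), FilterSpec(kind="none"))
        expected = -((2 * np.pi) ** 2) * np.sin(2 * np.pi * t)
        interior = slice(5, -5)
        np.testing.assert_allclose(
            stack.acceleration[interior, 0], expected[interior],
            rtol=1e-3, atol=1e-3 * (2 * np.pi) ** 2,
        )

    def test_short_trial_filter_error_advises_none(self):
        with pytest.raises(ValueError, match="none"):
            differentiate(_const_trial(n=12), FilterSpec())

    def test_series_lengths_match_input(self):
        trial, _ = build_reach_trial()
        stack = differentiate(trial)
        n = trial.n_samples
        assert stack.position.shape == (n, 3)
        assert stack.speed.shape == (n,)
        assert np.all(np.isfinite(stack.jerk))


class TestDetectOnset:
    def test_simultaneous_exceedance_without_refinement(self):
        # distance criterion first met at 50, acceleration at 40; the raw
        # trigger is the later of the two
        n = 100
        pos = np.zeros((n, 3))
        pos[50:, 0] = 0.5
        acc = np.zeros((n, 3))
        acc[40:, 0] = 1.0
        stack = DerivativeStack(
            position=pos, velocity=np.zeros((n, 3)), acceleration=acc,
            jerk=np.zeros((n, 3)), speed=np.zeros(n),
        )
        trial = _const_trial(n)
        assert detect_onset(trial, stack, refine=False) == 50

    def test_motionless_trial_raises(self):
        trial = _const_trial()
        stack = differentiate(trial, FilterSpec(kind="none"))
        with pytest.raises(NoMovementError):
            detect_onset(trial, stack)

    def test_reaction_time_on_noiseless_fixture(self, min_jerk_trial):
        trial, true_onset = min_jerk_trial
        stack = differentiate(trial, FilterSpec(kind="none"))
        onset = detect_onset(trial, stack)
        assert abs(onset - true_onset) <= 2
        rt = (onset - trial.go_signal_index) / trial.sampling_rate_hz
        assert rt == pytest.approx(0.30, abs=0.02)

    def test_onset_recovery_across_random_profiles(self, rng):
        errors = []
        for _ in range(50):
            trial, true_onset = build_reach_trial(
                amplitude=rng.uniform(0.1, 0.5),
                duration=rng.uniform(0.8, 2.5),
                reaction_time=rng.uniform(0.15, 0.5),
                time_to_peak_fraction=rng.uniform(0.3, 0.7),
            )
            stack = differentiate(trial, FilterSpec(kind="none"))
            errors.append(abs(detect_onset(trial, stack) - true_onset))
        assert max(errors) <= 2


class TestSummaryFeatures:
    def test_min_jerk_closed_forms(self, min_jerk_trial):
        trial, _ = min_jerk_trial
        stack = differentiate(trial, FilterSpec(kind="none"))
        onset = detect_onset(trial, stack)
        s = summary_features(trial, stack, onset)
        assert s["total_distance_m"] == pytest.approx(0.300, abs=0.003)
        assert s["max_velocity_mps"] == pytest.approx(0.5625, abs=0.006)
        assert s["time_to_peak_velocity_s"] == pytest.approx(0.50, abs=0.02)
        # A/T diluted slightly by the zero-speed boundary samples the
        # discrete window picks up
        assert s["avg_velocity_mps"] == pytest.approx(0.300, abs=0.008)
        assert s["max_acceleration_mps2"] == pytest.approx(10 / math.sqrt(3) * 0.3, rel=0.01)

    def test_overshoot_adds_path_length(self):
        from reachkin.synthetic_data import min_jerk_segment

        pre = np.zeros((80, 3))
        reach = min_jerk_segment(0.3, 1.0, np.array([1.0, 0, 0]), 100.0)
        out = min_jerk_segment(0.03, 0.4, np.array([1.0, 0, 0]), 100.0)
        back = min_jerk_segment(0.03, 0.4, np.array([-1.0, 0, 0]), 100.0)
        disp = np.vstack([pre, reach, out[1:] + reach[-1], back[1:] + reach[-1] + out[-1]])
        trial = Trial("s", Group.TD, 1, disp, go_signal_index=50)
        stack = differentiate(trial, FilterSpec(kind="none"))
        onset = detect_onset(trial, stack)
        s = summary_features(trial, stack, onset)
        assert s["total_distance_m"] == pytest.approx(0.360, abs=0.005)

    def test_window_too_short(self, min_jerk_trial):
        trial, _ = min_jerk_trial
        stack = differentiate(trial, FilterSpec(kind="none"))
        with pytest.raises(ValueError, match="window"):
            summary_features(trial, stack, trial.n_samples - 2)

    def test_invariants_on_random_trials(self, rng):
        for _ in range(10):
            trial, _ = build_reach_trial(
                amplitude=rng.uniform(0.1, 0.5), duration=rng.uniform(0.8, 2.0),
                noise_sd=1e-4, seed=int(rng.integers(1 << 31)), tail_s=0.3,
            )
            feats = extract_features(trial)
            d = feats.as_dict()
            assert all(v >= 0 for v in d.values())
            assert d["max_velocity_mps"] >= d["avg_velocity_mps"]
            assert d["max_acceleration_mps2"] >= d["avg_acceleration_mps2"]
            assert d["time_to_peak_velocity_s"] <= d["movement_time_s"]
            assert d["time_to_peak_acceleration_s"] <= d["movement_time_s"]


class TestZeroCrossings:
    def test_two_sign_changes(self):
        assert count_zero_crossings([1.0, -1.0, 1.0], hysteresis_fraction=0.0) == 2

    def test_excursion_inside_hysteresis_band(self):
        assert count_zero_crossings([1.0, -0.001, 1.0]) == 0

    def test_two_hz_sinusoid(self):
        t = np.arange(0.0, 3.0, 0.01)
        series = np.sin(4 * np.pi * t)
        assert count_zero_crossings(series) == 11
        assert sign_scan_crossings(series) == 11

    def test_exact_zero_resolves_to_next_signed_sample(self):
        assert count_zero_crossings([1.0, 0.0, 1.0], hysteresis_fraction=0.0) == 0
        assert count_zero_crossings([1.0, 0.0, -1.0], hysteresis_fraction=0.0) == 1

    def test_oracle_equivalence_random_signals(self, rng):
        for _ in range(200):
            series = rng.normal(0.0, 1.0, size=int(rng.integers(2, 120)))
            assert count_zero_crossings(series, 0.0) == sign_scan_crossings(series)

    @given(st.lists(st.floats(-100, 100, allow_nan=False), max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_property(self, series):
        assert count_zero_crossings(np.array(series), 0.0) == sign_scan_crossings(series)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            count_zero_crossings([1.0, np.nan])


class TestMovementUnits:
    @staticmethod
    def _stack_from_series(vel_x, acc_x, jerk_x, n):
        zeros = np.zeros((n, 3))
        vel = zeros.copy(); vel[:, 0] = vel_x
        acc = zeros.copy(); acc[:, 0] = acc_x
        jrk = zeros.copy(); jrk[:, 0] = jerk_x
        return DerivativeStack(position=zeros, velocity=vel, acceleration=acc,
                               jerk=jrk, speed=np.zeros(n))

    def test_rms_arithmetic(self):
        # per-axis counts (3, 4, 0) -> sqrt(25/3)
        x = np.array([1.0, -1.0, 1.0, -1.0])       # 3 crossings
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0])  # 4 crossings
        n = 5
        vel = np.zeros((n, 3))
        vel[:4, 0] = x
        vel[:, 1] = y
        stack = DerivativeStack(position=np.zeros((n, 3)), velocity=vel,
                                acceleration=np.zeros((n, 3)), jerk=np.zeros((n, 3)),
                                speed=np.zeros(n))
        mu1, mu2, mu3 = movement_units(stack, 0, n - 1, hysteresis_fraction=0.0)
        assert mu1 == pytest.approx(math.sqrt(25 / 3))
        assert mu2 == 0.0
        assert mu3 == 0.0

    def test_zero_counts(self):
        stack = self._stack_from_series(np.zeros(10), np.zeros(10), np.zeros(10), 10)
        assert movement_units(stack, 0, 9) == (0.0, 0.0, 0.0)

    def test_min_jerk_analytic_sign_pattern(self, min_jerk_trial):
        # velocity stays non-negative (no crossings); acceleration crosses
        # zero exactly once, at peak velocity
        trial, _ = min_jerk_trial
        stack = differentiate(trial, FilterSpec(kind="none"))
        onset = detect_onset(trial, stack)
        mu1, mu2, mu3 = movement_units(stack, onset, trial.n_samples - 1)
        assert mu1 == 0.0
        assert mu2 == pytest.approx(1 / math.sqrt(3))


class TestExtractFeatures:
    def test_all_fields_populated(self, min_jerk_trial):
        trial, _ = min_jerk_trial
        feats = extract_features(trial, NONE)
        d = feats.as_dict()
        assert len(d) == 12
        assert all(np.isfinite(v) for v in d.values())

    def test_rotation_invariance_of_scalar_features(self, rng):
        trial, _ = build_reach_trial(direction=(0.8, 0.36, 0.48), tail_s=0.2)
        base = extract_features(trial, NONE).as_dict()
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        rotated = Trial(
            trial.subject_id, trial.group, trial.trial_index,
            trial.displacement @ q.T, trial.sampling_rate_hz, trial.go_signal_index,
        )
        rot = extract_features(rotated, NONE).as_dict()
        for key, val in base.items():
            if key.startswith("mu_"):
                continue  # per-axis counts are frame-dependent by construction
            assert rot[key] == pytest.approx(val, rel=1e-6, abs=1e-9), key

    def test_group_profile_contrast_matched_seeds(self):
        from reachkin.synthetic_data import DEFAULT_PROFILES, compose_trial

        means = {}
        for group in (Group.TD, Group.ASD):
            rng = np.random.default_rng(2024)
            rows = []
            for _ in range(60):
                trial, _ = compose_trial(DEFAULT_PROFILES[group], rng)
                rows.append(extract_features(trial).as_array())
            means[group] = np.mean(rows, axis=0)
        from reachkin.kinematics import FEATURE_NAMES

        larger_in_asd = [
            "total_distance_m", "avg_velocity_mps", "max_velocity_mps",
            "avg_acceleration_mps2", "max_acceleration_mps2",
            "time_to_peak_velocity_s", "time_to_peak_acceleration_s",
            "mu_type2_rms",
        ]
        for name in larger_in_asd:
            i = FEATURE_NAMES.index(name)
            assert means[Group.ASD][i] > means[Group.TD][i], name

    def test_no_movement_propagates(self):
        trial = _const_trial()
        with pytest.raises(NoMovementError):
            extract_features(trial, NONE)
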