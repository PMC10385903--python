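"""Synthetic trial generator: trajectories, redundancy inversion, sEMG synthesis."""

from dataclasses import replace

import numpy as np
import pytest

from ankledyn.errors import InfeasibleTrialError
from ankledyn.forward import forward_ankle_moment
from ankledyn.inverse import inverse_ankle_moment
from ankledyn.subject import MUSCLE_NAMES, scale_subject
from ankledyn.synthetic import (
    MeasurementNoise,
    TrialSpec,
    generate_trajectories,
    generate_trial,
    minimum_jerk,
    required_activations,
    synthesize_emg,
)
from ankledyn.timeseries import resample_to


class TestTrajectories:
    def test_minimum_jerk_boundary_conditions(self):
        for u in (0.0, 1.0):
            s, ds, d2s = minimum_jerk(u)
            assert s == u and ds == 0.0 and d2s == 0.0
        s, _, _ = minimum_jerk(0.5)
        assert s == pytest.approx(0.5)

    def test_starts_and_ends_at_rest(self, subject):
        kin = generate_trajectories(TrialSpec(), subject)
        assert np.allclose(kin.velocities[0], 0.0)
        assert np.allclose(kin.accelerations[0], 0.0)
        assert np.allclose(kin.velocities[-1], 0.0, atol=1e-9)

    def test_hip_leads_knee_leads_ankle(self, subject):
        kin = generate_trajectories(TrialSpec(), subject)
        def onset(j):
            moving = np.abs(kin.velocities[:, j]) > 1e-9
            return kin.times[np.argmax(moving)]
        assert onset(2) < onset(1) < onset(0)  # HAT, thigh, shank

    def test_chair_force_consistency(self, subject):
        spec = TrialSpec()
        kin = generate_trajectories(spec, subject)
        assert kin.chair_force[0] <= subject.total_weight
        after = kin.times >= spec.seat_off_time
        assert np.all(kin.chair_force[after] == 0.0)
        before = kin.chair_force[~after]
        assert np.all(np.diff(before) <= 1e-12)  # monotone decay


class TestRequiredActivations:
    def test_zero_moment_demand_gives_near_zero_activations(self, subject):
        # static upright stance off the chair: the demanded moment and the
        # passive contributions are both (nearly) zero at reference posture
        n = 200
        t = np.arange(n) / 100.0
        from ankledyn.timeseries import KinematicState

        kin = KinematicState(
            times=t, angles=np.full((n, 3), np.pi / 2),
            velocities=np.zeros((n, 3)), accelerations=np.zeros((n, 3)),
            chair_force=np.zeros(n),
        )
        acts, _, clipped = required_activations(kin, subject, floor=0.0)
        assert not clipped
        for name in MUSCLE_NAMES:
            assert np.all(acts[name].values < 0.02)

    def test_round_trip_reproduces_target_moment(self, subject):
        """Feeding generated activations through the forward path recovers the
        inverse-dynamics target within 2 % RMS (noise-free)."""
        spec = TrialSpec(seed=5)
        kin = generate_trajectories(spec, subject)
        acts, _, clipped = required_activations(kin, subject, floor=spec.co_activation_floor)
        assert not clipped
        fwd = forward_ankle_moment(acts, kin, subject)
        target = resample_to(inverse_ankle_moment(kin, subject), fwd.times)
        rel = np.sqrt(np.mean((fwd.values - target.values) ** 2))
        rel /= np.sqrt(np.mean(target.values**2))
        assert rel < 0.02

    def test_default_spec_is_feasible_without_clipping(self, subject):
        kin = generate_trajectories(TrialSpec(), subject)
        _, _, clipped = required_activations(kin, subject, floor=0.05)
        assert not clipped

    def test_weak_muscles_make_the_trial_infeasible(self, subject):
        # a 4x heavier body with unscaled stature demands more plantarflexion
        # moment than the (mass-scaled-back) muscles can deliver
        heavy = scale_subject(subject, subject.body_mass * 4, subject.height)
        weak_muscles = {
            name: replace(m, peak_force=m.peak_force / 40)
            for name, m in heavy.muscles.items()
        }
        from dataclasses import replace as dc_replace

        weak = dc_replace(heavy, muscles=weak_muscles)
        kin = generate_trajectories(TrialSpec(), weak)
        with pytest.raises(InfeasibleTrialError):
            required_activations(kin, weak, floor=0.05)


class TestSynthesizeEmg:
    def test_zero_activation_gives_silent_channel(self, subject):
        spec = TrialSpec(seed=1)
        kin = generate_trajectories(spec, subject)
        acts, _, _ = required_activations(kin, subject, floor=0.0)
        zeroed = {
            name: replace(a, values=np.zeros_like(a.values))
            for name, a in acts.items()
        }
        rng = np.random.default_rng(0)
        channels = synthesize_emg(zeroed, dict(subject.rms_mvc), spec, rng)
        assert np.all(channels["soleus"].samples == 0.0)

    def test_full_activation_rms_converges_to_mvc(self, subject):
        from ankledyn.emg import windowed_rms

        spec = replace(
            TrialSpec(seed=9), duration=10.0, seat_off_time=4.0,
            measurement_noise=MeasurementNoise.zero(),
        )
        kin = generate_trajectories(spec, subject)
        acts, _, _ = required_activations(kin, subject, floor=0.0)
        saturated = {
            name: replace(a, values=np.ones_like(a.values))
            for name, a in acts.items()
        }
        rng = np.random.default_rng(4)
        channels = synthesize_emg(saturated, dict(subject.rms_mvc), spec, rng)
        _, rms = windowed_rms(channels["tib_ant"])
        mvc = subject.rms_mvc["tib_ant"]
        n_windows = rms.size
        tol = 3 / np.sqrt(2 * 50 * n_windows)
        assert abs(np.mean(rms) / mvc - 1.0) < tol

    def test_same_seed_bit_identical(self, subject):
        spec = TrialSpec(seed=33)
        kin = generate_trajectories(spec, subject)
        acts, _, _ = required_activations(kin, subject, floor=0.05)
        a = synthesize_emg(acts, dict(subject.rms_mvc), spec, np.random.default_rng(8))
        b = synthesize_emg(acts, dict(subject.rms_mvc), spec, np.random.default_rng(8))
        for name in MUSCLE_NAMES:
            assert np.array_equal(a[name].samples, b[name].samples)


class TestGenerateTrial:
    def test_reproducibility_bit_identical(self, subject):
        t1 = generate_trial(TrialSpec(seed=21), subject)
        t2 = generate_trial(TrialSpec(seed=21), subject)
        for name in MUSCLE_NAMES:
            assert np.array_equal(t1.emg[name].samples, t2.emg[name].samples)
        assert np.array_equal(t1.kinematics.angles, t2.kinematics.angles)
        assert np.array_equal(t1.kinematics.chair_force, t2.kinematics.chair_force)
        assert np.array_equal(
            t1.ground_truth.moment.values, t2.ground_truth.moment.values
        )

    def test_seeds_change_noise_but_not_ground_truth(self, subject):
        t1 = generate_trial(TrialSpec(seed=1), subject)
        t2 = generate_trial(TrialSpec(seed=2), subject)
        assert not np.array_equal(t1.emg["soleus"].samples, t2.emg["soleus"].samples)
        assert np.array_equal(
            t1.ground_truth.moment.values, t2.ground_truth.moment.values
        )

    def test_stream_shapes_and_ranges(self, subject):
        spec = TrialSpec(seed=3)
        trial = generate_trial(spec, subject)
        assert trial.emg["tib_ant"].samples.size == int(spec.duration * 1000)
        assert trial.kinematics.times.size == int(spec.duration * 100)
        for name in MUSCLE_NAMES:
            a = trial.ground_truth.activations[name].values
            assert np.all((a >= 0) & (a <= 1))
        assert not trial.ground_truth.clipped

    def test_noisy_activation_recovery_within_sampling_error(self, subject):
        """The estimator's activations track ground truth within the windowed
        RMS sampling error (3/sqrt(2N) relative, N = 50 samples/window)."""
        from ankledyn.emg import emg_to_activation

        trial = generate_trial(TrialSpec(seed=12), subject)
        truth = trial.ground_truth.activations
        for name in MUSCLE_NAMES:
            est = emg_to_activation(
                trial.emg[name], subject.rms_mvc[name],
                band=trial.spec.emg_noise_band,
            )
            rel = np.sqrt(np.mean((est.values - truth[name].values) ** 2
                                  / truth[name].values ** 2))
            assert rel <= 3 / np.sqrt(2 * 50)
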