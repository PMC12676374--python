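"""Tests for the synthetic arm: dynamics, clip generation, raw EMG."""

import numpy as np
import pytest

from myoreach.arm import (
    ELBOW_FLEXOR,
    ArmParams,
    ArmState,
    BurstSpec,
    ReferenceClip,
    fk_endpoint,
    generate_dataset,
    generate_reach_clip,
    step_dynamics,
    synthesize_raw_emg,
)
from myoreach.emg import block_downsample, envelope


def test_equilibrium_at_rest(arm_params):
    """Zero excitation from rest leaves the state unchanged (no gravity)."""
    state = ArmState.rest(arm_params)
    nxt = step_dynamics(state, np.zeros(arm_params.n_muscles), arm_params)
    np.testing.assert_allclose(nxt.q, state.q)
    np.testing.assert_allclose(nxt.v, state.v)
    np.testing.assert_allclose(nxt.a, state.a)


def test_kinetic_energy_decays_under_damping(arm_params):
    """With zero excitation and damping, kinetic energy strictly decreases."""
    state = ArmState.rest(arm_params)
    state.v = np.array([2.0, -3.0])
    inertia = arm_params.inertias
    energies = []
    for _ in range(50):
        energies.append(0.5 * float(inertia @ state.v**2))
        state = step_dynamics(state, np.zeros(arm_params.n_muscles), arm_params)
    energies = np.array(energies)
    assert np.all(np.diff(energies) < 0)


def test_flexor_excitation_raises_elbow_until_limit(arm_params):
    """Constant elbow-flexor drive monotonically increases the elbow angle."""
    state = ArmState.rest(arm_params)
    u = np.zeros(arm_params.n_muscles)
    u[ELBOW_FLEXOR] = 1.0
    elbows = [state.q[1]]
    for _ in range(3000):
        state = step_dynamics(state, u, arm_params)
        elbows.append(state.q[1])
    elbows = np.array(elbows)
    hi = arm_params.joint_limits[1][1]
    at_limit = np.isclose(elbows, hi)
    rising = np.diff(elbows) > 0
    # strictly increasing until the limit is reached, then pinned there
    assert np.all(rising[: np.argmax(at_limit) - 1])
    assert at_limit[-1]


def test_step_rejects_bad_input(arm_params):
    state = ArmState.rest(arm_params)
    with pytest.raises(ValueError, match="n_muscles"):
        step_dynamics(state, np.zeros(3), arm_params)
    with pytest.raises(ValueError, match="non-finite"):
        step_dynamics(state, np.full(arm_params.n_muscles, np.nan), arm_params)


def test_fmax_range_enforced():
    with pytest.raises(ValueError, match=r"\[0.2, 1.2\]"):
        ArmParams(f_max=np.array([0.9, 0.7, 1.5, 0.8, 0.5, 0.6]))


def test_antagonist_pairs_required():
    one_sided = np.abs(ArmParams().moment_arms)
    with pytest.raises(ValueError, match="antagonist"):
        ArmParams(moment_arms=one_sided)


def test_zero_bursts_give_constant_clip(arm_params):
    spec = BurstSpec(muscle=(0,), amplitude=(0.0,), center=(0.1,), width=(0.02,))
    clip, _ = generate_reach_clip(arm_params, spec, seed=0)
    np.testing.assert_allclose(clip.qhat,
                               np.tile(arm_params.q_rest, (60, 1)))


def test_reach_clip_deterministic_and_moves(arm_params):
    clip1, ro1 = generate_reach_clip(arm_params, seed=7)
    clip2, _ = generate_reach_clip(arm_params, seed=7)
    np.testing.assert_array_equal(clip1.qhat, clip2.qhat)
    start = fk_endpoint(arm_params.q_rest, arm_params)
    end = fk_endpoint(clip1.qhat[-1], arm_params)
    assert np.linalg.norm(end - start) > 0.0
    # velocity consistency: semi-implicit Euler makes diff(q)/dt == v exactly
    dq = np.diff(ro1.q, axis=0) / ro1.dt
    np.testing.assert_allclose(dq, ro1.v[1:], atol=1e-6)


def test_burst_outside_unit_interval_rejected(arm_params):
    spec = BurstSpec(muscle=(0, 0), amplitude=(0.8, 0.8),
                     center=(0.1, 0.1), width=(0.02, 0.02))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        generate_reach_clip(arm_params, spec, seed=0)


def test_dataset_shapes_and_determinism(arm_params):
    clips, _, manifest = generate_dataset(arm_params, n_clips=5, seed=3)
    assert len(clips) == 5
    assert all(c.n_frames == 60 for c in clips)
    assert len(manifest["clips"]) == 5
    clips2, _, _ = generate_dataset(arm_params, n_clips=5, seed=3)
    for a, b in zip(clips, clips2):
        np.testing.assert_array_equal(a.qhat, b.qhat)
    # different master seeds -> distinct data, equal shapes
    clips3, _, _ = generate_dataset(arm_params, n_clips=5, seed=4)
    assert clips3[0].qhat.shape == clips[0].qhat.shape
    assert not np.array_equal(clips3[0].qhat, clips[0].qhat)


def test_zero_jitter_clips_identical(arm_params):
    clips, _, _ = generate_dataset(arm_params, n_clips=3, jitter=0.0, seed=0)
    np.testing.assert_array_equal(clips[0].qhat, clips[1].qhat)
    np.testing.assert_array_equal(clips[1].qhat, clips[2].qhat)


def test_clip_duration_consistency_checked():
    with pytest.raises(ValueError, match="duration"):
        ReferenceClip("bad", np.zeros((30, 2)), dt=1 / 200, duration=0.3)


def test_raw_emg_zero_activation_silent():
    out = synthesize_raw_emg(np.zeros(60), snr=None, seed=0)
    np.testing.assert_array_equal(out, 0.0)


def test_raw_emg_std_scales_with_activation():
    """Signal RMS grows proportionally with a constant activation level."""
    stds = []
    for c in (0.2, 0.4, 0.8):
        reps = [
            synthesize_raw_emg(np.full(60, c), snr=None, seed=s).std()
            for s in range(5)
        ]
        stds.append(np.mean(reps))
    ratios = np.array(stds) / stds[0]
    np.testing.assert_allclose(ratios, [1.0, 2.0, 4.0], rtol=0.05)


def test_raw_emg_rejects_bad_rates_and_snr():
    with pytest.raises(ValueError, match="2000"):
        synthesize_raw_emg(np.zeros(10), fs=1000.0)
    with pytest.raises(ValueError, match="snr"):
        synthesize_raw_emg(np.zeros(10), snr=-1.0)


def test_envelope_recovery_single_channel(arm_params):
    """Processing a synthetic channel recovers its generating activation."""
    clip, _ = generate_reach_clip(arm_params, seed=2)
    act = clip.true_activations[:, ELBOW_FLEXOR]
    raw = synthesize_raw_emg(act, snr=10.0, seed=11)
    env = block_downsample(envelope(raw, 30000.0), 30000.0, 200.0)[:60]
    r = np.corrcoef(env, act)[0, 1]
    assert r >= 0.9
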