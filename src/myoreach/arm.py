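"""Planar two-link muscle-driven arm and synthetic data generation.

A desk-scale stand-in for a musculoskeletal forelimb model: two revolute
joints (shoulder, elbow) driven by six Hill-like muscle actuators
(mono-articular flexor/extensor per joint plus a biarticular pair). The
generator forward-simulates triphasic excitation bursts to produce
dynamically consistent reference reach clips with known ground-truth muscle
activations, and can synthesize raw surface-EMG-like signals from those
activations for testing the processing chain.

Muscle force is activation x maximum isometric force, with first-order
activation dynamics; joint torques come from a signed moment-arm matrix.
The mass matrix is diagonal with constant per-joint effective inertias, so
semi-implicit Euler integration is exactly passive under damping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "ArmParams",
    "ArmState",
    "ReferenceClip",
    "Rollout",
    "RawEMGRecording",
    "BurstSpec",
    "default_reach_bursts",
    "step_dynamics",
    "generate_reach_clip",
    "generate_dataset",
    "synthesize_raw_emg",
    "fk_endpoint",
    "MUSCLE_NAMES",
]

#: canonical muscle ordering for the default 2-joint / 6-muscle arm
MUSCLE_NAMES = (
    "shoulder_flexor",
    "shoulder_extensor",
    "elbow_flexor",      # biceps analogue
    "elbow_extensor",    # triceps analogue
    "biarticular_flexor",
    "biarticular_extensor",
)

ELBOW_FLEXOR = MUSCLE_NAMES.index("elbow_flexor")
ELBOW_EXTENSOR = MUSCLE_NAMES.index("elbow_extensor")


def _default_moment_arms() -> np.ndarray:
    # rows: (shoulder, elbow); columns follow MUSCLE_NAMES; metres, signed
    r, rb = 0.003, 0.002
    return np.array(
        [
            [+r, -r, 0.0, 0.0, +rb, -rb],
            [0.0, 0.0, +r, -r, +rb, -rb],
        ]
    )


@dataclass(frozen=True)
class ArmParams:
    """Physical parameters of the planar two-link arm.

    Default scale is a mouse forelimb: ~2 cm links, gram-scale masses,
    maximum muscle forces inside 0.2-1.2 N.
    """

    link_lengths: tuple[float, float] = (0.022, 0.025)   # m
    link_masses: tuple[float, float] = (0.005, 0.003)    # kg
    joint_damping: tuple[float, float] = (4e-4, 2.5e-4)  # N*m*s/rad
    joint_limits: tuple[tuple[float, float], ...] = ((-1.0, 2.0), (0.1, 2.8))
    n_muscles: int = 6
    moment_arms: np.ndarray = field(default_factory=_default_moment_arms)
    f_max: np.ndarray = field(
        default_factory=lambda: np.array([0.9, 0.7, 1.1, 0.8, 0.5, 0.6])
    )  # N, each within 0.2-1.2
    tau_act: float = 0.01   # s, activation time constant
    dt_phys: float = 1e-3   # s, physics step
    gravity: float = 0.0    # m/s^2; off by default (horizontal-plane reach)
    rest_posture: tuple[float, float] = (0.3, 1.2)  # rad

    def __post_init__(self) -> None:
        ma = np.asarray(self.moment_arms, dtype=float)
        fm = np.asarray(self.f_max, dtype=float)
        object.__setattr__(self, "moment_arms", ma)
        object.__setattr__(self, "f_max", fm)
        if self.dt_phys <= 0:
            raise ValueError("dt_phys must be positive")
        if self.tau_act <= 0:
            raise ValueError("tau_act must be positive")
        if ma.shape != (self.n_joints, self.n_muscles):
            raise ValueError(
                f"moment_arms shape {ma.shape} != "
                f"({self.n_joints}, {self.n_muscles})"
            )
        if fm.shape != (self.n_muscles,):
            raise ValueError("f_max must have one entry per muscle")
        if np.any(fm < 0.2) or np.any(fm > 1.2):
            raise ValueError("f_max values must lie in [0.2, 1.2] N")
        for j in range(self.n_joints):
            row = ma[j]
            if not (np.any(row > 0) and np.any(row < 0)):
                raise ValueError(
                    f"joint {j} lacks an antagonist pair (moment-arm signs)"
                )

    @property
    def n_joints(self) -> int:
        return len(self.link_lengths)

    @property
    def inertias(self) -> np.ndarray:
        """Constant per-joint effective inertias (kg*m^2), rod model."""
        m1, m2 = self.link_masses
        l1, l2 = self.link_lengths
        i_shoulder = m1 * l1**2 / 3.0 + m2 * (l1**2 + l2**2 / 3.0)
        i_elbow = m2 * l2**2 / 3.0
        return np.array([i_shoulder, i_elbow])

    @property
    def q_rest(self) -> np.ndarray:
        return np.asarray(self.rest_posture, dtype=float)

    @property
    def limits_lo(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.joint_limits])

    @property
    def limits_hi(self) -> np.ndarray:
        return np.array([hi for _, hi in self.joint_limits])


@dataclass
class ArmState:
    """Instantaneous arm state: joint angles, velocities, muscle activations."""

    q: np.ndarray  # (n_joints,) rad
    v: np.ndarray  # (n_joints,) rad/s
    a: np.ndarray  # (n_muscles,) in [0, 1]

    @classmethod
    def rest(cls, params: ArmParams) -> "ArmState":
        return cls(
            q=params.q_rest.copy(),
            v=np.zeros(params.n_joints),
            a=np.zeros(params.n_muscles),
        )


@dataclass
class ReferenceClip:
    """One trial's reference joint trajectory, the imitation target.

    ``true_activations`` is present for generated clips (ground truth known)
    and ``None`` for externally supplied kinematics.
    """

    clip_id: str
    qhat: np.ndarray          # (T, n_joints) rad
    dt: float                 # s between frames
    duration: float = 0.3     # s
    true_activations: np.ndarray | None = None  # (T, n_muscles)

    def __post_init__(self) -> None:
        self.qhat = np.asarray(self.qhat, dtype=float)
        if not np.all(np.isfinite(self.qhat)):
            raise ValueError(f"clip {self.clip_id}: non-finite qhat")
        if abs(len(self.qhat) * self.dt - self.duration) > self.dt:
            raise ValueError(
                f"clip {self.clip_id}: T*dt = {len(self.qhat) * self.dt:.4f}"
                f" inconsistent with duration {self.duration}"
            )

    @property
    def n_frames(self) -> int:
        return self.qhat.shape[0]


@dataclass
class Rollout:
    """Trajectory produced by forward simulation or by a policy.

    ``dt`` is the sampling interval of the stored arrays: physics rate for
    generator rollouts, control rate for policy rollouts.
    """

    clip_id: str
    q: np.ndarray                # (T, n_joints)
    v: np.ndarray                # (T, n_joints)
    actions: np.ndarray          # (T, n_muscles) in [0, 1]
    forces: np.ndarray           # (T, n_muscles) N, a * f_max
    dt: float
    reward_terms: dict[str, np.ndarray] | None = None
    intention_means: np.ndarray | None = None      # (T, latent_dim)
    layer_activations: dict[str, np.ndarray] | None = None


@dataclass
class RawEMGRecording:
    """Multichannel raw EMG-like signal with trial onset indices."""

    fs: float
    channels: list[str]
    signal: np.ndarray        # (n_samples, n_channels)
    trial_onsets: np.ndarray  # sample indices of reach starts

    def __post_init__(self) -> None:
        if self.fs < 2000:
            raise ValueError(
                f"fs = {self.fs} Hz too low: band-pass edge 1000 Hz "
                "must sit below Nyquist"
            )
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] < self.signal.shape[1]:
            raise ValueError("signal must be (n_samples, n_channels)")
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _gravity_torque(q: np.ndarray, params: ArmParams) -> np.ndarray:
    """Gravity torque for a vertical-plane arm; zero when gravity is off."""
    if params.gravity == 0.0:
        return np.zeros_like(q)
    g = params.gravity
    m1, m2 = params.link_masses
    l1, l2 = params.link_lengths
    q1 = q[..., 0]
    q12 = q[..., 0] + q[..., 1]
    t1 = -g * ((m1 * l1 / 2 + m2 * l1) * np.cos(q1) + m2 * l2 / 2 * np.cos(q12))
    t2 = -g * (m2 * l2 / 2 * np.cos(q12))
    return np.stack([t1, t2], axis=-1)


def step_dynamics_batch(
    q: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    excitation: np.ndarray,
    params: ArmParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Advance a batch of arm states one physics step (semi-implicit Euler).

    Arrays are (..., n_joints) / (..., n_muscles); broadcasting over leading
    dimensions vectorizes the parallel training environments. Returns
    ``(q, v, a, forces)`` after the step.
    """
    dt = params.dt_phys
    # first-order activation dynamics, exact exponential update
    decay = np.exp(-dt / params.tau_act)
    a_new = np.clip(excitation + (a - excitation) * decay, 0.0, 1.0)
    forces = a_new * params.f_max  # (..., n_muscles)
    torque = forces @ params.moment_arms.T  # (..., n_joints)
    torque = torque + _gravity_torque(q, params)
    damping = np.asarray(params.joint_damping)
    inertia = params.inertias
    acc = (torque - damping * v) / inertia
    v_new = v + dt * acc
    q_new = q + dt * v_new
    # joint limits: clamp with velocity zeroing at the limit
    lo, hi = params.limits_lo, params.limits_hi
    at_lo = q_new < lo
    at_hi = q_new > hi
    q_new = np.clip(q_new, lo, hi)
    v_new = np.where(at_lo | at_hi, 0.0, v_new)
    return q_new, v_new, a_new, forces


def step_dynamics(
    state: ArmState, excitation: np.ndarray, params: ArmParams
) -> ArmState:
    """Advance a single arm state one physics step.

    Raises ``ValueError`` on non-finite state or excitation, or on an
    excitation vector of the wrong length.
    """
    excitation = np.asarray(excitation, dtype=float)
    if excitation.shape != (params.n_muscles,):
        raise ValueError(
            f"excitation length {excitation.shape} != n_muscles "
            f"({params.n_muscles})"
        )
    if not (
        np.all(np.isfinite(excitation))
        and np.all(np.isfinite(state.q))
        and np.all(np.isfinite(state.v))
        and np.all(np.isfinite(state.a))
    ):
        raise ValueError("non-finite state or excitation")
    q, v, a, _ = step_dynamics_batch(state.q, state.v, state.a, excitation, params)
    return ArmState(q=q, v=v, a=a)


def fk_endpoint(q: np.ndarray, params: ArmParams) -> np.ndarray:
    """Forward kinematics: planar hand endpoint position(s) for angles q."""
    l1, l2 = params.link_lengths
    q = np.asarray(q)
    x = l1 * np.cos(q[..., 0]) + l2 * np.cos(q[..., 0] + q[..., 1])
    y = l1 * np.sin(q[..., 0]) + l2 * np.sin(q[..., 0] + q[..., 1])
    return np.stack([x, y], axis=-1)


# ---------------------------------------------------------------------------
# reach generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstSpec:
    """Gaussian excitation bursts: one row per burst.

    Each burst is ``amplitude * exp(-(t - center)^2 / (2 width^2))`` applied
    to one muscle; bursts targeting the same muscle sum and the result is
    required to stay in [0, 1].
    """

    muscle: tuple[int, ...]
    amplitude: tuple[float, ...]
    center: tuple[float, ...]   # s
    width: tuple[float, ...]    # s

    def excitations(self, t: np.ndarray, n_muscles: int) -> np.ndarray:
        """Excitation matrix (len(t), n_muscles); raises if outside [0, 1]."""
        u = np.zeros((len(t), n_muscles))
        for m, amp, c, w in zip(self.muscle, self.amplitude, self.center, self.width):
            u[:, m] += amp * np.exp(-0.5 * ((t - c) / w) ** 2)
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError(
                f"burst excitations leave [0, 1] (max {u.max():.3f}, "
                f"min {u.min():.3f})"
            )
        return u


def default_reach_bursts() -> BurstSpec:
    """Triphasic reach: agonist burst, antagonist brake, agonist clamp.

    Flexion of shoulder and elbow drives the hand forward; the antagonist
    burst decelerates it; a second agonist burst holds the final posture.
    """
    return BurstSpec(
        muscle=(ELBOW_FLEXOR, 0, ELBOW_EXTENSOR, 1, ELBOW_FLEXOR, 0),
        amplitude=(0.55, 0.45, 0.40, 0.30, 0.30, 0.22),
        center=(0.06, 0.06, 0.16, 0.16, 0.25, 0.25),
        width=(0.025, 0.025, 0.022, 0.022, 0.025, 0.025),
    )


def _jittered_bursts(
    base: BurstSpec, jitter: float, rng: np.random.Generator
) -> BurstSpec:
    """Multiplicative amplitude jitter and additive timing jitter."""
    amp = np.array(base.amplitude)
    cen = np.array(base.center)
    amp = np.clip(amp * (1.0 + jitter * rng.uniform(-1, 1, amp.shape)), 0.0, 0.95)
    cen = np.clip(cen + 0.05 * jitter * rng.uniform(-1, 1, cen.shape), 0.005, 0.29)
    return replace(base, amplitude=tuple(amp), center=tuple(cen))


def generate_reach_clip(
    params: ArmParams,
    burst_spec: BurstSpec | None = None,
    seed: int = 0,
    duration: float = 0.3,
    frame_rate: float = 200.0,
    clip_id: str = "clip_000",
) -> tuple[ReferenceClip, Rollout]:
    """Forward-simulate a reach and return it as a reference clip + rollout.

    The reference kinematics are the simulated trajectory itself, so the
    imitation target is guaranteed dynamically feasible and the ground-truth
    activations are known exactly. Deterministic given ``seed`` (the seed
    only matters when ``burst_spec`` is None and defaults are used verbatim;
    jitter is applied by :func:`generate_dataset`).
    """
    if burst_spec is None:
        burst_spec = default_reach_bursts()
    dt = params.dt_phys
    n_steps = int(round(duration / dt))
    t_phys = np.arange(n_steps) * dt
    u = burst_spec.excitations(t_phys, params.n_muscles)

    q = params.q_rest.copy()
    v = np.zeros(params.n_joints)
    a = np.zeros(params.n_muscles)
    qs = np.empty((n_steps, params.n_joints))
    vs = np.empty((n_steps, params.n_joints))
    acts = np.empty((n_steps, params.n_muscles))
    fs = np.empty((n_steps, params.n_muscles))
    for i in range(n_steps):
        q, v, a, f = step_dynamics_batch(q, v, a, u[i], params)
        qs[i], vs[i], acts[i], fs[i] = q, v, a, f

    rollout = Rollout(
        clip_id=clip_id, q=qs, v=vs, actions=u, forces=fs, dt=dt
    )
    # downsample to the clip frame rate (200 Hz default -> T = 60)
    stride = int(round(1.0 / (frame_rate * dt)))
    qhat = qs[stride - 1 :: stride]
    a_frames = acts[stride - 1 :: stride]
    clip = ReferenceClip(
        clip_id=clip_id,
        qhat=qhat,
        dt=1.0 / frame_rate,
        duration=duration,
        true_activations=a_frames,
    )
    return clip, rollout


def generate_dataset(
    params: ArmParams,
    n_clips: int = 46,
    jitter: float = 0.15,
    seed: int = 0,
    duration: float = 0.3,
    frame_rate: float = 200.0,
) -> tuple[list[ReferenceClip], list[Rollout], dict]:
    """Generate a dataset of jittered reach clips with a provenance manifest.

    Per-clip seeds derive from the master seed through ``SeedSequence``; the
    whole dataset is a pure function of ``(params, n_clips, jitter, seed)``.
    """
    if n_clips < 1:
        raise ValueError("n_clips must be >= 1")
    base = default_reach_bursts()
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_clips)
    clips: list[ReferenceClip] = []
    rollouts: list[Rollout] = []
    manifest: dict = {"master_seed": seed, "jitter": jitter, "clips": []}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        spec = _jittered_bursts(base, jitter, rng) if jitter > 0 else base
        cid = f"clip_{i:03d}"
        clip, ro = generate_reach_clip(
            params, spec, seed=i, duration=duration,
            frame_rate=frame_rate, clip_id=cid,
        )
        clips.append(clip)
        rollouts.append(ro)
        manifest["clips"].append(
            {"clip_id": cid, "seed_entropy": int(child.entropy if isinstance(child.entropy, int) else 0),
             "amplitudes": list(spec.amplitude), "centers": list(spec.center)}
        )
    return clips, rollouts, manifest


# ---------------------------------------------------------------------------
# synthetic raw EMG
# ---------------------------------------------------------------------------


def synthesize_raw_emg(
    activation: np.ndarray,
    clip_rate: float = 200.0,
    fs: float = 30000.0,
    snr: float | None = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize one channel of raw EMG-like signal from an activation trace.

    The activation (sampled at ``clip_rate``) is linearly upsampled to ``fs``
    and multiplies a 20-1000 Hz band-limited unit-variance noise carrier;
    broadband baseline noise is added with standard deviation set so that the
    modulated-signal RMS over baseline RMS equals ``snr`` (``None`` disables
    baseline noise). Deterministic given ``seed``.
    """
    activation = np.asarray(activation, dtype=float)
    if np.any(activation < 0) or np.any(activation > 1):
        raise ValueError("activation must lie in [0, 1]")
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    if fs < 2000:
        raise ValueError("fs must be >= 2000 Hz (band-pass edge at 1000 Hz)")
    n_in = len(activation)
    n_out = int(round(n_in * fs / clip_rate))
    t_in = np.arange(n_in) / clip_rate
    t_out = np.arange(n_out) / fs
    env = np.interp(t_out, t_in, activation)

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_out)
    sos = _sig.butter(4, [20.0, 1000.0], btype="bandpass", fs=fs, output="sos")
    carrier = _sig.sosfiltfilt(sos, white)
    std = carrier.std()
    if std > 0:
        carrier = carrier / std
    out = env * carrier
    if snr is not None:
        sig_rms = np.sqrt(np.mean(out**2))
        noise_std = sig_rms / snr if sig_rms > 0 else 0.0
        out = out + noise_std * rng.standard_normal(n_out)
    return out


def synthesize_recording(
    clips: list[ReferenceClip],
    channel_muscles: dict[str, int] | None = None,
    fs: float = 30000.0,
    snr: float | None = 10.0,
    seed: int = 0,
    gap: float = 0.1,
) -> RawEMGRecording:
    """Concatenate per-clip synthetic EMG into one continuous recording.

    Trials are separated by ``gap`` seconds of baseline; ``trial_onsets``
    marks each reach start. Channels default to the biceps/triceps analogues.
    """
    if channel_muscles is None:
        channel_muscles = {"biceps": ELBOW_FLEXOR, "triceps": ELBOW_EXTENSOR}
    names = list(channel_muscles)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(clips) * len(names))

    gap_n = int(round(gap * fs))
    pieces: list[np.ndarray] = []
    onsets: list[int] = []
    pos = gap_n
    for ci, clip in enumerate(clips):
        if clip.true_activations is None:
            raise ValueError(f"clip {clip.clip_id} has no ground-truth activations")
        chans = []
        for ni, name in enumerate(names):
            act = clip.true_activations[:, channel_muscles[name]]
            raw = synthesize_raw_emg(
                act, clip_rate=1.0 / clip.dt, fs=fs, snr=snr,
                seed=int(child_seeds[ci * len(names) + ni]),
            )
            chans.append(raw)
        pieces.append(np.stack(chans, axis=1))
        onsets.append(pos)
        pos += pieces[-1].shape[0] + gap_n
    n_total = pos
    signal = np.zeros((n_total, len(names)))
    for onset, piece in zip(onsets, pieces):
        signal[onset : onset + piece.shape[0]] = piece
    if snr is not None:
        rng = np.random.default_rng(ss.spawn(1)[0])
        base_rms = np.sqrt(np.mean(signal**2)) / snr
        signal = signal + base_rms * rng.standard_normal(signal.shape)
    return RawEMGRecording(
        fs=fs, channels=names, signal=signal, trial_onsets=np.array(onsets)
    )
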