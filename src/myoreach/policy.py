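"""Encoder-decoder imitation policy trained with PPO.

The policy mirrors a motor-intention architecture: an encoder MLP reads a
short window of future reference joint angles and emits a diagonal-Gaussian
latent (the "motor intention"); a decoder MLP maps the intention mean plus
proprioception (joint angles and velocities) to a per-muscle Gaussian over
pre-squash controls, executed through a sigmoid so actions stay in [0, 1].
Training uses clipped-surrogate proximal policy optimization with
generalized advantage estimation, an entropy bonus, and KL regularization
of the intention distribution toward the standard normal.

Everything is numpy with hand-written gradients (see :mod:`myoreach.nets`);
training runs a vector of parallel environments that each replay one
reference clip per episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .arm import ArmParams, ReferenceClip, Rollout, step_dynamics_batch
from .nets import MLP, Adam
from .rewards import RewardWeights

__all__ = [
    "PPOConfig",
    "PolicyConfig",
    "IntentionDistribution",
    "ActionDistribution",
    "EncoderDecoderPolicy",
    "VecReachEnv",
    "compute_gae",
    "ppo_loss_and_grads",
    "ppo_update",
    "train",
    "rollout",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PPOConfig:
    clip_eps: float = 0.2
    discount: float = 0.95
    gae_lambda: float = 0.95
    lr: float = 3e-4
    minibatch: int = 256
    epochs: int = 4
    n_envs: int = 32
    total_steps: int = 200_000
    value_coeff: float = 0.5


@dataclass(frozen=True)
class PolicyConfig:
    """Architecture and training hyperparameters.

    Desk-scale defaults use 3x64 hidden layers; 3x512 (the full-scale
    width) is available by config.
    """

    encoder_layers: tuple[int, ...] = (64, 64, 64)
    decoder_layers: tuple[int, ...] = (64, 64, 64)
    latent_dim: int = 16
    kl_weight: float = 1e-5
    entropy_cost: float = 1e-3
    ref_window: int = 5
    init_action_log_std: float = -1.0
    vel_scale: float = 0.2  # proprioceptive velocity scaling (s/rad)
    ppo: PPOConfig = field(default_factory=PPOConfig)

    def __post_init__(self) -> None:
        if self.kl_weight < 0 or self.entropy_cost < 0:
            raise ValueError("kl_weight and entropy_cost must be >= 0")
        if self.ref_window < 1:
            raise ValueError("ref_window must be >= 1")


@dataclass
class IntentionDistribution:
    """Diagonal Gaussian over the motor-intention latent."""

    mean: np.ndarray
    log_std: np.ndarray

    def kl_to_standard_normal(self) -> np.ndarray:
        """Closed-form KL(N(mean, std) || N(0, I)), summed over dims."""
        var = np.exp(2.0 * self.log_std)
        return np.sum(
            0.5 * (self.mean**2 + var - 1.0) - self.log_std, axis=-1
        )

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.mean + np.exp(self.log_std) * rng.standard_normal(
            self.mean.shape
        )


@dataclass
class ActionDistribution:
    """Per-muscle Gaussian over pre-squash controls, executed via sigmoid."""

    pre_mean: np.ndarray   # (..., n_muscles), unbounded
    log_std: np.ndarray    # (n_muscles,)

    @property
    def mean_action(self) -> np.ndarray:
        return _sigmoid(self.pre_mean)

    def entropy(self) -> float:
        """Gaussian entropy (pre-squash), summed over muscles."""
        return float(np.sum(self.log_std + 0.5 * (_LOG_2PI + 1.0)))

    def sample_pre(self, rng: np.random.Generator) -> np.ndarray:
        return self.pre_mean + np.exp(self.log_std) * rng.standard_normal(
            self.pre_mean.shape
        )

    def log_prob_pre(self, u: np.ndarray) -> np.ndarray:
        diff = (u - self.pre_mean) / np.exp(self.log_std)
        return (
            -0.5 * np.sum(diff**2, axis=-1)
            - np.sum(self.log_std)
            - 0.5 * u.shape[-1] * _LOG_2PI
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class EncoderDecoderPolicy:
    """Motor-intention policy with a separate value network."""

    def __init__(self, config: PolicyConfig, n_joints: int, n_muscles: int,
                 rng: np.random.Generator, q_rest: np.ndarray | None = None):
        self.config = config
        self.n_joints = n_joints
        self.n_muscles = n_muscles
        self.q_rest = (
            np.zeros(n_joints) if q_rest is None else np.asarray(q_rest, float)
        )
        ref_dim = config.ref_window * n_joints
        prop_dim = 2 * n_joints
        self.encoder = MLP(
            [ref_dim, *config.encoder_layers, 2 * config.latent_dim], rng
        )
        self.decoder = MLP(
            [config.latent_dim + prop_dim, *config.decoder_layers, n_muscles],
            rng,
        )
        self.value_net = MLP([ref_dim + prop_dim, *config.decoder_layers, 1], rng)
        self.action_log_std = np.full(
            n_muscles, config.init_action_log_std, dtype=float
        )

    # -- observation encoding ----------------------------------------------

    def ref_obs(self, qhat_window: np.ndarray) -> np.ndarray:
        """Flatten a (ref_window, n_joints) reference window (batched OK)."""
        w = np.asarray(qhat_window, dtype=float) - self.q_rest
        expected = (self.config.ref_window, self.n_joints)
        if w.shape[-2:] != expected:
            raise ValueError(f"window shape {w.shape[-2:]} != {expected}")
        return w.reshape(*w.shape[:-2], -1)

    def prop_obs(self, q: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [np.asarray(q) - self.q_rest,
             self.config.vel_scale * np.asarray(v)], axis=-1
        )

    # -- heads ---------------------------------------------------------------

    def encode(self, qhat_window: np.ndarray) -> IntentionDistribution:
        """Map a reference window to the intention distribution."""
        ref = self.ref_obs(qhat_window)
        if not np.all(np.isfinite(ref)):
            raise ValueError("non-finite reference window")
        out = self.encoder.forward(np.atleast_2d(ref))
        L = self.config.latent_dim
        dist = IntentionDistribution(mean=out[..., :L], log_std=out[..., L:])
        if ref.ndim == 1:
            dist = IntentionDistribution(dist.mean[0], dist.log_std[0])
        return dist

    def decode(self, latent: np.ndarray, q: np.ndarray,
               v: np.ndarray) -> ActionDistribution:
        """Map (intention sample, proprioception) to the action distribution."""
        latent = np.asarray(latent, dtype=float)
        if latent.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent dim {latent.shape[-1]} != {self.config.latent_dim}"
            )
        x = np.concatenate([latent, self.prop_obs(q, v)], axis=-1)
        pre = self.decoder.forward(np.atleast_2d(x))
        if x.ndim == 1:
            pre = pre[0]
        return ActionDistribution(pre_mean=pre, log_std=self.action_log_std)

    def value(self, ref: np.ndarray, prop: np.ndarray) -> np.ndarray:
        return self.value_net.forward(
            np.concatenate([ref, prop], axis=-1)
        )[..., 0]

    # -- parameter bookkeeping ----------------------------------------------

    def param_dicts(self) -> list[dict]:
        return [
            self.encoder.params(),
            self.decoder.params(),
            {"action_log_std": self.action_log_std},
            self.value_net.params(),
        ]

    def zero_grad_dicts(self) -> list[dict]:
        return [
            self.encoder.zero_grads(),
            self.decoder.zero_grads(),
            {"action_log_std": np.zeros_like(self.action_log_std)},
            self.value_net.zero_grads(),
        ]


# ---------------------------------------------------------------------------
# vectorized replay environment
# ---------------------------------------------------------------------------


class VecReachEnv:
    """N parallel arms, each replaying one reference clip per episode.

    All clips must share the frame interval and length. Physics substeps
    run at ``params.dt_phys`` inside each control frame; the per-frame
    reward is evaluated at the frame boundary against the current
    reference frame.
    """

    def __init__(self, clips: list[ReferenceClip], params: ArmParams,
                 weights: RewardWeights, n_envs: int,
                 rng: np.random.Generator, ref_window: int = 5):
        if not clips:
            raise ValueError("need at least one clip")
        dts = {c.dt for c in clips}
        lens = {c.n_frames for c in clips}
        if len(dts) != 1 or len(lens) != 1:
            raise ValueError("clips must share dt and length")
        self.params = params
        self.weights = weights
        self.n_envs = n_envs
        self.rng = rng
        self.ref_window = ref_window
        self.dt_frame = clips[0].dt
        self.T = clips[0].n_frames
        self.substeps = int(round(self.dt_frame / params.dt_phys))
        if self.substeps < 1:
            raise ValueError("frame interval shorter than physics step")
        self.qhat = np.stack([c.qhat for c in clips])  # (n_clips, T, nj)
        # pad reference with repeated last frame for the look-ahead window
        pad = np.repeat(self.qhat[:, -1:, :], ref_window, axis=1)
        self.qhat_padded = np.concatenate([self.qhat, pad], axis=1)
        self.clip_idx = np.zeros(n_envs, dtype=int)
        self.t = 0
        self.q = np.tile(params.q_rest, (n_envs, 1))
        self.v = np.zeros((n_envs, params.n_joints))
        self.a = np.zeros((n_envs, params.n_muscles))

    def reset(self) -> None:
        """Start a new episode: sample a clip per env, reset arm to rest."""
        self.clip_idx = self.rng.integers(0, self.qhat.shape[0], self.n_envs)
        self.t = 0
        self.q = np.tile(self.params.q_rest, (self.n_envs, 1))
        self.v[:] = 0.0
        self.a[:] = 0.0

    def ref_windows(self) -> np.ndarray:
        """(n_envs, ref_window, n_joints) look-ahead reference windows."""
        return self.qhat_padded[
            self.clip_idx[:, None],
            self.t + np.arange(self.ref_window)[None, :],
        ]

    def step(self, actions: np.ndarray) -> dict[str, np.ndarray]:
        """Advance one control frame under executed actions in [0, 1]."""
        from . import rewards as _rw

        p = self.params
        for _ in range(self.substeps):
            self.q, self.v, self.a, forces = step_dynamics_batch(
                self.q, self.v, self.a, actions, p
            )
        qhat_t = self.qhat[self.clip_idx, self.t]
        r_joint = _rw.joint_reward(self.q, qhat_t, self.weights.alpha_joint)
        c_ctrl = _rw.control_cost(actions)
        f_joint = forces @ p.moment_arms.T
        c_energy = _rw.energy_cost(
            self.v, f_joint, signed=self.weights.signed_energy
        )
        r_total = _rw.total_reward(r_joint, c_ctrl, c_energy, self.weights)
        self.t += 1
        return {
            "r_joint": r_joint, "c_ctrl": c_ctrl,
            "c_energy": c_energy, "r_total": r_total,
        }


# ---------------------------------------------------------------------------
# PPO
# ---------------------------------------------------------------------------


def compute_gae(rewards: np.ndarray, values: np.ndarray, discount: float,
                gae_lambda: float) -> tuple[np.ndarray, np.ndarray]:
    """Episodic generalized advantage estimation.

    ``rewards`` and ``values`` are (T, n_envs); episodes terminate at T
    with no bootstrap. Returns (advantages, returns), same shape.
    """
    T = rewards.shape[0]
    adv = np.zeros_like(rewards)
    last = np.zeros(rewards.shape[1])
    for t in range(T - 1, -1, -1):
        next_v = values[t + 1] if t + 1 < T else 0.0
        delta = rewards[t] + discount * next_v - values[t]
        last = delta + discount * gae_lambda * last
        adv[t] = last
    return adv, adv + values


def ppo_loss_and_grads(policy: EncoderDecoderPolicy, batch: dict,
                       config: PolicyConfig) -> tuple[dict, list[dict]]:
    """Clipped-surrogate PPO loss with analytic gradients.

    ``batch`` holds ``ref`` (B, ref_dim), ``prop`` (B, prop_dim), ``u``
    (pre-squash action samples, B x M), ``old_logp``, ``adv``, ``ret``.
    Total loss = clip_loss + value_coeff * value_loss
    - entropy_cost * entropy + kl_weight * kl_reg. Gradients follow the
    same parameter ordering as ``policy.param_dicts()``.
    """
    ppo = config.ppo
    ref, prop = batch["ref"], batch["prop"]
    u, old_logp = batch["u"], batch["old_logp"]
    adv, ret = batch["adv"], batch["ret"]
    B = ref.shape[0]
    L = config.latent_dim

    enc_grads = policy.encoder.zero_grads()
    dec_grads = policy.decoder.zero_grads()
    val_grads = policy.value_net.zero_grads()
    ls_grad = np.zeros_like(policy.action_log_std)

    # policy forward (latent mean in the differentiable path)
    enc_cache: list = []
    enc_out = policy.encoder.forward(ref, enc_cache)
    mu_z, logstd_z = enc_out[:, :L], enc_out[:, L:]
    dec_in = np.concatenate([mu_z, prop], axis=1)
    dec_cache: list = []
    m = policy.decoder.forward(dec_in, dec_cache)

    sigma = np.exp(policy.action_log_std)
    diff = (u - m) / sigma
    logp = (
        -0.5 * np.sum(diff**2, axis=1)
        - np.sum(policy.action_log_std)
        - 0.5 * u.shape[1] * _LOG_2PI
    )
    ratio = np.exp(logp - old_logp)
    unclipped = ratio * adv
    clipped = np.clip(ratio, 1.0 - ppo.clip_eps, 1.0 + ppo.clip_eps) * adv
    take_unclipped = unclipped <= clipped
    clip_loss = -np.mean(np.minimum(unclipped, clipped))

    # entropy bonus (state-independent Gaussian)
    entropy = float(
        np.sum(policy.action_log_std + 0.5 * (_LOG_2PI + 1.0))
    )

    # KL of the intention distribution to N(0, I)
    var_z = np.exp(2.0 * logstd_z)
    kl_reg = float(
        np.mean(np.sum(0.5 * (mu_z**2 + var_z - 1.0) - logstd_z, axis=1))
    )

    # value head
    val_cache: list = []
    v_in = np.concatenate([ref, prop], axis=1)
    V = policy.value_net.forward(v_in, val_cache)[:, 0]
    value_loss = float(np.mean((V - ret) ** 2))

    total = (
        clip_loss
        + ppo.value_coeff * value_loss
        - config.entropy_cost * entropy
        + config.kl_weight * kl_reg
    )
    components = {
        "clip_loss": float(clip_loss),
        "value_loss": value_loss,
        "entropy_bonus": entropy,
        "kl_reg": kl_reg,
        "total_loss": float(total),
    }
    for name, val in components.items():
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite PPO loss component {name}: {components}"
            )

    # ---- backward ----
    g_logp = -(take_unclipped * adv * ratio) / B          # dL/dlogp
    g_m = g_logp[:, None] * (diff / sigma)                # dlogp/dm chain
    ls_grad += np.sum(g_logp[:, None] * (diff**2 - 1.0), axis=0)
    ls_grad += -config.entropy_cost * np.ones_like(ls_grad)

    g_dec_in = policy.decoder.backward(dec_cache, g_m, dec_grads)
    g_mu = g_dec_in[:, :L] + config.kl_weight * mu_z / B
    g_logstd_z = config.kl_weight * (var_z - 1.0) / B
    g_enc_out = np.concatenate([g_mu, g_logstd_z], axis=1)
    policy.encoder.backward(enc_cache, g_enc_out, enc_grads)

    g_V = ppo.value_coeff * 2.0 * (V - ret) / B
    policy.value_net.backward(val_cache, g_V[:, None], val_grads)

    grads = [enc_grads, dec_grads, {"action_log_std": ls_grad}, val_grads]
    return components, grads


def ppo_update(policy: EncoderDecoderPolicy, batch: dict,
               config: PolicyConfig, optimizer: Adam) -> dict:
    """One gradient step on a minibatch; returns the loss components."""
    components, grads = ppo_loss_and_grads(policy, batch, config)
    optimizer.step(policy.param_dicts(), grads)
    return components


# ---------------------------------------------------------------------------
# training and rollout
# ---------------------------------------------------------------------------


def train(
    clips: list[ReferenceClip],
    weights: RewardWeights,
    config: PolicyConfig,
    seed: int,
    params: ArmParams | None = None,
) -> tuple[EncoderDecoderPolicy, pd.DataFrame]:
    """Train the imitation policy on a set of reference clips.

    Parallel environments each replay a uniformly sampled clip per episode;
    the returned curve records the mean per-step reward terms of the
    collected (stochastic) rollouts against cumulative environment steps.
    Fully reproducible given ``seed``.
    """
    if not clips:
        raise ValueError("need at least one clip")
    if params is None:
        params = ArmParams()
    ppo = config.ppo
    ss = np.random.SeedSequence(seed)
    rng_init, rng_env, rng_act, rng_shuffle = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    policy = EncoderDecoderPolicy(
        config, params.n_joints, params.n_muscles, rng_init,
        q_rest=params.q_rest,
    )
    env = VecReachEnv(clips, params, weights, ppo.n_envs, rng_env,
                      ref_window=config.ref_window)
    optimizer = Adam(policy.param_dicts(), lr=ppo.lr)
    T, n_envs = env.T, ppo.n_envs
    steps_per_iter = T * n_envs
    n_iters = max(1, ppo.total_steps // steps_per_iter)

    curve_rows = []
    for it in range(n_iters):
        env.reset()
        refs = np.empty((T, n_envs, config.ref_window * policy.n_joints))
        props = np.empty((T, n_envs, 2 * policy.n_joints))
        us = np.empty((T, n_envs, policy.n_muscles))
        logps = np.empty((T, n_envs))
        rews = np.empty((T, n_envs))
        vals = np.empty((T, n_envs))
        terms_acc = {"r_joint": 0.0, "c_ctrl": 0.0, "c_energy": 0.0}
        for t in range(T):
            ref = policy.ref_obs(env.ref_windows())
            prop = policy.prop_obs(env.q, env.v)
            enc_out = policy.encoder.forward(ref)
            mu_z = enc_out[:, : config.latent_dim]
            pre = policy.decoder.forward(
                np.concatenate([mu_z, prop], axis=1)
            )
            dist = ActionDistribution(pre, policy.action_log_std)
            u = dist.sample_pre(rng_act)
            actions = _sigmoid(u)
            info = env.step(actions)
            refs[t], props[t], us[t] = ref, prop, u
            logps[t] = dist.log_prob_pre(u)
            rews[t] = info["r_total"]
            vals[t] = policy.value(ref, prop)
            for k in terms_acc:
                terms_acc[k] += float(np.mean(info[k]))
        adv, ret = compute_gae(rews, vals, ppo.discount, ppo.gae_lambda)
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)

        flat = {
            "ref": refs.reshape(-1, refs.shape[-1]),
            "prop": props.reshape(-1, props.shape[-1]),
            "u": us.reshape(-1, us.shape[-1]),
            "old_logp": logps.reshape(-1),
            "adv": adv.reshape(-1),
            "ret": ret.reshape(-1),
        }
        n = flat["ref"].shape[0]
        mb = min(ppo.minibatch, n)
        for _ in range(ppo.epochs):
            order = rng_shuffle.permutation(n)
            for start in range(0, n - mb + 1, mb):
                idx = order[start : start + mb]
                batch = {k: v[idx] for k, v in flat.items()}
                ppo_update(policy, batch, config, optimizer)

        curve_rows.append(
            {
                "step": (it + 1) * steps_per_iter,
                "mean_r_joint": terms_acc["r_joint"] / T,
                "mean_c_ctrl": terms_acc["c_ctrl"] / T,
                "mean_c_energy": terms_acc["c_energy"] / T,
                "mean_r_total": float(np.mean(rews)),
            }
        )
    return policy, pd.DataFrame(curve_rows)


def rollout(
    policy: EncoderDecoderPolicy,
    clip: ReferenceClip,
    params: ArmParams | None = None,
    weights: RewardWeights | None = None,
    deterministic: bool = True,
    record_activations: bool = False,
    seed: int = 0,
) -> Rollout:
    """Roll the policy out on one clip.

    With ``deterministic=True`` (default) the intention mean and action
    mean are used throughout; otherwise both are sampled. When
    ``record_activations`` is set, the intention means and each decoder
    hidden layer's activations are retained for geometry analysis.
    """
    if params is None:
        params = ArmParams()
    if weights is None:
        weights = RewardWeights()
    if clip.qhat.shape[1] != policy.n_joints:
        raise ValueError("clip joint count does not match policy")
    env = VecReachEnv([clip], params, weights, 1,
                      np.random.default_rng(seed),
                      ref_window=policy.config.ref_window)
    env.reset()
    env.clip_idx[:] = 0
    rng = np.random.default_rng(seed)
    T = env.T
    qs = np.empty((T, policy.n_joints))
    vs = np.empty((T, policy.n_joints))
    acts = np.empty((T, policy.n_muscles))
    forces = np.empty((T, policy.n_muscles))
    zs = np.empty((T, policy.config.latent_dim))
    terms = {k: np.empty(T) for k in ("r_joint", "c_ctrl", "c_energy", "r_total")}
    layer_acts: dict[str, list[np.ndarray]] = {}

    for t in range(T):
        window = env.ref_windows()
        dist = policy.encode(window)
        z = dist.mean if deterministic else dist.sample(rng)
        prop = policy.prop_obs(env.q, env.v)
        dec_in = np.concatenate([z, prop], axis=1)
        if record_activations:
            hidden = policy.decoder.hidden_activations(dec_in)
            for i, h in enumerate(hidden):
                layer_acts.setdefault(f"decoder_{i + 1}", []).append(h[0])
        pre = policy.decoder.forward(dec_in)
        adist = ActionDistribution(pre, policy.action_log_std)
        u = adist.pre_mean if deterministic else adist.sample_pre(rng)
        action = _sigmoid(u)
        info = env.step(action)
        qs[t], vs[t] = env.q[0], env.v[0]
        acts[t] = action[0]
        forces[t] = env.a[0] * params.f_max
        zs[t] = z[0]
        for k in terms:
            terms[k][t] = float(info[k][0])

    return Rollout(
        clip_id=clip.clip_id, q=qs, v=vs, actions=acts, forces=forces,
        dt=clip.dt, reward_terms=terms, intention_means=zs,
        layer_activations=(
            {k: np.stack(v) for k, v in layer_acts.items()}
            if record_activations else None
        ),
    )
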