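"""Experiment configuration: nested, validated, YAML round-trippable.

Every field has a default; unknown keys are rejected so typos fail loudly
(``lamda_ctrl`` will name itself in the error). Configs serialize to YAML
and hash stably, and every pipeline output records the hash of the config
that produced it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["ExperimentConfig", "load_config", "save_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ArmSection(_Strict):
    n_clips: int = 46
    jitter: float = 0.15
    duration: float = 0.3
    frame_rate: float = 200.0


class EMGSection(_Strict):
    fs: float = 30000.0
    snr: float = 10.0
    target_rate: float = 200.0
    length: int = 60


class RewardSection(_Strict):
    lambda_joint: float = 1.0
    lambda_ctrl: float = 0.0
    lambda_energy: float = 0.0
    alpha_joint: float = 1.0


class PPOSection(_Strict):
    clip_eps: float = 0.2
    discount: float = 0.95
    gae_lambda: float = 0.95
    lr: float = 3e-4
    minibatch: int = 256
    epochs: int = 4
    n_envs: int = 32
    total_steps: int = 200_000
    value_coeff: float = 0.5


class PolicySection(_Strict):
    encoder_layers: tuple[int, ...] = (64, 64, 64)
    decoder_layers: tuple[int, ...] = (64, 64, 64)
    latent_dim: int = 16
    kl_weight: float = 1e-5
    entropy_cost: float = 1e-3
    ref_window: int = 5
    ppo: PPOSection = Field(default_factory=PPOSection)


class SweepSection(_Strict):
    ctrl_values: tuple[float, ...] = (0.0, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4)
    energy_values: tuple[float, ...] = (0.0,)
    n_seeds: int = 5
    hf_band: tuple[float, float] = (10.0, 1000.0)


class EDMSection(_Strict):
    E_max: int = 10
    tau_values: tuple[int, ...] = (-1, -2, -3, -4)
    Tp_max: int = 10
    standardize: bool = False


class ExperimentConfig(_Strict):
    arm: ArmSection = Field(default_factory=ArmSection)
    emg: EMGSection = Field(default_factory=EMGSection)
    reward: RewardSection = Field(default_factory=RewardSection)
    policy: PolicySection = Field(default_factory=PolicySection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    edm: EDMSection = Field(default_factory=EDMSection)
    seed: int = 0
    out_dir: str = "results"

    def to_policy_config(self):
        from .policy import PolicyConfig, PPOConfig

        return PolicyConfig(
            encoder_layers=tuple(self.policy.encoder_layers),
            decoder_layers=tuple(self.policy.decoder_layers),
            latent_dim=self.policy.latent_dim,
            kl_weight=self.policy.kl_weight,
            entropy_cost=self.policy.entropy_cost,
            ref_window=self.policy.ref_window,
            ppo=PPOConfig(**self.policy.ppo.model_dump()),
        )

    def to_reward_weights(self):
        from .rewards import RewardWeights

        return RewardWeights(
            lambda_joint=self.reward.lambda_joint,
            lambda_ctrl=self.reward.lambda_ctrl,
            lambda_energy=self.reward.lambda_energy,
            alpha_joint=self.reward.alpha_joint,
        )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML config; defaults fill missing sections, unknown keys
    raise with the offending key named."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return ExperimentConfig.model_validate(raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the config contents."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
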