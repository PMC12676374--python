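"""Shared fixtures: arm parameters, synthetic datasets, tiny policies."""

from __future__ import annotations

import numpy as np
import pytest

from myoreach.arm import ArmParams, ReferenceClip, generate_dataset
from myoreach.policy import PolicyConfig, PPOConfig


@pytest.fixture(scope="session")
def arm_params() -> ArmParams:
    return ArmParams()


@pytest.fixture(scope="session")
def small_dataset(arm_params):
    """12 jittered reach clips with ground-truth activations + rollouts."""
    clips, rollouts, manifest = generate_dataset(
        arm_params, n_clips=12, jitter=0.15, seed=1
    )
    return clips, rollouts, manifest


@pytest.fixture(scope="session")
def default_dataset(arm_params):
    """The full default dataset: 46 jittered clips (no EMG noise needed)."""
    clips, rollouts, manifest = generate_dataset(
        arm_params, n_clips=46, jitter=0.15, seed=1
    )
    return clips, rollouts, manifest


@pytest.fixture(scope="session")
def tiny_policy_config() -> PolicyConfig:
    """Desk-scale net for quick training in tests."""
    return PolicyConfig(
        encoder_layers=(32, 32, 32),
        decoder_layers=(32, 32, 32),
        latent_dim=8,
        ppo=PPOConfig(total_steps=20_000, n_envs=32),
    )


@pytest.fixture(scope="session")
def constant_clip(arm_params) -> ReferenceClip:
    """A 300 ms clip holding the rest posture."""
    qhat = np.tile(arm_params.q_rest, (60, 1))
    return ReferenceClip("const", qhat, dt=1.0 / 200.0)
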