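#!/usr/bin/env python
"""Train the motor-intention imitation policy on the reach clips.

PPO with a joint-tracking reward (no physics costs here; the sweep in
step 04 adds them) on the clips from step 01. Prints the training curve
summary and the deterministic-rollout tracking quality, and writes
training_curve.csv under results/train/.
"""

from pathlib import Path

import numpy as np

from myoreach.arm import ArmParams
from myoreach.io import read_clips_h5
from myoreach.policy import PolicyConfig, PPOConfig, rollout, train
from myoreach.rewards import RewardWeights

DATA = Path("results/data")
OUT = Path("results/train")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = ArmParams()
    clips, _ = read_clips_h5(DATA / "clips.h5")
    cfg = PolicyConfig(
        encoder_layers=(64, 64, 64), decoder_layers=(64, 64, 64),
        latent_dim=16, ppo=PPOConfig(total_steps=200_000, n_envs=32),
    )
    policy, curve = train(clips, RewardWeights(), cfg, seed=SEED,
                          params=params)
    curve.to_csv(OUT / "training_curve.csv", index=False)
    first, last = curve.iloc[0], curve.iloc[-1]
    print(f"training: {last['step']:.0f} env steps")
    print(f"mean r_joint (stochastic rollouts): "
          f"{first['mean_r_joint']:.3f} -> {last['mean_r_joint']:.3f}")

    r_det = np.mean([
        rollout(policy, c, params=params).reward_terms["r_joint"].mean()
        for c in clips
    ])
    print(f"deterministic rollout mean r_joint over {len(clips)} clips: "
          f"{r_det:.3f}")


if __name__ == "__main__":
    main()
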