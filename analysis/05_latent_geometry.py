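#!/usr/bin/env python
"""PCA geometry of the motor-intention bottleneck and decoder layers.

Trains a policy, rolls out every clip with recorded activations, and
reports the variance explained by the top three principal components of
the intention means and of each decoder hidden layer, plus a tidy table
of 3-D projections joined with the concurrent shoulder angle for
trajectory plots. Writes latent_variance.csv and projections.csv under
results/latent/.
"""

from pathlib import Path

from myoreach.arm import ArmParams
from myoreach.io import read_clips_h5
from myoreach.latent import analyze_policy_layers, variance_table
from myoreach.policy import PolicyConfig, PPOConfig, rollout, train
from myoreach.rewards import RewardWeights

DATA = Path("results/data")
OUT = Path("results/latent")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = ArmParams()
    clips, _ = read_clips_h5(DATA / "clips.h5")
    cfg = PolicyConfig(
        encoder_layers=(64, 64, 64), decoder_layers=(64, 64, 64),
        latent_dim=16, ppo=PPOConfig(total_steps=100_000, n_envs=32),
    )
    policy, _ = train(clips, RewardWeights(), cfg, seed=SEED, params=params)
    ros = [
        rollout(policy, c, params=params, record_activations=True)
        for c in clips
    ]
    report = analyze_policy_layers(ros)
    vt = variance_table(report)
    vt.to_csv(OUT / "latent_variance.csv", index=False)
    report["table"].to_csv(OUT / "projections.csv", index=False)

    print("variance explained by top-3 PCs, per layer:")
    for layer, grp in vt.groupby("layer"):
        fr = grp.sort_values("pc")["variance_fraction"].to_numpy()
        tot = fr.sum()
        print(f"  {layer:10s}: " + "  ".join(
            f"PC{i + 1} {100 * v:.1f}%" for i, v in enumerate(fr)
        ) + f"   (top-3 total {100 * tot:.1f}%)")


if __name__ == "__main__":
    main()
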