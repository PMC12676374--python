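# myoreach

Muscle-driven arm imitation learning, EMG envelope processing, and
simplex-projection decoding of muscle activity from joint kinematics — a
desk-scale, fully seeded pipeline for a question from motor
neuromechanics: **do physics costs in an imitation objective make
simulated muscle activity more like real EMG?**

The pipeline is built for researchers who want to probe that question
end to end without a GPU or an animal: a planar two-link, six-muscle arm
generates reaching trials with *known* ground-truth activations; an
encoder–decoder policy with a Gaussian "motor intention" bottleneck
imitates them under the reward

```
r_t = λ_joint · exp(−α Σ_i (q_{t,i} − q̂_{t,i})²) − λ_ctrl · Σ_j a_{t,j}² − λ_energy · Σ_j |v_{t,j}|·|τ_{t,j}|
```

trained with PPO; simulated activations are compared against EMG
envelopes processed exactly as in the lab (20–1000 Hz band-pass,
rectification, 50 Hz low-pass, 200 Hz block-averaging, 60-sample trial
windows, 98th-percentile normalization); and Takens delay embedding with
simplex projection (k = E+1 neighbors, weights `exp(−d_i/d_1)`,
Spearman-ρ skill) decodes muscle activity from joint kinematics.

Because every reference clip is forward-simulated, each stage has a
parameter-recovery guarantee to test against — the envelope chain must
recover the generating activations, the decoder must find them from the
kinematics — and the central claim becomes a seeded experiment: sweep
λ_ctrl, watch amplitude and high-frequency action power fall.

## Worked example

```bash
python analysis/01_generate_data.py
python analysis/02_process_emg.py
python analysis/03_train_policy.py
python analysis/04_constraint_sweep.py
python analysis/05_latent_geometry.py
python analysis/06_edm_decoding.py
```

Step 01 generates 46 jittered 300 ms reach clips (60 frames at 200 Hz)
plus 30 kHz synthetic raw EMG for the biceps/triceps analogues:

```
generated 46 clips of 60 frames at 200 Hz
hand displacement: mean 16.9 mm, range 14.8-19.7 mm
peak ground-truth activation: 0.59
raw EMG: 555000 samples x 2 channels at 30000 Hz (18.5 s)
```

Step 02 runs the envelope chain and checks recovery — the correlation
between what the chain extracts from noisy raw EMG and the activations
that generated it:

```
envelopes: (46, 60, 2) (trials x samples x channels) at 200 Hz
biceps: envelope vs ground-truth activation r = 0.920
triceps: envelope vs ground-truth activation r = 0.965
```

Step 03 trains the imitation policy (200k environment steps, ~10 s on
one CPU) and reports tracking quality:

```
mean r_joint (stochastic rollouts): 0.961 -> 0.973
deterministic rollout mean r_joint over 46 clips: 0.978
```

Step 04 sweeps λ_ctrl over {0, .1, .15, .2, .25, .3, .4} with 3 seeds
per value (written with 95% CIs to `results/sweep/sweep.csv`):

```
lambda_ctrl  r_joint   hf_power   sum(a^2)   MAE(biceps)
   0.00     0.970     0.3224   1.512     0.676
   0.10     0.968     0.2714   1.457     0.638
   0.20     0.973     0.2799   1.321     0.614
   0.30     0.980     0.3532   1.150     0.625
   0.40     0.976     0.2324   1.050     0.627
```

The signature result: with no control cost the over-actuated arm
co-contracts freely (Σa² ≈ 1.5, i.e. mean activation ≈ 0.5 per muscle);
raising λ_ctrl drives Σa² down monotonically toward the conservative,
EMG-like regime, the EMG error improves over the λ = 0 baseline, and
the 10–100 Hz share of action power falls between the grid endpoints
(the fine-grained HF trend is noisy at desk scale — see
`docs/methods.md`). Joint tracking stays high across this grid.

Step 05 reports the PCA compression of the motor-intention bottleneck
and each decoder layer:

```
decoder_1 : PC1 72.8%  PC2 19.5%  PC3 5.8%   (top-3 total 98.0%)
decoder_2 : PC1 79.5%  PC2 13.0%  PC3 5.8%   (top-3 total 98.2%)
decoder_3 : PC1 84.9%  PC2 10.9%  PC3 3.2%   (top-3 total 99.0%)
intention : PC1 90.1%  PC2  7.0%  PC3 2.8%   (top-3 total 99.9%)
```

and step 06 decodes the ground-truth biceps/triceps activations from
delay-embedded joint angles:

```
biceps:  joint angles -> activation, simplex rho = 0.967 (E=3, tau=-1, Tp=1)
triceps: joint angles -> activation, simplex rho = 0.903 (E=3, tau=-1, Tp=1)
```

All tables land under `results/`; each script states what it found on
stdout.

## Library layout

| module | contents |
| --- | --- |
| `myoreach.arm` | two-link six-muscle arm, reach generator, synthetic raw EMG |
| `myoreach.emg` | band-pass / rectify / low-pass / block-average / normalize chain |
| `myoreach.rewards` | joint reward, control cost, energy cost |
| `myoreach.nets`, `myoreach.policy` | numpy MLPs with backprop; encoder–decoder policy, PPO, rollouts |
| `myoreach.latent` | PCA of intention/decoder-layer activations |
| `myoreach.edm` | delay embedding, simplex projection, ρ grid search |
| `myoreach.sweep` | λ-grid sweep, HF power metric, EMG MAE, 95% CIs |
| `myoreach.config`, `myoreach.io`, `myoreach.pipeline`, `myoreach.cli` | YAML config, HDF5/CSV I/O, end-to-end runner, `myoreach` CLI |

A `myoreach` console script exposes `generate`, `process-emg`, `train`,
`sweep`, `latent`, `edm` and `run` subcommands; `myoreach run --seed 0
--out results/run` executes the whole pipeline. See `docs/methods.md`
for the models, assumptions, numerical conventions, and known
limitations.
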