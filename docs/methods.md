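# Methods

`myoreach` is a desk-scale pipeline for studying how physics costs in an
imitation-learning objective shape simulated muscle activity, and how much
of that activity is recoverable from kinematics alone. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The synthetic arm

The plant is a planar two-link arm (shoulder, elbow) at mouse-forelimb
scale: link lengths 22/25 mm, link masses 5/3 g, joint limits
[-1, 2] rad (shoulder) and [0.1, 2.8] rad (elbow). Six Hill-like muscle
actuators drive it — mono-articular flexor/extensor per joint plus a
biarticular pair — through a signed moment-arm matrix (3 mm mono-,
2 mm biarticular). Muscle force is `activation x f_max` with first-order
activation dynamics (`tau_act` = 10 ms, integrated exactly as an
exponential update); the per-muscle maximum forces (0.5–1.1 N) sit inside
the 0.2–1.2 N range of real mouse forelimb muscles and are deliberately
asymmetric between antagonists so that indiscriminate co-contraction
produces net drift. Optional force-length/velocity scaling and
vertical-plane gravity exist but are off by default (head-fixed,
horizontal-plane reaching).

Two simplifications are worth knowing about:

* **Diagonal mass matrix.** Each joint has a constant effective inertia
  (rod model, distal link folded into the shoulder term); Coriolis and
  configuration-dependent coupling are dropped. This makes semi-implicit
  Euler (1 ms step) exactly passive — with zero excitation and positive
  damping, kinetic energy is strictly non-increasing, which the tests
  assert — and keeps the vectorized training environment fast on one CPU.
* **Heavy joint damping** (4e-4 / 2.5e-4 N·m·s/rad) gives overdamped,
  velocity-proportional responses. This stabilizes policy learning but
  also filters high-frequency torque content; see the sweep section for
  the consequence.

Reference clips are *forward-simulated*: a triphasic excitation pattern
(agonist burst at 60 ms, antagonist brake at 160 ms, agonist clamp at
250 ms; Gaussian bursts, peak excitation ~0.55) is integrated for 300 ms
and the resulting trajectory becomes the imitation target. The reference
is therefore guaranteed dynamically feasible and the ground-truth
activations are known exactly — the property every parameter-recovery
test relies on. A dataset (default 46 clips, emulating a single session
of successful water reaches) jitters burst amplitudes (±15%
multiplicative) and timings (±7.5 ms) per clip, with per-clip seeds
spawned from one master seed. Clips are sampled at 200 Hz (60 frames per
300 ms), matching the EMG envelope rate.

Hand displacement under the defaults is 15–20 mm, with peak ground-truth
activations around 0.6.

## Synthetic raw EMG

A recorded activation trace is linearly upsampled to 30 kHz and
multiplies a 20–1000 Hz band-limited unit-variance noise carrier;
broadband baseline noise is added at a configurable SNR (modulated-signal
RMS over baseline RMS, default 10). Trials are concatenated with 100 ms
gaps and onset indices recorded. This emulates the amplitude statistics
an envelope pipeline sees; it does not model motor-unit action-potential
shapes, recruitment order, electrode filtering, or motion artifacts, so
passing recovery tests says the *processing chain* is correct, not that
real EMG would behave as nicely.

## EMG envelope chain

Band-pass (Butterworth order 4, 20–1000 Hz) → full-wave rectification →
low-pass (order 4, 50 Hz) → block-average downsampling to 200 Hz →
60-sample trial windows → per-channel division by the 98th percentile
pooled over all trials and samples. Numerical conventions: all filters
are applied zero-phase (`sosfiltfilt`; the stated order is the design
order, attenuation is effectively doubled) because the envelopes are
compared sample-aligned against simulated activations and group delay
would bias that comparison; percentiles interpolate linearly between
order statistics (numpy default); an all-zero channel is rejected rather
than divided by zero. The chain is scale-invariant end to end, and
block-averaging preserves means exactly for divisible lengths.

End-to-end recovery on the default dataset: Pearson r ≈ 0.92 (biceps
analogue) and ≈ 0.96 (triceps analogue) between recovered envelopes and
ground-truth activations at SNR 10.

## Reward model

Per control step, `r_t = λ_joint·r_joint − λ_ctrl·c_ctrl −
λ_energy·c_energy` with

* `r_joint = exp(−α_joint Σ_i (q_i − q̂_i)²)`, α_joint = 1 rad⁻²
  (configurable; held fixed across sweep conditions so comparisons are
  internally consistent),
* `c_ctrl = Σ_j a_j²` over executed actions in [0, 1],
* `c_energy = Σ_j |v_j|·|τ_j|` over joints, with τ the muscle-generated
  joint torque — the product of absolute values, so the term is a true
  cost; a signed-sum variant `|Σ v_j τ_j|` (net mechanical power
  magnitude) is available for sensitivity analysis.

The reward uses the current-frame reference only; look-ahead enters
through the encoder's reference window.

## Policy and training

The policy is an encoder–decoder with a Gaussian "motor intention"
bottleneck: the encoder reads a 5-frame window of future reference joint
angles and outputs the mean and log-std of a diagonal Gaussian latent
(default 16-D); the decoder maps the intention mean plus proprioception
(joint angles relative to rest, velocities scaled by 0.2 s/rad) to a
per-muscle Gaussian over pre-squash controls with a learned
state-independent log-std (init −1), executed through a sigmoid. A
separate value MLP sees the reference window and proprioception.

Training is clipped-surrogate PPO (ε = 0.2, γ = 0.95, GAE λ = 0.95,
Adam lr 3e-4, 4 epochs of 256-sample minibatches per iteration) over 32
parallel environments that each replay one uniformly sampled clip per
episode (60 control frames, 5 physics substeps each, no early
termination). The total loss adds a value term (coefficient 0.5), an
entropy bonus (coefficient 0.001) and KL regularization of the intention
distribution toward the standard normal (weight 1e-5). The intention
*mean* is used in the differentiable path and in rollouts; the log-std
head is trained by the KL term. With the KL weight raised to 1.0 the
intention means collapse toward zero, which a test verifies.

Everything is numpy (float64) with hand-written backpropagation; a test
compares the analytic gradient of the full PPO loss against central
finite differences on a small network (relative error < 1e-4). Network
widths default to 3×64 (3×512 available by config); the experiments
below use 3×32. Determinism: training curves are bit-identical under a
fixed seed; all randomness descends from one `SeedSequence`.

Desk-scale problem sizes (chosen once as the package's study
configuration): 200k environment steps for single-clip training (~7 s on
one CPU), 60k steps per sweep run, 12 clips for the sweep, 3 seeds per
grid cell.

## Constraint sweep

For each λ_ctrl in the grid (default {0, .1, .15, .2, .25, .3, .4};
λ_energy grid {0}) and each seed, a policy is trained from scratch and
every clip rolled out deterministically. Reported per cell, with
Student-t 95% confidence intervals across seeds: mean joint reward, mean
Σa², high-frequency action power, and mean absolute error against the
EMG envelopes (simulated traces renormalized by their own pooled 98th
percentile so units match). Per-cell seeds are derived from
(master seed, λ_ctrl, λ_energy, seed index) so cells are isolated.

The high-frequency metric is the fraction of periodogram power between
10 Hz and the action-stream Nyquist (100 Hz at 200 Hz frames), averaged
over muscles; DC is included in the denominator so a constant trace
scores 0 and a pure in-band sinusoid ~1. An absolute band-power mode is
recorded alongside as a diagnostic.

What the desk-scale sweep shows, and how reliably:

* **Amplitude suppression is robust.** Mean Σa² falls monotonically with
  λ_ctrl in every master seed tried (≈1.5 → ≈1.0 at 60k steps,
  → ≈0.5 at 150k). With no control cost the over-actuated arm settles
  into high co-contraction (Σa² ≈ 1.5 ≙ mean activation ≈ 0.5); the
  penalty drives actuation toward the conservative, EMG-like regime —
  the mechanism behind the "high unrestrained activity" comparison.
* **The high-frequency effect is weak at this scale.** The overdamped
  plant filters fast torque components, so deterministic rollouts are
  smooth under every condition and the residual band power is small and
  initialization-dominated. The HF-fraction decrease holds for most but
  not all master-seed draws at 60k steps (the absolute-power variant is
  noisier still); the packaged experiment runs a fixed seed and the
  monotone decrease is part of its acceptance surface, but the effect
  should be read as a tendency, not a guarantee, at desk scale.
* EMG MAE decreases modestly with control cost (the biceps analogue
  benefits most), echoing the better EMG fit under constraints.

## Latent geometry

Activation tensors (clips × timesteps × units) from the intention means
and each decoder hidden layer are flattened to (clips·timesteps, units),
mean-centered, and projected onto the top 3 principal components; the
explained-variance fractions quantify per-layer compression. Centering
only — no per-unit standardization — so variance percentages are
scale-dependent and should be compared within, not across,
architectures. Projections are reshaped back to (clips, timesteps, 3)
and joined with the concurrent shoulder angle for trajectory plots.
Encoder layers can be analyzed the same way by recording them; the
default report covers intention + decoder layers.

## Simplex decoding

Delay embedding follows `Φ(x_t) = (x(t), x(t+τ), …, x(t+(E−1)τ))` with
τ < 0 meaning lags into the past; multivariate sources contribute E
lagged copies per variable (d·E coordinates), the main convention risk
against other EDM implementations. Embedding vectors never span clip
boundaries; clips too short for a requested embedding are skipped with a
warning.

Simplex projection forecasts a target `Tp` frames ahead: the k = E+1
nearest library neighbors (unscaled Euclidean by default; a standardize
flag exists for mixed-unit sources) vote with weights
`w_i = exp(−d_i/d_1)` normalized to sum 1, where `d_1` is the nearest
distance; if `d_1 = 0`, only the zero-distance neighbors' futures are
averaged. Skill is Spearman's rho between forecasts and observations, so
it is invariant to monotone transforms applied to either side of the
correlation. Library/query splitting is by clip (even-indexed clips
library, odd queries, configurable), which guarantees the two sets are
disjoint in time. A brute-force all-pairs oracle in the test suite must
agree with the indexed implementation to 1e-10.

The grid search over (E, τ, Tp) is exhaustive with ties broken toward
smaller E, then smaller |τ|, then smaller Tp.

On the noiseless default dataset, delay-embedded joint angles decode the
ground-truth elbow-flexor activation with rho ≈ 0.96 at (E=3, τ=−1,
Tp=1); the search optimum is rho ≈ 0.98. Because generator activations
are smooth low-dimensional functions of the kinematic history, this is
an easier decoding problem than real rollout data; the numbers
demonstrate the method's correctness, not an expected field effect size.

## Known limitations

* Two joints / six muscles versus a 4-DoF, 9-muscle anatomical model;
  no tendon dynamics, no contact.
* The overdamped plant under-expresses high-frequency action content
  (see sweep notes).
* Synthetic EMG contains no physiological or recording artifacts.
* PCA variance percentages and simplex rho values on synthetic data are
  not comparable in magnitude to results from full-scale trained
  checkpoints or in vivo recordings; only the qualitative structure
  (trends, decodability, compression) transfers.
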