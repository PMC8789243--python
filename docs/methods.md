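# Methods

## Network and settling dynamics

The simulator models a three-layer recurrent network: `n_in` input units
clamped to the stimulus pixels for the whole trajectory, `n_h` hidden units,
and `n_out` output units with feedback projections onto the hidden layer
(`W_oh`).  An optional hidden↔hidden matrix exists behind a flag
(`hidden_recurrence`, off by default) because the loop through the output
layer already makes the network recurrent and nothing in the phenomena below
requires the extra matrix.

All units use the logistic activation.  This is the one activation
consistent with the clamping convention — teaching signals are exact 0/1
values, so the activation range must be the unit interval.  Updates are
synchronous: at step `t` every unclamped unit applies the sigmoid to the
weighted sum of the step `t−1` activities (inputs held fixed; state starts
at zero, so step 1 is `σ(stimulus-driven input)`).  Pre-activations are
clipped to ±500 before the sigmoid so runaway weights saturate instead of
overflowing.

Settling runs for a fixed `T_settle = 20` steps and the step-20 vector is
*defined* as the steady state; there is no early exit.  On small test
networks the step-20 state agrees with a 10×-longer iteration to better
than 1e−6, and the one-step residual is checked in the test suite.

Three phases:

* **free**: no output constraint; the endpoint is the free steady state.
* **clamped**: from step `t_clamp = 8` onward the output units are
  overwritten with the one-hot target, bit-for-bit.
* **clamped with adaptation** (`a > 0`): additionally, each hidden unit's
  update becomes the convex combination `a·x̃ + (1−a)·σ(net input)`.
  The forecast `x̃` is computed **once per trajectory** from the
  trajectory's own steps 1..5 (these precede the clamp, so they equal the
  free-phase prefix) and held fixed for the rest of the settle.  Per-step
  recomputation would feed the adapted activity back into its own forecast;
  with nothing to decide between the two, the fixed-per-trajectory variant
  was chosen as the simpler and more stable one.
  Adaptation applies to hidden units only: output units are clamped (the
  nudge would fight the clamp) and input units carry the stimulus.

Numerical guard: the forecast used as the adaptation *target* is clipped to
[0, 1] before the convex combination.  The forecast estimates the activity
of a logistic unit, which lives in that interval; without the clip an
occasional extrapolating forecast can push hidden activity outside the
activation range and destabilise the rest of training (we observed
catastrophic accuracy collapses after ~100 epochs without it).  Surprise and
the weight update use the raw, unclipped forecast.

## Steady-state predictors

Each hidden and output unit gets an independent ordinary-least-squares model
of its settling endpoint from its first `K = 5` steps:
`x(20) ≈ x̃ = λ(1)x(1) + … + λ(K)x(K) + b`.  Rank-deficient designs (e.g.
constant activity) fall back to the minimum-norm solution.  An optional
ridge penalty on the λ coefficients (never the intercept) is exposed;
the digit protocols use `ridge = 1e−3` because late in training the
settling trajectories saturate, the per-step regressors become nearly
collinear, and unregularised coefficients blow up.

Output units are predicted too: their forecasts enter the output-weight
updates and the output-layer surprise.

Refit schedule: the initial predictor is fitted on a large block of
free-phase runs (1,600 stimuli in the reference protocol).  Epoch 1 trains
against this initial fit — the weights have not changed yet, so an immediate
refit would only shrink the fitting set — and every later epoch refits on
fresh free-phase runs over that epoch's stimuli (`refit_every_n_epochs`,
default 1).  Refitting is necessary for the late-training surprise decline:
the forecaster must track the current weights.

## Learning rule and training loop

Every plastic weight follows `Δw_ij = α·x_i·(x_j − x̃_j)` with `x` the
clamped steady state (adapted if `a > 0`; for output units this is the
clamp target itself) and `x̃` the same trajectory's forecast.  Setting
`x̃ = 0` recovers Hebb's rule exactly — the training loop exposes this as a
`zero_prediction` switch and the test suite verifies trace-level equality
with a hand-written Hebbian loop.

Updates are applied online, immediately after each stimulus, in a seeded
random order (a batch mode that accumulates the epoch's updates is available
behind `batch_updates`).  All three matrices `W_ih`, `W_ho`, `W_oh` are
plastic by default.  A `symmetric_feedback` mode ties `W_oh = W_hoᵀ`
(the classical energy-based-network choice).  It is off by default: in our
experiments the mirrored feedback grows with the large output-layer surprise
and the configuration becomes unstable late in training (final accuracy up
to 0.2 below its running maximum, with or without adaptation).

Per epoch the loop records: held-out free-phase accuracy, mean surprise of
the training pass (over stimuli and units, with hidden/output breakdowns),
and — when adaptation is on — mean sNCC from paired clamped settles that
differ only in `a`.

## Surprise, sNCC, C_e

* `neuron_surprise(x, x̃) = |x − x̃|`, element-wise; the epoch statistic is
  the grand mean over the epoch's stimuli and all hidden + output units.
  The per-layer means are first-class outputs because the two layers behave
  very differently: output-unit surprise starts at ~0.5 by construction
  (untrained logistic outputs sit near 0.5, clamp targets are 0/1) and
  decays monotonically, whereas hidden-unit surprise starts near zero,
  surges while the teaching signal gains influence, and decays once the
  task is mastered.  The **hidden-layer curve** is therefore the carrier of
  the rise-then-fall "skill consciousness" signature, and it is what the
  shape checks in the test suite and the acceptance script evaluate; the
  all-units mean cannot start near zero in this architecture.
* `sncc(x, x_A) = |x − x_A|` on steady states of paired settles that share
  weights, stimulus and clamp and differ only in adaptation.  It is 0 at
  `a = 0` and shrinks to 0 as `a → 0` (checked numerically on toy nets;
  global monotonicity in `a` is not asserted).
* `compute_ce(P_s, P_A, P_m) = d(P_s, P_m) − d(P_A, P_m)` with Euclidean
  `d` (the metric is an enum with one built-in; sensory spaces may warrant
  others).  The forager's move is modelled as the convex combination
  `P_A = a·P_p + (1−a)·P_s`, deliberately mirroring the neuronal adaptation
  update; the value is returned unclipped, so maladaptive moves score
  negative.  `neuron_ce_bridge` returns the two limiting neuronal forms
  (`|x − x_A|`, `|x − x̃|`) for numerical comparison.

## Synthetic data

`generate_synthetic_digits` renders ten fixed 7×5 stroke-grid glyphs onto an
arbitrary pixel grid (nearest-neighbour, one-pixel blank border) and
corrupts each sample with i.i.d. Gaussian pixel noise and an optional
uniform ±1-pixel shift, clipping to [0, 1].  Classes are exactly balanced
and everything is seeded.  What it emulates: digit-like stimuli of
controllable difficulty with translation jitter.  What it does not: stroke
thickness/style variability, elastic deformation, and the long-tailed
ambiguity of real handwriting — so passing tests demonstrate the learning
dynamics, not performance claims about real datasets.  External data can be
supplied as IDX image/label files (magic 0x803/0x801, big-endian), with the
center crop (extra margin dropped bottom/right, row-major flattening) that
produces the 21×20 = 420-pixel input of the reference architecture.

## Protocols and chosen parameters

Reference protocol: 420-50-10 network, 1,600 free-phase stimuli for the
initial predictor fit, 400 clamped stimuli per epoch, `T = 20`, clamp at 8,
forecast window 5.

The test suite and acceptance script run a **reduced protocol**: 100-20-5
network on 10×10 digits (5 classes), 200 free-fit/80 train stimuli per
epoch, 60 epochs, held-out evaluation on 1,000 fresh generator draws.  Its
frozen conditions, with reasons:

| parameter | value | why |
|---|---|---|
| learning rate α | 0.05 | the 60-epoch budget then covers the complete rise *and* fall of the surprise curve; at 0.01 the decline is incomplete by epoch 80 |
| generator noise SD | 0.4 | hand-written-digit-like difficulty; at 0.1 the task saturates at 100% accuracy and ablation comparisons become ceiling ties |
| predictor ridge | 1e−3 | see above: near-collinear late-training designs |
| eval set | 1,000 held-out draws | accuracy differences of interest are ~0.005; a 100-stimulus eval has sampling noise ~0.02 |
| weight init | U(−0.1, 0.1) | weak initial feedback, so the untrained network is barely "aware" of the clamp, as the narrative requires |

Defaults elsewhere (TrainConfig α = 0.01, generator noise 0.1) keep the
single-stimulus and toy examples gentle.

## Known limitations

* The accuracy benefit of adaptation is small at this scale.  Across a wide
  sweep (α ∈ 0.01–0.2, noise 0.1–0.5, both feedback modes, 60–120 epochs)
  the paired effect of `a = 0.2` vs `a = 0` is ≈ 0 except in the stable
  reduced-protocol regime, where it is consistently but weakly positive
  (≈ +0.4 accuracy points, most seeds ≥ 0).  The multi-seed mean is the
  meaningful quantity; single seeds can go either way.
* Steady state is a fixed-step convention; strongly recurrent weight
  settings can oscillate, which the residual diagnostic exposes but nothing
  prevents.
* The C_e forager is a single-step illustration — there is no multi-step
  foraging dynamics or internal-model learning.
* The metabolic-energy derivation that motivates the learning rule is
  documented background only; the package implements the rule itself.
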