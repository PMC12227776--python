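# Methods

## The circuit model

`laminar` simulates a rate-based model of the canonical three-layer
neocortical motif.  Thalamic input **x**ₜ reaches layer 4 and, through a
parallel pathway, layer 5; layer 2/3 integrates the one-step-*delayed* L4
encoding of the previous input with a top-down context vector and projects
to L5.  All units are logistic-sigmoid rate neurons without bias terms:

    z_L4(t−1)  = σ(W_thal→L4 · x(t−1))
    z_L2/3(t)  = σ(W_L4→L2/3 · z_L4(t−1) + W_td→L2/3 · I_td(t))
    z_L5(t)    = σ(α · W_L2/3→L5 · z_L2/3(t) + W_thal→L5 · x(t))

α (default 0.3) models dendritic-to-somatic attenuation of the L2/3→L5
drive.  Two linear readouts sit on the dynamics: the L2/3 *prediction* of
L5 activity, ẑ_L5 = W_L2/3→L5 · z_L2/3 (a raw product — neither α-scaled
nor squashed), and the L5 *reconstruction* of its own thalamic input,
x̂ = W_dec · z_L5.

## Learning

Training minimises a joint cost

    C_total = λ_p · ½‖ẑ_L5 − z_L5‖² + λ_r · ½‖x − x̂‖²

by online gradient steps, one per timestep.  The first term is temporal
self-supervision: L2/3, which has only the previous input and the context,
must predict the latent L5 encoding of the input it has not yet seen.  The
second term is a reconstruction regulariser applied to L5 alone; without
it the predictive cost admits the degenerate input-independent solution
(representational collapse).  The reconstruction gradient is *blocked*
from every matrix upstream of L5 — W_L2/3→L5, W_L4→L2/3, W_thal→L4 and
W_td→L2/3 learn from prediction error only, while W_thal→L5 sees both
terms and W_dec only the reconstruction.

The L2/3→L5 update is

    ΔW_L2/3→L5 = −η λ_p (e ⊙ (1 − α σ′(u_L5))) z_L2/3ᵀ ,  e = ẑ_L5 − z_L5,

where the elementwise gate (1 − α σ′(u_L5)) is the attenuation effect of
the drive that W_L2/3→L5 itself exerts on its target.  The error reaching
L2/3 travels through an explicit feedback pathway B in place of the
transpose: B = W_L2/3→L5ᵀ (weight mirroring, the default), a fixed random
matrix drawn once (feedback alignment), or zero.  A Bernoulli mask with
connection probability p can dilute the feedback pathway; forward
connections are always dense.  The thalamus→L5 update keeps the σ′(u_L5)
factor required by the chain rule; a `literal_eq9` flag reproduces the
closed form without it (which then deviates from the true gradient — the
finite-difference tests document the distinction).  Every analytic update
is validated against central finite differences at relative error ≤ 1e−5.

Defaults: λ_p = λ_r = 1, Adam with η = 1e−3 (β₁ = 0.9, β₂ = 0.999), plain
SGD available by flag.  Updates are strictly online; no mini-batching.

### Numerical choices that matter

* **Input standardization.**  Gabor pixels are centred (x − 0.5) before
  the circuit.  With logistic units and no biases, a positive-mean input
  forces the prediction weights to develop a coherent positive mean
  component; the feedback of prediction error through such weights is
  coherent across all of L2/3 and silences the layer (we verified this
  failure mode across optimizers and λ settings).  Centring removes it
  without touching the circuit equations.
* **Visuomotor sign conventions.**  Visual flow is scaled to [0, 2] with
  zero preserved, so a halted flow is the *absence* of input rather than
  an extreme negative input, and locomotion speed is scaled to [0, 1].
  For visuomotor experiments the four excitatory forward pathways
  (thalamus→L4, thalamus→L5, L4→L2/3, L2/3→L5) are kept non-negative by
  projection after each update, as glutamatergic projections are.  This
  matters: with unconstrained weights the emergent L5 population code is
  systematically flow-*inhibited* (we observed this across seeds,
  initialisations and optimizers, and in a minimal reconstruction-only
  model — without bias terms the population mean activity absorbs the
  decoder's constant offset, which favours negative input coupling), and
  every mismatch-error sign then inverts relative to the phenomenology
  the model is meant to capture.  The sign constraint pins a flow-excited
  code, as in visual cortex.  Gabor-task experiments use unconstrained
  weights; their analyses (decodability, sparseness) are sign-free.
* **Initialisation.**  Zero-mean Gaussian, 1/√fan-in, seeded; sign-
  constrained runs take the elementwise absolute value of the same draw.
* **Degenerate inputs.**  All-zero rate vectors are rejected by the
  sparseness metric; PCA on zero-variance features returns a flagged
  degenerate result; non-finite training costs abort with a diagnostic.

## Synthetic tasks

**Contextual Gabor task.**  28×28 Gabor patches; orientation classes at
0°, 18°, …, 162°; per-frame spatial frequency ~ N(0.2, 0.1) cycles/pixel
(truncated at 0.02 to avoid degenerate gratings) and envelope widths ~
U(3, 8) pixels per axis; phase 0, centred, min–max rescaled to [0, 1].
A three-valued context (−18°, 0°, +18°), delivered to L2/3 as a one-hot
vector, rotates the orientation for the next frame; at the two boundary
classes the context is resampled uniformly from the two admissible
options.  Corruptions: additive Gaussian noise x* = x + λ·ε; occluding
square patches set to exactly zero (default 10×10); uniform positional
jitter of the patch centre.

**Visuomotor task.**  Locomotion speed follows a ±1/0 random walk
(equal probabilities) reflected into [0, speed_max]; the ceiling
(default 8) models a bounded running-speed range — an unbounded reflected
walk drifts like √T and saturates the sigmoid front end.  Visual flow is
f(speed) broadcast over 10 dimensions plus N(0, noise_sd²) noise, with
f linear (default) or sinusoidal.  Closed-loop mismatch windows force the
flow to exactly zero for 600 consecutive steps; windows are placed
non-overlapping with at least a window-length gap so baselines stay
clean.  Open-loop streams drive the flow from an independent random walk.
The open-loop *probe* presents flow-on windows of 60 steps, each preceded
by an equal zero-flow stretch (excluded from the baseline).  The short
probe window is deliberate: the circuit's L4 memory is one timestep, so
its prediction re-locks onto a sustained probe flow within a few steps
and a 600-step window would dilute the onset underestimation that the
probe is designed to expose.

What the generators do *not* emulate: natural image statistics, fixation
or eye-movement structure, trial structure or inter-trial intervals,
neuronal noise, and any within-session nonstationarity.  Passing tests
therefore show that the *learning principle* produces the layered
phenomenology under clean stationary streams, not that it survives the
full variability of in vivo recordings.

## Analyses

* **Decoding.**  Multinomial logistic regression (linear SVM for the
  occlusion test), stratified 80/20 split, seeded.  "Output of L2/3"
  is the prediction vector ẑ_L5; since L2/3 at time t has seen only
  x(t−1) and the context, decoding the orientation of x(t) from it
  measures next-input prediction.  Chance is computed empirically by
  label shuffling.
* **Sparseness.**  Treves–Rolls S = (Σ rᵢ/N)² / Σ(rᵢ²/N) on sigmoid
  activations, averaged over a trial; S ∈ (1/N, 1] and *smaller* S means
  sparser.  Layer comparisons and the sparseness–accuracy correlations
  use the normalized sparseness (1 − S)/(1 − 1/N), so that larger values
  mean sparser codes and the statement "L2/3 is the sparsest layer" reads
  off the numbers directly.
* **Mismatch errors.**  ME per neuron is the gradient of C_total with
  respect to that neuron's activity, averaged over mismatch steps minus
  its average over baseline steps (all non-mismatch steps excluding a
  10-step guard margin around each window and any stream-marked
  exclusions).  Positive ME is the depolarisation analogue.  Simulated
  stimulation multiplies a layer's activation vector by a gain ≥ 1 during
  mismatch steps only (optionally restricted to the neurons whose
  baseline ME was positive or negative) before downstream propagation;
  the σ′ gate keeps the unstimulated operating point, treating the boost
  as an additive response change rather than a re-squashed drive.
* **Robustness.**  For each noise level, intact and prediction-ablated
  circuits are trained on the corrupted stream (the circuit only ever
  sees x + λ·ε) and their L5 reconstructions are scored against the clean
  input.  "Ablated" disables the self-supervised cost (λ_p = 0), which
  freezes the whole L2/3 pathway at its random initial state — the
  untrained prediction drive remains, as in the circuit-ablation it
  models.  The reference is a single-hidden-layer autoencoder trained
  explicitly on (corrupted → clean) pairs pooled across levels.

## Experiment protocol and problem sizes

Defaults: 128 units per layer, 784-pixel input, 20 000 online training
steps for the Gabor task and 30 000 for the visuomotor task — lengths at
which the held-out decoding accuracies and costs have plateaued — and
five initial conditions per experiment, reported as mean ± s.e.m.
Closed-loop visuomotor training streams contain occasional halts
(window start probability 5·10⁻⁴ per step); mismatch probes use a higher
window rate (4·10⁻³) on a held-out stream.  The acceptance suite runs
reduced problem sizes where stated in its fixtures (64-unit layers for
knockout, collapse and robustness checks; a 16–128 size sweep at 10 000
steps for the sparseness–accuracy correlation); these sizes are the
package's desk-scale defaults for those analyses.

The collapse check uses plain SGD: the collapse is a property of the loss
landscape, and Adam's per-parameter step normalisation injects a small
variance floor that obscures the limit.

## Known limitations

* The sparseness–accuracy correlation for L5 comes out *positive* in our
  size-and-seed sweeps (small L5 populations are simultaneously denser
  and slightly worse decoders — a size–competence confound), whereas the
  weakly negative published value presumably reflects a sweep regime in
  which L5 sparseness is flat and competence saturated.  The L2/3
  correlation (strongly positive) reproduces robustly.
* The open-loop inversion is an order of magnitude weaker than the
  closed-loop mismatch errors (|ME| ~ 1e−3 vs ~1e−1): with flow driven by
  a random walk, the one-step L4 route predicts the probe flow well
  after its onset, so only the onset underestimation survives averaging.
  The L2/3 sign flip holds in multi-seed means; the L5 flip hovers near
  zero and its sign is not reliable at desk scale.
* At the lowest noise level (λ = 0.2) the intact circuit's reconstruction
  residual is marginally *worse* than the prediction-ablated circuit's:
  the α-attenuated prediction can contribute at most a bounded share of
  the L5 drive, so its denoising benefit emerges only once the noise is
  large relative to that share.  From λ ≈ 0.6 upward the intact circuit
  is consistently more robust.
* L5 current-input decoding accuracy sits a few points above the
  published value (≈95% vs 89%) under our defaults; the L2/3 prediction
  accuracy (≈93%) matches.
* Recurrence within L2/3, spiking dynamics, dendritic compartments,
  interneuron circuits and multi-area stacking are out of scope.
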