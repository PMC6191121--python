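# Methods

## The task

Each trial presents a sequence of image frames on a fixed pixel grid.  The
first three frames are a black (all-zero) fixation screen; from stimulus
onset onward each frame shows one image of one of two (or ten) classes,
corrupted by **pixel-replacement noise**: a fraction *p* ∈ {0, 0.50, 0.75,
0.88, 0.94, 0.97} of pixels is replaced by i.i.d. Uniform(0, 1) draws.
*Signal strength* is 100·(1 − p).  In the **static** regime one replacement
mask and one set of replacement values are drawn per trial and repeated on
every frame; in the **dynamic** regime both are redrawn per frame, so
successive frames carry independent evidence.  The number of replaced
pixels is exactly round(p·H·W), chosen uniformly without replacement (a
Bernoulli-per-pixel scheme would only randomize the count; the fixed count
is deterministic and directly testable).

### Synthetic stimuli

No external image dataset is required.  Each class is a fixed skeleton of
three line strokes joining four anchor points, rendered as Gaussian tubes
(half-width 0.09·min(H, W)) with intensities in [0, 1].  Sampling an image
jitters the anchors by a Gaussian with s.d. 0.5·`variability` in unit image
coordinates, emulating the within-class variability of handwritten digits.
With the default `variability = 0.1` a logistic readout reaches > 95 %
held-out accuracy at zero noise, so the classes are linearly separable —
the property that makes a single recurrent layer sufficient.  For the
two-alternative task the two skeletons are additionally required to differ
by a mean absolute pixel difference of at least 0.2 (candidate skeletons
are resampled until separated), mirroring the visual distinctness of a
typical digit pair.  What the generator does **not** emulate: stroke-width
and style variation, translation/rotation of whole digits, and correlations
between pixels of natural handwriting.  Passing tests therefore demonstrate
the network and learning-rule mechanics under controlled separability, not
performance on real handwriting.

An optional IDX-format reader is provided for users who have the classic
digit dataset on disk; nothing in the package or its tests uses it.

## Network

A single recurrent layer of gated recurrent units with a readout layer.
With input **x**_t and hidden state **h**_{t−1}:

    r_t = σ(U_r x_t + W_r h_{t−1} + b_r)
    z_t = σ(U_z x_t + W_z h_{t−1} + b_z)
    h_t = τ z_t ⊙ h_{t−1} + (1 − τ z_t) ⊙ σ(U_c x_t + W_h (r_t ⊙ h_{t−1}) + b_h)

The hidden nonlinearity is a sigmoid (not tanh), keeping activities in
(0, 1) and interpretable as normalized firing rates.  The constant τ = 0.5
caps the retention factor at τ·z < 1: the state always leaks, which sets
the temporal profile of the dynamics.  The candidate term has its own input
matrix `U_c` by default; `tied_candidate_input=True` reuses `U_z` inside
the candidate (both wirings are supported because published descriptions of
this cell differ on this point, and the two are not equivalent).  The
readout is affine; softmax, where needed, is applied by the consumer.

Initial hidden state: all-zeros, reset at every trial (the fixation frames
let the dynamics settle before stimulus onset).  Weights: fan-in-scaled
uniform, deterministic under the configured seed.

All gradients — supervised backpropagation through time and the
reinforcement objective below — are computed by an explicit reverse pass in
float64.  The single most important test in the repository checks every
parameter's analytic gradient against central finite differences (step
1e−4) to relative error < 1e−5.

## Supervised learning

The network is unrolled over the fixation frames plus a fixed number of
stimulus frames (the *readout time*, 1–10) and trained by BPTT with the
softmax cross-entropy loss applied to the final step only (earlier outputs
receive exactly zero gradient — a tested invariant).  Optimizer Adam,
lr 1e−3, batch 64, 5000 updates at full scale (the paper-scale default;
the desk preset below reduces this); these optimizer settings are not
stated in the source study and are standard choices.  Fixation frames are
prepended but not counted in the readout time.

The headline supervised result is qualitative: with a static mask, extra
time steps add no information and accuracy is flat in readout time; with a
dynamic mask accuracy grows with readout time, the more so the higher the
noise.  Accuracy-over-time curves are summarized by a nonlinear
least-squares fit of f(t) = A·exp(B·t) + C (multi-start over the sign of
B; non-convergence is reported, not raised) and by the first time step
reaching 90 % of the curve's maximum.

## Reward-based learning

The agent chooses among three actions each step — request another
observation, or commit to class 1 or class 2.  Rewards: +1 for the correct
class after onset; 0 for the wrong class, for any choice during fixation
(which also ends the trial), and at the 50-step timeout; each observation
costs `observation_cost` (0, −0.005 or −0.01).  The 50-step limit counts
from trial start, fixation included.

Two separate GRU networks (no shared parameters) give the policy (softmax
over 3 actions) and the scalar value estimate.  Over a batch of N completed
episodes the objective minimized is

    Q = (1/N) Σ_n [ −J_n + 0.5·V_n + β·R_n ]

with J_n = Σ_t γ^t ρ_t the discounted return, V_n the mean squared
advantage, and R_n = Σ_t Σ_a π log π the negative policy entropy (β = 1
gives the bare objective; see below).  The policy gradient is REINFORCE
with baseline, ∇J_n = Σ_t ∇log π(a_t|x_t)·A_t, with A_t treated as a
constant; the critic receives gradients only through V_n.

### Advantage forms

Two advantage definitions are implemented:

- `residual` (default for the standalone operations):
  A_t = Σ_{t'≥t} [ρ_{t'} − v(x_{t'})], optionally with γ^(t'−t) inside the
  sum.  This is the form the source equations print, and the worked
  micro-examples in the tests use it.
- `baseline` (used for training): A_t = (Σ_{t'≥t} γ^{t'−t} ρ_{t'}) − v(x_t),
  the standard REINFORCE-with-baseline estimator.

The residual form subtracts a value estimate at *every* tail step.  Once
the critic is accurate (v ≈ 0.8 per post-onset step on this task), every
extra observation lowers the advantage of all earlier actions by ≈ v, so
correct long trials acquire large negative advantages and the learned
policy collapses to premature or immediate responses — we verified this
empirically (training plateaus at ~40 % answered trials with A ≈ −0.5 for
correct 5-step episodes).  Since the phenomena of interest — trials
lengthening with noise, learning curves that first master timing and then
accuracy — require the agent to sustain long trials, the training
configurations use the baseline form.  Both forms pass the
finite-difference gradient check.

### Training configuration

Actions are sampled from the policy (stochastic throughout; there is no
greedy evaluation mode — evaluation repeats the sampling policy).  Updates
use Adam over batches of 16 completed episodes.  Readout heads are
initialized to zero so the initial policy is exactly uniform and the
initial value exactly zero; with randomly initialized heads the untrained
critic emits nonzero values, premature choices acquire spurious positive
advantages, and the policy collapses before encountering any reward
(observed, and standard practice guards against it).

γ is not printed in the source study; we use γ = 0.98 with discounted
advantages.  The choice is economic: one extra observation multiplies the
eventual +1 reward by γ, so waiting k steps is worth it only if accuracy
improves by more than a factor γ^k.  With γ = 0.9 no achievable accuracy
gain on this task justifies even five extra observations and the agent
always responds immediately; with γ ≥ 0.995 waiting is nearly free and
errors become slower than correct responses, the opposite of the
time-pressure regime under study.  γ = 0.98 produces the intended regime:
observation counts rise with noise, and correct trials run longer than
errors.  The entropy weight is β = 0.05 (β = 1 makes the per-step
exploration bonus, ~log 3, dominate the +1 terminal reward and the policy
cannot commit to any action); learning rate 2e−3.

## Analyses

- **Behavioral summary** per noise level: accuracy over answered trials
  with exact binomial CIs, mean observations ± s.e.m., full trial-length
  histograms (optionally re-binned by 6 steps and normalized per level),
  and a two-sample Mann-Whitney rank test comparing correct vs incorrect
  trial lengths.
- **Psychometric fit**: cumulative Weibull (floor 0.5, lapse-bounded) of
  accuracy vs signal strength.  **Chronometric fit**: ordinary least
  squares line of mean observations vs signal strength.
- **Generalization**: train on noise {0, 0.75} only, evaluate the frozen
  policy on all six levels; interpolation (0.50) and extrapolation (0.88–
  0.97) are read off the per-level summary.
- **Unit time courses**: per (noise × class) condition, hidden activity
  averaged over trials aligned to trial start; trials shorter than a probe
  step are excluded from that step's average.  By default all answered
  trials enter the averages, and the policy network's units are analyzed
  (both are configurable).
- **Clustering**: each unit's feature vector concatenates its
  condition-averaged time courses over all (noise, class) conditions,
  z-scored per unit.  k-means (Lloyd, best of 10 restarts — the same
  scikit-learn implementation the source study used) is run for k = 1..8
  and k* selected by an explicit elbow rule: the k maximizing the
  perpendicular distance from the (k, d) point to the chord between the
  first and last points of the normalized d-vs-k curve; a numerically
  straight curve is flagged as having no elbow.
- **Psychophysical kernel**: PK_t = ⟨s_t⟩_{D=1} − ⟨s_t⟩_{D=2}, the
  difference between the mean stimulus frame in view at post-onset step t
  over trials decided for class 1 vs class 2; the reported amplitude is
  the mean absolute pixel value of the difference image.  Steps lacking a
  minimum trial count of either decision are omitted.

## Scale presets

`full` mirrors the source study's stated sizes: 28×28 grid, 100 hidden
units per network, 200 000 environment steps, 5000 supervised updates.
`desk` is the configuration every test and the acceptance script run at:
14×14 grid, 30 hidden units, 150 000 environment steps, 1200 supervised
updates, 400-trial held-out evaluations.  At desk scale trials last 4–6
steps rather than up to 50, high-noise ten-class cells (97 % noise) remain
at chance, and the hidden-unit cluster structure resolves three rather
than four clusters (the fixation-offset and uncertainty-coding clusters
need longer integration windows to separate); these are known desk-scale
deviations, reported as computed.

## Numerical choices

Float64 throughout.  Sigmoid evaluated in the numerically stable split
form; softmax and cross-entropy max-shifted.  0·log 0 := 0 in the entropy.
Hidden activities are strictly inside (0, 1) in exact arithmetic but may
round to 1.0 under extreme pre-activations in float64.  Exponential fits
clip the exponent at ±500; k-means ties are resolved by the best of 10
seeded restarts.  All randomness flows from explicit integer seeds;
training, evaluation and the full pipeline are bit-reproducible given the
same configuration and seed.
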