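# Methods

## The federated protocol

The simulator runs `T` communication rounds between a server and `K` clients.
Every round: (1) each client downloads the global weights `w_global` and, for
prototype-guided variants, the global prototype set `P_global`; (2) each
client initialises its local model at `w_global`, trains for `E` epochs of
seeded mini-batches, and uploads the pseudo-gradient
`g_k = w_updated − w_global` together with its updated class prototypes and
per-class support counts; (3) the server refines the gradients (GRA
variants), averages them uniformly (`g_global = (1/K) Σ g̃_k` — never
weighted by client size), applies `w_global ← w_global + g_global`, and
updates the global prototypes.  The checkpoint with the highest test accuracy
across rounds is kept as the final model, mirroring the reference protocol
for this task; selecting on the test subject is methodologically unusual but
reproduced as-is, so reported test metrics are optimistically biased in the
same way for every algorithm.

Four algorithms share this loop: `fedavg` (no prototypes, no refinement),
`plu_only`, `gra_only`, and `fedaar` (both).  With `lambda_pgreg = 0` and
refinement disabled, `fedaar` is *bitwise* identical to `fedavg` on the same
seed — the test suite asserts this reduction.

## Prototype-guided local update (PLU)

A *prototype* is the mean penultimate-layer feature vector of one class.
During local training each mini-batch contributes
`L_PGReg = Σ_c ‖P_c_batch − P_c_global‖₂` (unsquared Euclidean norm, summed
over classes present in the batch *and* available globally), weighted by `λ`
in the total loss.  Gradients flow into the features only; the global
prototypes are constants, and the classifier head receives exactly the
cross-entropy gradient (asserted in tests).  `λ` is held at zero while the
global prototype set is entirely empty — in round one there is nothing to
regularise against, and the distance is undefined for missing prototypes.

After training, the client runs one deterministic full-dataset forward pass
and rebuilds its prototypes from **correctly classified** samples only
(argmax ties break toward the lowest class index), uploading per-class
support counts `n_c`.  The server forms the support-weighted average `P̄_c`
and blends it into the global prototype:

* empty global slot → adopt `P̄_c` directly;
* fewer than two available global classes → blend with `γ = 0.5` (no nearest
  other class exists);
* otherwise `P_c_global ← γ_c P_c_global + (1 − γ_c) P̄_c` with
  `γ_c = 1/(1 + exp(b − a))`, where `a = d(P̄_c, P_c_global)` and `b` is the
  distance from `P̄_c` to the nearest *other* class's global prototype.
  The logistic form is the overflow-safe rewriting of the exponential ratio
  `e^a/(e^a + e^b)`; both forms agree to 1e-12 in tests.  γ grows with `a`:
  the farther the fresh average has drifted, the more the old prototype is
  trusted.  Distances are plain (unsquared) Euclidean throughout.

## Gradient-refinement-based aggregation (GRA)

Two gradients *conflict* when their cosine similarity is negative.  For each
client `i` independently, the working vector starts at `g_i` and visits all
other clients in a per-client seeded random order; on conflict with `g_j` it
is replaced by its projection onto the normal plane of `g_j`
(`g̃ᵢ = gᵢ − (gᵢ·gⱼ/‖gⱼ‖²)gⱼ`).  Design choices:

* projection targets are always the **original** `g_j`, and every client is
  refined from an immutable snapshot of the originals (parallel semantics):
  the result cannot depend on the order clients are processed, only on each
  client's own seeded comparison order (one flag away: refining against
  already-refined gradients);
* `cos = 0` — including zero vectors — is non-conflicting (a projection at
  exactly 90° would be a no-op anyway);
* refinement acts on the whole flat parameter vector, one global angle, not
  per layer.

Each projection is exactly orthogonal to its target afterwards and never
increases the vector norm; with two clients the refined pair is mutually
non-conflicting.  Both properties, and equivalence with an independent
brute-force implementation of the compare-and-project rule over all possible
comparison orders (K ≤ 4, dim ≤ 8, 100 random instances), are asserted in
tests at 1e-6.

## Model

The classifier contract is deliberately thin: deterministic seeded
initialisation, logits, penultimate features, exact manual backpropagation,
and a stable flatten/unflatten of all trainable weights (layer-major,
declaration order).  Two architectures: `small_cnn` (two valid
conv1d→ReLU→maxpool(2) blocks over all six channels, global average pool,
linear→ReLU to a `d`-dimensional feature, linear head) and
`dual_branch_cnn` (separate trunks for accelerometer and gyroscope channels,
concatenated before the feature layer).  Neither uses batch normalisation,
so the flat vector fully determines behaviour and GRA operates on pure
trainable weights.  Backpropagation is verified against central finite
differences of the full loss (CE + λ·PGReg) to 1e-3 relative error.

`feature_dim` defaults to 64 (the reference architecture's width is not
published; 128 is one flag away).  Local optimisation is Adam with L2 weight
decay folded into the gradient, fresh optimiser state every round (the
pseudo-gradient convention), and a ×0.1 learning-rate decay every 20
*communication rounds* — with `E = 1` a round is the only epoch-like unit
the server sees.

## Metrics

Per-class one-vs-rest precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F1 = 2TP/(2TP+FP+FN)` from a C×C confusion matrix, macro-averaged with
equal class weight, and accuracy `= trace/total`; all in percent.  Classes
absent from the ground truth are excluded from the macro averages with a
warning; an undefined precision (class never predicted) counts as 0.  The
implementation is cross-checked against scikit-learn's macro
precision/recall/F1 as an independent route.

## Synthetic federation generator

The generator emulates the one property of multi-animal sensor data the
protocol is sensitive to: *clients drawn from distinct distributions*.  Class
`c` owns a per-channel bank of sinusoids (fundamental + weaker second
harmonic; frequency 0.5–6 Hz, amplitude 0.6–1.4, constant offset ±0.5).
Each subject perturbs the bank with per-channel amplitude scale
(1 + shift·N(0, 0.2)), phase offset (shift·N(0, 0.5)) and bias
(shift·N(0, 0.3)); windows get an independent uniform start phase and
i.i.d. Gaussian noise (`noise_sd`, default 0.3).  Label counts per client
follow Dirichlet(α)–multinomial; α = 0.5 by default produces strong label
skew, including clients missing entire classes.  Units are nominal; per-
channel z-scoring (statistics from the training pool only) makes them
irrelevant downstream.  Per-channel z-score was adopted as the
normalisation scheme; min–max is the plausible alternative.

The held-out test subject is always a **fresh** perturbation draw, never one
of the K training shifts — the synthetic analogue of leave-one-subject-out —
and carries a **balanced** label distribution: the evaluation covers the
subject's full activity repertoire, keeping macro metrics well defined (a
Dirichlet draw would randomly drop classes from the macro average).

What the generator does *not* emulate: temporal autocorrelation across
windows, sensor drift and orientation changes, transition windows between
activities, class imbalance of a shared global prior.  Passing tests show the
federated machinery behaves correctly under controlled heterogeneity; they
do not certify performance on real IMU data.

## The scaled-down benchmark

`fedaar.benchmark` fixes a desk-runnable analogue of the full experiment:
K = 5 clients × 600 windows of 50 timesteps, six classes, client shift 1.0,
label skew α = 0.5, `small_cnn` with d = 32, T = 30 rounds, three paired
runs (seed also re-randomises the model init), FedAAR vs FedAvg.  Problem
sizes were chosen so the whole comparison runs in a few minutes on one CPU
core.

Two protocol constants required scaling from the full-size recipe
(lr 5e-5, weight decay 0.15, tuned for a much larger model and ~34 000
optimisation steps; this benchmark takes 90):

* the learning rate (1e-2) is the value that maximises the *FedAvg
  baseline's* mean best test accuracy over {1e-3, 3e-3, 1e-2} — a
  calibration that cannot favour FedAAR;
* weight decay (7.5e-4) transports the full-scale recipe by holding the
  per-step effective decay `lr × wd` fixed.  Notably, using the full-size
  0.15 at this learning rate makes the shared decay term dominate every
  client's gradient, aligning all pseudo-gradients (no conflict ever fires)
  — an artefact of transplanting a decay constant across a 200× change in
  learning rate, not a property of the method.

All other hyper-parameters keep their defaults (λ = 0.05, E = 1, batch 256,
×0.1 decay every 20 rounds).

Known limitation: at this scale each client takes only three optimisation
steps per round, so within-round client drift — the phenomenon the prototype
regulariser corrects — is small, and the FedAAR−FedAvg macro-F1 gap is of
the same order as the seed-to-seed spread of a three-run mean.  The
directional ordering should therefore be read as a qualitative check of the
mechanism, not a measurement of the method's full-scale effect size.

## Numerical conventions

All arrays are float64.  Seeds are combined hierarchically through numpy
`default_rng` sequences (config seed → purpose tag → client/round), so every
client's batch order, the generator's draws, and each round's comparison
orders are independently reproducible.  Degenerate inputs fail loudly:
zero-variance channels name the channel, non-finite losses name the round
and batch, truncated dataset containers raise instead of loading partially,
and prototype rows masked unavailable are never read.
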