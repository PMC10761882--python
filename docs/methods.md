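# Methods

## The problem and the model

Training a text classifier for a niche scientific domain (the motivating
case is flagging articles about post-acute sequelae of SARS-CoV-2, "long
COVID") is limited by annotated data.  Paraphrase augmentation enlarges
the training set: a sequence-to-sequence paraphraser S rewrites each
training text x into x̂, and (x̂, y) inherits the original label.  But S
itself must be trained on whatever paraphrase corpus is available, which
is typically *out of domain*; pairs that teach S the wrong register
produce augmentations that hurt the classifier.

This package implements a learned data-reweighting answer.  A
meta-weight network (MWN) W — a 1 → h → h → 1 perceptron with a terminal
sigmoid (default h = 25, dropout 0.2) — maps each paraphrase pair's
teacher-forcing loss l_i = l(S, t_i, s_i) to a weight a_i = W(l_i) ∈
(0, 1).  Three nested problems are solved:

1. **Inner (paraphraser).**  S*(W) = argmin_S Σ_i W(l_i)·l_i.  W is held
   constant here; letting this stage adapt W would drive every weight to
   zero (the degenerate solution).
2. **Middle (classifier).**  C*(S*(W)) = argmin_C L(C, D_meta-tr) +
   γ·L(C, G(D_meta-tr, S*(W))), where G denotes the paraphrased copy of
   the meta-training split and γ (default 0.85) trades original against
   generated data.
3. **Outer (weights).**  min_W L(C*(S*(W)), D_meta-val), the classifier
   loss on a held-out 20% of the training set.

Each problem is approximated by a single gradient step (one-step
unroll).  The outer gradient

∇_W L = (∂S′/∂W)(∂C′/∂S′)(∂L/∂C′) = η_s η_c γ ∇²_{W,S} f · ∇²_{S′,C} L_gen · ∇_{C′} L_val

is estimated without forming second derivatives, by two levels of
symmetric perturbations: the classifier is displaced by ±α v with
v = ∇_{C′}L_val and α = alpha_scale/‖v‖ (alpha_scale = 0.01), and the
paraphraser by ±α_S^± g^± with g^± = ∇_{S′}L_gen(C^±), α_S^± =
alpha_scale/‖g^±‖.  The gradient of the stage-I objective with respect
to W, differenced across the four perturbed paraphraser states and
scaled by η_s η_c γ / (2α), is the meta-gradient.  Both levels use the
standard central-difference prefactor 1/(2·step); a variant with the
1/step prefactor (which evaluates to exactly twice the target) is
available as `fd_prefactor="printed"`.

After the alternating epochs (default 10) the classifier is fine-tuned
on the full training split (default 20 epochs, AdamW with β₁ = 0.9,
β₂ = 0.999, ε = 1e-8).

## Differentiable coupling through generation

The outer gradient needs ∂C′/∂S′ ≠ 0, but decoding is discrete.  The
package uses expected-embedding (soft) coupling: each meta-train text is
greedily decoded once per iteration; the decoder is then re-run with
teacher forcing on its own decode, giving per-position distributions
p_t over the vocabulary; the classifier consumes Σ_v p_t(v)·E[v], the
expectation of its embedding rows.  The resulting loss is
differentiable in both C and S.  Hard greedy decodes are used for the
final augmented dataset and all reported metrics.  Straight-through
coupling was considered and rejected: the expected-embedding path needs
no bias correction and is exact in the one-hot limit (a property the
tests check).

## Exact oracle

`exact_hypergradient_oracle` computes ∇_W L(C′(S′(W)), D_meta-val) by
building the entire two-stage computation as one differentiable graph
and applying reverse-mode differentiation twice (gradients of
gradients).  The package ships its own small higher-order reverse-mode
engine (`paramlo.autodiff`, float64, NumPy-backed): every primitive's
vector-Jacobian product is expressed in traced primitives, so a gradient
is itself differentiable.  The oracle is validated against brute-force
central differences of the full pipeline and serves as the reference
for the finite-difference scheme; it is used only in tests and
diagnostics.

## Smoothness and the finite-difference scheme

Symmetric differences estimate curvature and therefore assume the loss
surface is twice differentiable on the perturbation scale.  With ReLU
activations a 0.01-norm parameter perturbation routinely crosses kinks,
and the difference then measures the discontinuity in the gradient
instead of curvature — we observed estimates anti-parallel to the true
gradient in that regime.  The MWN therefore defaults to tanh hidden
activations (the reference description specifies only "MLP"), and the
desk-scale classifier uses a tanh dense layer; the full-scale reference
classifier stack (embedding → bi-LSTM(64) → dropout 0.5 → bi-LSTM(32) →
dropout 0.5 → ReLU dense(20) → softmax, inputs truncated at 128 tokens)
keeps ReLU, as `dense_activation="relu"`.  Dropout is disabled inside
all hypergradient computations so perturbed evaluations share one
deterministic regime.

Every α-style denominator is floored at 1e-12; hitting the floor —
including a vanished meta-val gradient when the classifier has
saturated — yields a flagged all-zero meta-gradient, never a division
error.

Two gradient semantics around the weighting deserve note:

* The unroll differentiates the full product W(l)·l through both
  factors, as the stage-I equation is written; `detach_mwn_input=True`
  treats the MWN input as constant.  Under detached semantics the
  symmetric ∇_W differences must hold the MWN *input* at the
  unperturbed losses (the stop-gradient removes that path from the
  objective, but a numerical perturbation would still move the values);
  the implementation does this, and the tests verify agreement with the
  oracle under all flag combinations.
* The *committed* stage-I training step always uses the weights as
  constant multipliers (plain reweighted SGD).  Differentiating the
  weighting function with respect to its own input inside a committed
  step lets the optimizer reduce the objective by pushing losses toward
  regions of low weight — a close cousin of the degenerate solution —
  and is numerically ill-conditioned when weights are standardized.
  With `commit_weight_norm="mean"` (desk-scale default) the committed
  weights are additionally self-normalized, w_i / mean(w): the learned
  *relative* weighting is preserved while the global step size stays
  comparable to unweighted training, so the reweighted method and the
  separate-training baseline train their paraphrasers at the same
  effective rate.  Likewise the committed stage-II step always trains
  the classifier on hard-decoded generated text; the soft
  expected-embedding loss exists to carry the paraphraser dependence
  inside the unroll, not to train the classifier.

## Input standardization of the weight network

Raw per-pair losses cluster tightly around their batch mean, so the
gradient of every MWN parameter is dominated by the shared
"average usefulness" signal and the network can learn a constant shift
long before any loss-dependent profile.  With
`mwn_standardize_input=True` the input is z-scored per batch (statistics
treated as constants; std floored at 0.1 nat so near-identical batches
do not amplify ordering noise).  The reference-scale default keeps raw
inputs.

## Commit rule and optimizers

The one-step SGD unrolls define the hypergradient; the committed
updates default to feeding the same per-iteration gradients through
each model's optimizer (`commit="optimizer"`, AdamW for the classifier
and the weight network, matching the reference protocol of training all
three models with AdamW; the paraphraser commits by SGD in the
desk-scale profile).  `commit="candidate"` commits the unroll states
themselves.  At desk scale, plain-SGD classifier commits either
stagnate or diverge for any usable rate, which is why the optimizer
commit is the default.

## Synthetic two-domain task

The generator builds two disjoint token vocabularies: domain A carries
the classification task, domain B is off-domain.  Classification texts
are domain-A strings whose label is the signal-token group (K groups of
synonym-paired tokens) with the strict plurality, then corrupted by
replacing each token with probability `noise_rate` by a uniform random
domain-A token.  `bayes_reference_accuracy` scores the generating rule
itself on the noised corpus — the ceiling any classifier can approach.
Paraphrase targets apply a fixed involutive synonym map (token 2i ↔
2i+1) within one domain; signal groups are synonym-closed, so the ideal
paraphrase provably preserves labels.  In-domain pairs are drawn from
the same signal-structured distribution as the classification corpus;
off-domain pairs are uniform domain-B strings.  Because signal tokens
exist only in domain A, off-domain pairs cannot teach the classifier
anything — the ground truth the weight network is expected to discover.

Default profile: 30+30 tokens, 4 signal tokens in 2 groups, 60 pairs at
50% in-domain, 120/40/80 train/val/test, lengths 6–12, noise 0.1.  The
generator mimics none of the surface statistics of natural language;
passing tests demonstrate the optimization machinery, not linguistic
competence.

## The desk-scale profile

`MLOConfig.test_profile()` runs the whole method in about 1.5 minutes
on one CPU: embedding 8, GRU hidden 12, bi-LSTM 8+8, decode bounds
(1, 16), η_s = 0.05 (SGD), classifier AdamW 0.01, weight network AdamW
0.05.  Reference-scale rates (2e-5 / 3e-3 / 1e-4) are tuned to AdamW on
pretrained transformers and move nothing at this scale.  Several
choices in this profile exist specifically because the meta-signal of a
one-step unroll is weak and noisy at desk scale; each was adopted after
measuring the failure it addresses:

* **Paraphraser warm-up** (280 unweighted steps, batch 32, lr 0.02)
  stands in for the pretrained seq2seq the full-scale protocol
  fine-tunes.  Below roughly 90% label preservation of its greedy
  generations, in-domain augmentation injects label noise into exactly
  the tokens the classifier relies on, and the true meta-signal
  *correctly* prefers off-domain pairs — inverting the premise the
  domain-recovery experiment probes.  The paraphraser decoder is
  conditioned on the position-aligned source-token embedding (no
  attention), without which a tiny GRU cannot learn token-level
  rewriting at all.
* **Full meta-val evaluation and classification batch 24** per
  iteration reduce the variance of the hypergradient; the per-draw
  noise of the per-pair signal is ~40× its mean at batch 8.
* **AdamW ε = 1e-12 for the weight network**: desk-scale meta-gradients
  are ~1e-9 per coordinate, and the reference ε = 1e-8 (appropriate for
  O(1) gradients) suppresses precisely the weak differential
  coordinates.
* **Meta early-stopping** (`meta_early_stop`): once the epoch-mean
  meta-val loss stops improving, the classifier has fit its 96-example
  meta-train split and the subsequent feedback consists of spikes up to
  1000× the median magnitude with seed-dependent sign; weight-network
  updates freeze at that point.  Off by default at reference scale.
* **MWN init scale 0.3** (weights; biases zero, so the initial map is
  exactly 0.5 at a zero input): at very small init the parameter
  gradient is input-independent and the network can only learn a
  constant shift.

## Evaluation protocol

Binary tasks report positive-class precision/recall/F1 and the
positive-score ranking AUC; multi-class tasks report macro averages and
one-vs-one AUC (mean of pairwise binary ranking AUCs over class pairs).
Ties are midranked, so uninformative scores give AUC 0.5; a class with
no predictions contributes 0 with a warning.  Seed sweeps report the
mean and the population standard deviation; the γ sweep's default grid
is {0.01, 0.85, 3, 5}.

## Known limitations

* The synthetic task's weight-recovery result is directional and
  marginal: the integrated signal-to-noise of 80 meta-iterations is
  near 1, so individual runs can still end with a flat or inverted
  weight profile, and occasional corpus realizations (for example, ones
  whose noise draw leaves few hard examples, so the classifier
  saturates early and the feedback window shrinks) can fail the
  majority-of-seeds pattern altogether.
* The soft coupling's gradient through a peaked decoder distribution is
  exponentially small in the logit margin; at full scale this is the
  usual vanishing-exploration problem of soft relaxations.
* The engine is pure NumPy and favours clarity over speed; models
  beyond a few hundred thousand parameters are impractical.
* Beam search is deterministic with width 4 and no length
  normalization; sampling-based decoding is not implemented.
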