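"""The three-stage alternating optimization loop and its hypergradients.

Each iteration draws one minibatch from the paraphrase corpus, the
meta-train split and the meta-val split, then:

1. one-step gradient descent of the paraphraser S on the weighted
   teacher-forcing objective sum_i W(l_i) * l_i (the weight network W is
   held constant here — learning W by this stage's own gradient would
   drive all weights to zero, the degenerate solution);
2. one-step gradient descent of the classifier C on
   L(C, batch) + gamma * L(C, generated batch), where the generated-data
   loss flows through the soft expected-embedding path and therefore
   retains its dependence on the updated paraphraser S';
3. a finite-difference approximation of the gradient of the meta-val
   classifier loss with respect to W, followed by one optimizer step on W.

The candidate S' and C' from the unrolls are also the committed updates
for the iteration.  After the alternating epochs the classifier is
fine-tuned on the full training split.

`exact_hypergradient_oracle` computes the same outer gradient by full
double-backward differentiation through both unrolled steps; it exists to
validate the finite-difference scheme on tiny instances and is used only
in tests and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import MLOConfig, OptimizerSettings
from .data import GeneratedExample, LabeledCorpus, ParaphraseCorpus
from .models import (
    ClassifierState,
    ParaphraserState,
    Params,
    Vocabulary,
    classifier_loss,
    generate,
    generate_ids,
    init_classifier,
    init_paraphraser,
    paraphrase_loss_vector,
    soft_generated_loss,
    weighted_paraphrase_loss,
)
from .mwn import MWNParams, loss_stats, mwn_forward, mwn_init

logger = logging.getLogger("paramlo.engine")


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class Optimizer:
    """Functional AdamW / SGD: step() maps a param dict to a new one."""

    def __init__(self, settings: OptimizerSettings):
        self.s = settings
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Params, grads: Dict[str, np.ndarray]) -> Params:
        s = self.s
        if s.name == "sgd":
            return {
                k: Tensor(p.data - s.lr * grads[k], requires_grad=True)
                for k, p in params.items()
            }
        self.t += 1
        out: Params = {}
        for k, p in params.items():
            g = grads[k]
            m = self.m.get(k, np.zeros_like(p.data))
            v = self.v.get(k, np.zeros_like(p.data))
            m = s.beta1 * m + (1 - s.beta1) * g
            v = s.beta2 * v + (1 - s.beta2) * g * g
            self.m[k], self.v[k] = m, v
            mhat = m / (1 - s.beta1**self.t)
            vhat = v / (1 - s.beta2**self.t)
            new = p.data - s.lr * (
                mhat / (np.sqrt(vhat) + s.eps) + s.weight_decay * p.data
            )
            out[k] = Tensor(new, requires_grad=True)
        return out


# ---------------------------------------------------------------------------
# stage updates (functional: inputs are never modified)
# ---------------------------------------------------------------------------


def _grad_dict(
    loss: Tensor, params: Params, create_graph: bool = False
) -> Dict[str, Tensor]:
    keys = sorted(params)
    gs = ad.grad(loss, [params[k] for k in keys], create_graph=create_graph)
    return dict(zip(keys, gs))

def _check_finite(grads: Dict[str, Tensor], what: str) -> None:
    for k, g in grads.items():
        if not np.all(np.isfinite(g.data)):
            raise FloatingPointError(f"non-finite gradient in {what} ({k})")


def _sgd_params(params: Params, grads: Dict[str, Tensor], lr: float) -> Params:
    return {
        k: Tensor(p.data - lr * grads[k].data, requires_grad=True)
        for k, p in params.items()
    }


def _flat(params: Params, d: Dict[str, Tensor]) -> np.ndarray:
    return np.concatenate([np.ravel(d[k].data) for k in sorted(params)])


def stage1_update(
    S: ParaphraserState,
    W: Optional[MWNParams],
    paraphrase_batch: Sequence,
    eta_s: float,
    reduction: str = "sum",
    detach_mwn_input: bool = False,
    standardize: bool = False,
    with_commit_grads: bool = False,
    commit_weight_norm: str = "none",
) -> Tuple[ParaphraserState, float, np.ndarray, np.ndarray, Dict[str, Tensor]]:
    """S' = S - eta_s * grad_S sum_i W(l_i) l_i; S itself is untouched.

    With ``W=None`` the objective is unweighted (the no-feedback ablation).
    Returns (S', objective value, per-pair losses, per-pair weights, and
    the stage gradients).  With ``with_commit_grads`` a sixth element is
    returned: the gradient of the same objective with the weights held
    constant — plain reweighted SGD semantics, the form a committed
    training step uses.  (The unroll gradient follows the full product,
    whose weight-derivative term is what the outer gradient chains
    through.)
    """
    if not paraphrase_batch:
        raise ValueError("empty paraphrase batch")
    commit_grads = None
    if W is None:
        losses = paraphrase_loss_vector(S, paraphrase_batch)
        weights = Tensor(np.ones(len(paraphrase_batch)))
        total = ad.tsum(losses)
        if reduction == "mean":
            total = total * (1.0 / len(paraphrase_batch))
    else:
        total, losses, weights = weighted_paraphrase_loss(
            S,
            W,
            paraphrase_batch,
            reduction=reduction,
            detach_mwn_input=detach_mwn_input,
            standardize=standardize,
        )
        if with_commit_grads:
            w_const = weights.data
            if commit_weight_norm == "mean":
                w_const = w_const / max(float(w_const.mean()), 1e-8)
            total_c = ad.tsum(Tensor(w_const) * losses)
            if reduction == "mean":
                total_c = total_c * (1.0 / len(paraphrase_batch))
            commit_grads = _grad_dict(total_c, S.params)
            _check_finite(commit_grads, "stage-I commit")
    grads = _grad_dict(total, S.params)
    _check_finite(grads, "stage-I")
    if eta_s == 0.0:
        new = S.with_params(dict(S.params))
    else:
        new = S.with_params(_sgd_params(S.params, grads, eta_s))
    if with_commit_grads:
        if commit_grads is None:
            commit_grads = grads
        return new, total.item(), losses.data, weights.data, grads, commit_grads
    return new, total.item(), losses.data, weights.data, grads


def _hard_generated_records(
    S: ParaphraserState,
    class_batch: Sequence,
    decoded_ids: List[List[int]],
) -> List[Tuple[str, int]]:
    vocab = S.vocab
    return [
        (vocab.decode(ids), ex.label) for ids, ex in zip(decoded_ids, class_batch)
    ]


def stage2_update(
    C: ClassifierState,
    S_prime: ParaphraserState,
    class_batch: Sequence,
    gamma: float,
    eta_c: float,
    only_aug: bool = False,
    hard_generations: bool = False,
    decoded_ids: Optional[List[List[int]]] = None,
    with_commit_grads: bool = False,
) -> Tuple[ClassifierState, float, List[List[int]], Dict[str, Tensor]]:
    """C' = C - eta_c * grad_C [L(C, batch) + gamma * L(C, G(batch, S'))].

    The generated-data term uses the soft decoding path by default, so the
    loss (and hence C') retains its differentiable dependence on S'.  With
    ``hard_generations`` the generated texts enter as plain tokens with no
    S-gradient (the separate-training ablation).  Returns (C', loss value,
    decoded token ids) — decodes are shared with the hypergradient step.
    With ``with_commit_grads`` a fifth element carries the gradient of the
    same objective with *hard*-decoded generations: committed training
    consumes generated text as text, while the soft path exists to carry
    the paraphraser dependence inside the unroll.
    """
    if not class_batch:
        raise ValueError("empty classification batch")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if decoded_ids is None:
        decoded_ids = [generate_ids(S_prime, ex.text) for ex in class_batch]
    records = [(ex.text, ex.label) for ex in class_batch]

    if gamma == 0.0 and not only_aug:
        total = classifier_loss(C, records)
    else:
        if hard_generations:
            gen_records = _hard_generated_records(S_prime, class_batch, decoded_ids)
            gen = classifier_loss(C, gen_records)
        else:
            gen = soft_generated_loss(C, S_prime, class_batch, decoded_ids=decoded_ids)
        if only_aug:
            total = gen
        else:
            total = classifier_loss(C, records) + gamma * gen
    grads = _grad_dict(total, C.params)
    _check_finite(grads, "stage-II")
    if eta_c == 0.0:
        new = C.with_params(dict(C.params))
    else:
        new = C.with_params(_sgd_params(C.params, grads, eta_c))
    if not with_commit_grads:
        return new, total.item(), decoded_ids, grads
    if hard_generations:
        commit = grads
    else:
        gen_records = _hard_generated_records(S_prime, class_batch, decoded_ids)
        gen_h = classifier_loss(C, gen_records)
        if only_aug:
            total_h = gen_h
        elif gamma == 0.0:
            total_h = classifier_loss(C, records)
        else:
            total_h = classifier_loss(C, records) + gamma * gen_h
        commit = _grad_dict(total_h, C.params)
        _check_finite(commit, "stage-II commit")
    return new, total.item(), decoded_ids, grads, commit


# ---------------------------------------------------------------------------
# hypergradients
# ---------------------------------------------------------------------------


@dataclass
class HypergradResult:
    grad_w: Dict[str, np.ndarray]
    alpha: float
    alpha_s_plus: float
    alpha_s_minus: float
    val_grad_norm: float
    degenerate: bool
    # diagnostics (also used by the training loop to commit updates)
    s_prime: Optional[ParaphraserState] = None
    c_prime: Optional[ClassifierState] = None
    stage1_loss: float = 0.0
    stage2_loss: float = 0.0
    val_loss: float = 0.0
    weights: Optional[np.ndarray] = None
    pair_losses: Optional[np.ndarray] = None
    decoded_ids: Optional[List[List[int]]] = None

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [np.ravel(self.grad_w[k]) for k in sorted(self.grad_w)]
        )


def _zero_like_params(params: Params) -> Dict[str, np.ndarray]:
    return {k: np.zeros_like(v.data) for k, v in params.items()}


def _perturbed(params: Params, direction: Dict[str, Tensor], step: float) -> Params:
    return {
        k: Tensor(p.data + step * direction[k].data) for k, p in params.items()
    }


def _mwn_grad_at(
    W: MWNParams,
    S: ParaphraserState,
    s_params: Params,
    batch,
    reduction: str,
    standardize: bool = False,
    stats=None,
    frozen_inputs: Optional[np.ndarray] = None,
) -> Dict[str, Tensor]:
    """grad_W of sum_i W(l_i(S~)) * l_i(S~) at fixed paraphraser params.

    ``stats`` carries the unperturbed batch statistics so the standardized
    objective is differenced consistently across perturbed states.  When
    the stage-I objective detaches the weight-network input, the input
    must stay at the unperturbed losses (``frozen_inputs``) while the
    multiplier follows the perturbed state — otherwise the symmetric
    difference picks up curvature through a path the stop-gradient
    removed from the objective.
    """
    losses = paraphrase_loss_vector(S, batch, params=s_params).detach()
    w_in = losses if frozen_inputs is None else Tensor(frozen_inputs)
    weights = mwn_forward(
        W, w_in, mode="eval", standardize=standardize, stats=stats
    )
    total = ad.tsum(weights * Tensor(losses.data))
    if reduction == "mean":
        total = total * (1.0 / len(batch))
    return _grad_dict(total, W.params)


def fd_hypergradient(
    W: MWNParams,
    S: ParaphraserState,
    C: ClassifierState,
    paraphrase_batch: Sequence,
    class_batch: Sequence,
    mlo_val_batch: Sequence,
    config: MLOConfig,
    decoded_ids: Optional[List[List[int]]] = None,
    precomputed: Optional[tuple] = None,
) -> HypergradResult:
    """Finite-difference approximation of grad_W L(C'(S'(W)), meta-val).

    Follows the two-level symmetric-perturbation scheme: the classifier is
    perturbed along the meta-val gradient at C' (step alpha =
    alpha_scale / ||grad||), the paraphraser along the generated-loss
    gradients under each perturbed classifier (steps alpha_S^+/-), and the
    weight-network gradient of the stage-I objective is differenced at the
    four perturbed paraphraser states.  Every denominator is floored; a
    floored denominator yields a flagged zero gradient rather than a
    division error.
    """
    if not paraphrase_batch or not class_batch or not mlo_val_batch:
        raise ValueError("all three batches must be non-empty")
    floor = config.denominator_floor
    val_records = [(ex.text, ex.label) for ex in mlo_val_batch]

    if precomputed is not None:
        S_prime, l1, losses, weights, C_prime, l2, decoded_ids = precomputed
    else:
        S_prime, l1, losses, weights, _ = stage1_update(
            S,
            W,
            paraphrase_batch,
            config.eta_s,
            reduction=config.loss_reduction,
            detach_mwn_input=config.detach_mwn_input,
            standardize=config.mwn_standardize_input,
        )
        C_prime, l2, decoded_ids, _ = stage2_update(
            C,
            S_prime,
            class_batch,
            config.gamma,
            config.eta_c,
            only_aug=config.only_aug,
            decoded_ids=decoded_ids,
        )
    val_loss_t = classifier_loss(C, val_records, params=C_prime.params)
    v = _grad_dict(val_loss_t, C_prime.params)
    val_grad_norm = float(np.linalg.norm(_flat(C_prime.params, v)))

    base = dict(
        s_prime=S_prime,
        c_prime=C_prime,
        stage1_loss=l1,
        stage2_loss=l2,
        val_loss=val_loss_t.item(),
        weights=weights,
        pair_losses=losses,
        decoded_ids=decoded_ids,
    )

    if config.gamma == 0.0:
        # the outer gradient is proportional to gamma
        return HypergradResult(
            _zero_like_params(W.params), 0.0, 0.0, 0.0, val_grad_norm, False, **base
        )
    if val_grad_norm < floor:
        logger.warning("meta-val gradient vanished; degenerate hypergradient")
        return HypergradResult(
            _zero_like_params(W.params), 0.0, 0.0, 0.0, val_grad_norm, True, **base
        )

    alpha = config.alpha_scale / val_grad_norm
    g_branch: Dict[str, Dict[str, Tensor]] = {}
    norms: Dict[str, float] = {}
    for sign, lab in ((+1.0, "plus"), (-1.0, "minus")):
        c_pert = _perturbed(C.params, v, sign * alpha)
        # fresh leaves for S' so the generated loss differentiates to them
        s_leaves = {
            k: Tensor(p.data, requires_grad=True) for k, p in S_prime.params.items()
        }
        gen = soft_generated_loss(
            C,
            S_prime,
            class_batch,
            c_params=c_pert,
            s_params=s_leaves,
            decoded_ids=decoded_ids,
        )
        g = _grad_dict(gen, s_leaves)
        g_branch[lab] = g
        norms[lab] = float(np.linalg.norm(_flat(s_leaves, g)))

    if min(norms.values()) < floor:
        logger.warning("generated-loss gradient vanished; degenerate hypergradient")
        return HypergradResult(
            _zero_like_params(W.params),
            alpha,
            0.0,
            0.0,
            val_grad_norm,
            True,
            **base,
        )

    alpha_s = {lab: config.alpha_scale / norms[lab] for lab in ("plus", "minus")}
    prefac_denom = 1.0 if config.fd_prefactor == "printed" else 2.0
    stats = loss_stats(losses) if config.mwn_standardize_input else None
    frozen = losses if config.detach_mwn_input else None

    branch_diff: Dict[str, Dict[str, np.ndarray]] = {}
    for lab in ("plus", "minus"):
        g = g_branch[lab]
        step = alpha_s[lab]
        gw_hi = _mwn_grad_at(
            W,
            S,
            _perturbed(S.params, g, +step),
            paraphrase_batch,
            config.loss_reduction,
            standardize=config.mwn_standardize_input,
            stats=stats,
            frozen_inputs=frozen,
        )
        gw_lo = _mwn_grad_at(
            W,
            S,
            _perturbed(S.params, g, -step),
            paraphrase_batch,
            config.loss_reduction,
            standardize=config.mwn_standardize_input,
            stats=stats,
            frozen_inputs=frozen,
        )
        branch_diff[lab] = {
            k: (gw_hi[k].data - gw_lo[k].data) / (prefac_denom * step)
            for k in W.params
        }

    scale = config.eta_s * config.eta_c * config.gamma / (2.0 * alpha)
    grad_w = {
        k: scale * (branch_diff["plus"][k] - branch_diff["minus"][k])
        for k in W.params
    }
    return HypergradResult(
        grad_w,
        alpha,
        alpha_s["plus"],
        alpha_s["minus"],
        val_grad_norm,
        False,
        **base,
    )


def exact_hypergradient_oracle(
    W: MWNParams,
    S: ParaphraserState,
    C: ClassifierState,
    paraphrase_batch: Sequence,
    class_batch: Sequence,
    mlo_val_batch: Sequence,
    config: MLOConfig,
    decoded_ids: Optional[List[List[int]]] = None,
    size_guard: int = 50_000,
) -> Dict[str, np.ndarray]:
    """Exact grad_W L(C'(S'(W)), meta-val) by double-backward autodiff.

    Differentiates through both one-step updates with graph construction
    enabled; intended for validation on tiny instances only (hence the
    parameter-count guard).
    """
    n_par = sum(
        int(p.data.size)
        for st in (W.params, S.params, C.params)
        for p in st.values()
    )
    if n_par > size_guard:
        raise ValueError(
            f"instance has {n_par} parameters; oracle guard is {size_guard}"
        )
    if decoded_ids is None:
        S_tmp, *_ = stage1_update(
            S, W, paraphrase_batch, config.eta_s, reduction=config.loss_reduction
        )
        decoded_ids = [generate_ids(S_tmp, ex.text) for ex in class_batch]

    # stage I with graph
    losses = paraphrase_loss_vector(S, paraphrase_batch)
    w_in = losses.detach() if config.detach_mwn_input else losses
    stats = loss_stats(losses.data) if config.mwn_standardize_input else None
    weights = mwn_forward(
        W,
        w_in,
        mode="eval",
        standardize=config.mwn_standardize_input,
        stats=stats,
    )
    total1 = ad.tsum(weights * losses)
    if config.loss_reduction == "mean":
        total1 = total1 * (1.0 / len(paraphrase_batch))
    s_keys = sorted(S.params)
    gS = ad.grad(total1, [S.params[k] for k in s_keys], create_graph=True)
    s_prime = {
        k: S.params[k] + (-config.eta_s) * g for k, g in zip(s_keys, gS)
    }

    # stage II with graph; generated term depends on both C and S'(W)
    records = [(ex.text, ex.label) for ex in class_batch]
    gen = soft_generated_loss(
        C, S, class_batch, c_params=C.params, s_params=s_prime, decoded_ids=decoded_ids
    )
    if config.only_aug:
        total2 = gen
    else:
        total2 = classifier_loss(C, records) + config.gamma * gen
    c_keys = sorted(C.params)
    gC = ad.grad(total2, [C.params[k] for k in c_keys], create_graph=True)
    c_prime = {
        k: C.params[k] + (-config.eta_c) * g for k, g in zip(c_keys, gC)
    }

    # stage III: meta-val loss at C'(S'(W)), differentiated to W
    val_records = [(ex.text, ex.label) for ex in mlo_val_batch]
    val_loss = classifier_loss(C, val_records, params=c_prime)
    w_keys = sorted(W.params)
    gW = ad.grad(val_loss, [W.params[k] for k in w_keys])
    return {k: g.data for k, g in zip(w_keys, gW)}


def mwn_update(
    W: MWNParams,
    grad_w: Dict[str, np.ndarray],
    optimizer: Optimizer,
) -> MWNParams:
    """One optimizer step on the weight network."""
    for k, g in grad_w.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite weight-network gradient ({k})")
    return W.with_params(optimizer.step(W.params, grad_w))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainingHistory:
    records: List[dict] = field(default_factory=list)
    epoch_records: List[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "records": self.records,
                "epochs": self.epoch_records,
                "summary": self.summary,
            },
            sort_keys=True,
        )

    def write_jsonl(self, path) -> None:
        import json

        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _batches(n: int, size: int, rng: np.random.Generator):
    """Yield shuffled index minibatches covering range(n) once."""
    perm = rng.permutation(n)
    for i in range(0, n, size):
        yield perm[i : i + size]


def _cycled_batches(n: int, size: int, count: int, rng: np.random.Generator):
    out = []
    while len(out) < count:
        out.extend(list(_batches(n, size, rng)))
    return out[:count]


def pair_weights(
    W: MWNParams,
    S: ParaphraserState,
    corpus: ParaphraseCorpus,
    standardize: bool = False,
) -> np.ndarray:
    """Current MWN weight of every pair in a corpus (eval mode).

    With standardization the z-scores use the whole corpus's loss
    statistics, so weights remain comparable across pairs.
    """
    all_losses = []
    for i in range(0, len(corpus), 16):
        batch = list(corpus)[i : i + 16]
        all_losses.append(paraphrase_loss_vector(S, batch).data)
    losses = np.concatenate(all_losses)
    stats = loss_stats(losses) if standardize else None
    return mwn_forward(
        W, losses, mode="eval", standardize=standardize, stats=stats
    ).data


def train_mlo(
    config: MLOConfig,
    paraphrase_corpus: ParaphraseCorpus,
    mlo_train: LabeledCorpus,
    mlo_val: LabeledCorpus,
    full_train: LabeledCorpus,
    vocab: Optional[Vocabulary] = None,
) -> Tuple[ClassifierState, ParaphraserState, MWNParams, TrainingHistory]:
    """Run the full alternating loop plus final fine-tuning.

    All randomness derives from ``config.seed``.  In the separate-training
    ablation the weight network is frozen and stage II consumes hard
    decodes; in the generated-data-only ablation stage II drops the
    original-data loss term.
    """
    if vocab is None:
        texts = [p.source_text for p in paraphrase_corpus]
        texts += [p.target_text for p in paraphrase_corpus]
        texts += [ex.text for ex in full_train]
        vocab = Vocabulary.build(texts)

    ss = np.random.SeedSequence(config.seed)
    s_init, c_init, w_init, s_shuffle = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    rng = np.random.default_rng(s_shuffle)

    S = init_paraphraser(
        vocab,
        embed_dim=config.s_embed,
        hidden=config.s_hidden,
        min_len=config.min_len,
        max_len=config.max_len,
        seed=s_init,
    )
    C = init_classifier(
        vocab,
        label_count=full_train.label_count,
        embed_dim=config.c_embed,
        hidden1=config.c_hidden1,
        hidden2=config.c_hidden2,
        dense=config.c_dense,
        dropout1=config.c_dropout1,
        dropout2=config.c_dropout2,
        max_input_len=config.max_input_len,
        dense_activation=config.c_dense_activation,
        seed=c_init,
    )
    W = mwn_init(
        config.mwn_hidden,
        config.mwn_dropout,
        seed=w_init,
        hidden_activation=config.mwn_activation,
        init_scale=config.mwn_init_scale,
    )
    w_opt = Optimizer(config.optimizer_w)
    use_opt = config.commit == "optimizer"
    s_opt = Optimizer(config.optimizer_s) if use_opt else None
    c_opt = Optimizer(config.optimizer_c) if use_opt else None

    pairs = list(paraphrase_corpus)
    trn = list(mlo_train)
    val = list(mlo_val)
    history = TrainingHistory()

    # paraphraser warm-up: plain unweighted training, standing in for the
    # pretrained seq2seq the full-scale protocol starts from
    warm_lr = config.eta_s if config.s_warmup_lr is None else config.s_warmup_lr
    warm_bs = min(config.s_warmup_batch, len(pairs))
    warm = 0
    while warm < config.s_warmup_steps:
        for wb in _batches(len(pairs), warm_bs, rng):
            if warm >= config.s_warmup_steps:
                break
            S, *_ = stage1_update(
                S,
                None,
                [pairs[i] for i in wb],
                warm_lr,
                reduction=config.loss_reduction,
            )
            warm += 1

    it = 0
    cached_decodes: Dict[int, List[List[int]]] = {}
    meta_active = True
    best_val = np.inf

    for epoch in range(config.mlo_epochs):
        pbs = list(_batches(len(pairs), config.paraphrase_batch, rng))
        cbs = _cycled_batches(len(trn), config.class_batch, len(pbs), rng)
        if config.val_batch is None:
            vbs = [np.arange(len(val))] * len(pbs)
        else:
            vbs = _cycled_batches(len(val), config.val_batch, len(pbs), rng)
        for bi, (pb, cb, vb) in enumerate(zip(pbs, cbs, vbs)):
            pbatch = [pairs[i] for i in pb]
            cbatch = [trn[i] for i in cb]
            vbatch = [val[i] for i in vb]
            decoded = None
            if config.cache_generations:
                key = hash(tuple(cb.tolist()))
                decoded = cached_decodes.get(key)

            mwn = None if config.para_sep else W
            S_prime, l1, losses, weights, gS, gS_commit = stage1_update(
                S,
                mwn,
                pbatch,
                config.eta_s,
                reduction=config.loss_reduction,
                detach_mwn_input=config.detach_mwn_input,
                standardize=config.mwn_standardize_input,
                with_commit_grads=True,
                commit_weight_norm=config.commit_weight_norm,
            )
            C_prime, l2, decoded, gC, gC_commit = stage2_update(
                C,
                S_prime,
                cbatch,
                config.gamma,
                config.eta_c,
                only_aug=config.only_aug,
                hard_generations=config.para_sep,
                decoded_ids=decoded,
                with_commit_grads=True,
            )
            if config.para_sep:
                val_records = [(ex.text, ex.label) for ex in vbatch]
                vloss = classifier_loss(C_prime, val_records).item()
                rec_extra = dict(
                    mlo_val_loss=vloss, hypergrad_norm=0.0, degenerate=False
                )
            else:
                res = fd_hypergradient(
                    W,
                    S,
                    C,
                    pbatch,
                    cbatch,
                    vbatch,
                    config,
                    decoded_ids=decoded,
                    precomputed=(S_prime, l1, losses, weights, C_prime, l2, decoded),
                )
                grad_w = res.grad_w
                if config.hypergrad_norm == "unit" and not res.degenerate:
                    norm = float(np.linalg.norm(res.flat()))
                    if norm > config.denominator_floor:
                        grad_w = {k: g / norm for k, g in grad_w.items()}
                if meta_active:
                    W = mwn_update(W, grad_w, w_opt)
                rec_extra = dict(
                    mlo_val_loss=res.val_loss,
                    hypergrad_norm=float(np.linalg.norm(res.flat())),
                    degenerate=res.degenerate,
                )
            if use_opt:
                S = S.with_params(
                    s_opt.step(S.params, {k: g.data for k, g in gS_commit.items()})
                )
                C = C.with_params(
                    c_opt.step(C.params, {k: g.data for k, g in gC_commit.items()})
                )
            else:
                S, C = S_prime, C_prime
            if config.cache_generations and decoded is not None:
                cached_decodes[hash(tuple(cb.tolist()))] = decoded

            history.records.append(
                dict(
                    iteration=it,
                    epoch=epoch,
                    stage1_loss=float(l1),
                    stage2_loss=float(l2),
                    mwn_weight_mean=float(np.mean(weights)),
                    mwn_weight_min=float(np.min(weights)),
                    mwn_weight_max=float(np.max(weights)),
                    **rec_extra,
                )
            )
            it += 1
        epoch_recs = [r for r in history.records if r["epoch"] == epoch]
        epoch_val = float(np.mean([r["mlo_val_loss"] for r in epoch_recs]))
        history.epoch_records.append(
            dict(
                epoch=epoch,
                mean_stage2_loss=float(
                    np.mean([r["stage2_loss"] for r in epoch_recs])
                ),
                mean_mlo_val_loss=epoch_val,
                meta_active=meta_active,
            )
        )
        if config.meta_early_stop and meta_active:
            if epoch_val > best_val:
                meta_active = False
                logger.info(
                    "meta-val loss stopped improving after epoch %d; "
                    "freezing weight-network updates",
                    epoch,
                )
            best_val = min(best_val, epoch_val)

    C = finetune(
        C,
        full_train,
        epochs=config.finetune_epochs,
        settings=config.optimizer_c,
        batch_size=config.class_batch,
        rng=rng,
        history=history,
    )

    weights_final = pair_weights(
        W, S, paraphrase_corpus, standardize=config.mwn_standardize_input
    )
    tags = [p.domain_tag for p in paraphrase_corpus]
    summary = dict(
        final_mwn_weight_mean=float(np.mean(weights_final)),
    )
    if all(t is not None for t in tags):
        in_w = weights_final[[t == "in_domain" for t in tags]]
        off_w = weights_final[[t == "off_domain" for t in tags]]
        if len(in_w) and len(off_w):
            summary["final_in_domain_weight_mean"] = float(np.mean(in_w))
            summary["final_off_domain_weight_mean"] = float(np.mean(off_w))
    history.summary = summary
    return C, S, W, history


def finetune(
    C: ClassifierState,
    full_train: LabeledCorpus,
    epochs: int = 20,
    eta_c: Optional[float] = None,
    settings: Optional[OptimizerSettings] = None,
    batch_size: int = 8,
    rng: Optional[np.random.Generator] = None,
    history: Optional[TrainingHistory] = None,
) -> ClassifierState:
    """Standard supervised epochs on the full training split.

    ``epochs=0`` returns the classifier unchanged.  Uses AdamW by default;
    passing ``eta_c`` instead selects plain SGD at that rate.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    if epochs == 0:
        return C
    if rng is None:
        rng = np.random.default_rng(0)
    if settings is None:
        settings = (
            OptimizerSettings(name="sgd", lr=eta_c)
            if eta_c is not None
            else OptimizerSettings(lr=3e-3)
        )
    elif eta_c is not None:
        settings = OptimizerSettings(name="sgd", lr=eta_c)
    opt = Optimizer(settings)
    examples = list(full_train)
    for epoch in range(epochs):
        epoch_losses = []
        for idx in _batches(len(examples), batch_size, rng):
            batch = [(examples[i].text, examples[i].label) for i in idx]
            loss = classifier_loss(C, batch)
            grads = _grad_dict(loss, C.params)
            _check_finite(grads, "fine-tuning")
            C = C.with_params(
                opt.step(C.params, {k: g.data for k, g in grads.items()})
            )
            epoch_losses.append(loss.item())
        if history is not None:
            history.epoch_records.append(
                dict(
                    finetune_epoch=epoch,
                    mean_train_loss=float(np.mean(epoch_losses)),
                )
            )
    return C


def augment_dataset(
    S: ParaphraserState,
    corpus: LabeledCorpus,
    strategy: str = "greedy",
    seed: int = 0,
) -> List[GeneratedExample]:
    """One label-preserving paraphrase per example; failures are skipped."""
    out: List[GeneratedExample] = []
    failures = 0
    for ex in corpus:
        try:
            text = generate(S, ex.text, strategy=strategy, seed=seed)
            out.append(GeneratedExample(text=text, label=ex.label, source_id=ex.id))
        except Exception as err:  # noqa: BLE001 - record and continue
            failures += 1
            logger.warning("generation failed for %r: %s", ex.id, err)
    if failures:
        logger.warning("%d/%d generations failed and were skipped", failures, len(corpus))
    return out
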