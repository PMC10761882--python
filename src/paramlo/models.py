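"""Reference paraphraser and classifier models.

The paraphraser ``S`` is a single-layer GRU encoder-decoder over a shared
whitespace-token vocabulary; the decoder is conditioned on the encoder's
final state and, at each step, on the embedding of the source token at
the same position (alignment conditioning — no attention, but
token-level rewriting stays learnable at tiny sizes); the classifier ``C`` is the two-layer
bidirectional-LSTM stack (embedding -> bi-LSTM -> dropout -> bi-LSTM ->
dropout -> ReLU dense(20) -> softmax) commonly used for small-corpus text
classification.  Both are written functionally: parameters live in plain
dicts of autodiff tensors, and every forward accepts an arbitrary parameter
dict, so one-step-updated "candidate" parameters (which are graph nodes,
not leaves) can be pushed through unchanged.  That property is what lets
the meta-gradient machinery differentiate through the updates.

The two models share one :class:`Vocabulary`.  Augmentation text flows from
S to C either as hard greedy decodes (for reported metrics and the final
augmented dataset) or through the *soft* expected-embedding path
(:func:`soft_generated_loss`), which keeps the classifier loss
differentiable in the paraphraser parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

CHECKPOINT_VERSION = 1

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"


class Vocabulary:
    """Bijective token<->id mapping with reserved special ids 0..3."""

    def __init__(self, tokens: Sequence[str]):
        specials = [PAD, BOS, EOS, UNK]
        seen = dict.fromkeys(specials)
        for t in tokens:
            if t not in seen:
                seen[t] = None
        self._id_to_token: List[str] = list(seen)
        self._token_to_id: Dict[str, int] = {
            t: i for i, t in enumerate(self._id_to_token)
        }
        self.pad_id, self.bos_id, self.eos_id, self.unk_id = 0, 1, 2, 3

    def __len__(self) -> int:
        return len(self._id_to_token)

    @property
    def size(self) -> int:
        return len(self._id_to_token)

    def encode(self, text: str) -> List[int]:
        return [
            self._token_to_id.get(tok, self.unk_id) for tok in text.split()
        ]

    def decode(self, ids: Sequence[int]) -> str:
        return " ".join(
            self._id_to_token[i]
            for i in ids
            if i not in (self.pad_id, self.bos_id, self.eos_id)
        )

    def token(self, i: int) -> str:
        return self._id_to_token[i]

    @classmethod
    def build(cls, texts: Sequence[str]) -> "Vocabulary":
        tokens: List[str] = []
        for t in texts:
            tokens.extend(t.split())
        return cls(sorted(set(tokens)))

    def content_hash(self) -> str:
        h = hashlib.sha256("\x00".join(self._id_to_token).encode("utf-8"))
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# parameter helpers
# ---------------------------------------------------------------------------

Params = Dict[str, Tensor]


def clone_params(params: Params) -> Params:
    return {k: Tensor(v.data.copy(), requires_grad=True) for k, v in params.items()}


def params_checksum(params: Params) -> str:
    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k].data).tobytes())
    return h.hexdigest()


def flatten_params(params: Params) -> np.ndarray:
    return np.concatenate(
        [np.ravel(params[k].data) for k in sorted(params)]
    )


def flatten_grads(params: Params, grads: Dict[str, Tensor]) -> np.ndarray:
    return np.concatenate(
        [np.ravel(grads[k].data) for k in sorted(params)]
    )


def _uniform(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _arch_hash(spec: dict) -> str:
    return hashlib.sha256(
        json.dumps(spec, sort_keys=True).encode()
    ).hexdigest()[:16]


def _pad_batch(
    id_lists: Sequence[Sequence[int]], pad_id: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Pad to a (B, T) int array plus float mask; T = longest sequence."""
    T = max(len(x) for x in id_lists)
    B = len(id_lists)
    ids = np.full((B, T), pad_id, dtype=np.int64)
    mask = np.zeros((B, T))
    for i, x in enumerate(id_lists):
        ids[i, : len(x)] = x
        mask[i, : len(x)] = 1.0
    return ids, mask


# ---------------------------------------------------------------------------
# paraphraser: GRU encoder-decoder
# ---------------------------------------------------------------------------


@dataclass
class ParaphraserState:
    """Seq2seq parameters plus vocabulary and decode-length bounds."""

    params: Params
    vocab: Vocabulary
    embed_dim: int
    hidden: int
    min_len: int = 65
    max_len: int = 128

    def __post_init__(self):
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("decode bounds must satisfy 1 <= min_len <= max_len")
        if self.params["out_W"].shape[1] != self.vocab.size:
            raise ValueError("output projection width must equal vocabulary size")

    def with_params(self, params: Params) -> "ParaphraserState":
        return replace(self, params=params)

    def arch_spec(self) -> dict:
        return {
            "model": "gru_seq2seq",
            "vocab": self.vocab.size,
            "embed": self.embed_dim,
            "hidden": self.hidden,
        }


def init_paraphraser(
    vocab: Vocabulary,
    embed_dim: int = 16,
    hidden: int = 16,
    min_len: int = 65,
    max_len: int = 128,
    seed: int = 0,
) -> ParaphraserState:
    rng = np.random.default_rng(seed)
    V, E, H = vocab.size, embed_dim, hidden
    s_in = 1.0 / np.sqrt(E)
    s_h = 1.0 / np.sqrt(H)
    params: Params = {
        "emb": Tensor(rng.normal(0.0, 0.1, size=(V, E)), requires_grad=True),
        "enc_Wx": _uniform(rng, (E, 3 * H), s_in),
        "enc_Wh": _uniform(rng, (H, 3 * H), s_h),
        "enc_b": _zeros(3 * H),
        "dec_Wx": _uniform(rng, (2 * E, 3 * H), s_in),
        "dec_Wh": _uniform(rng, (H, 3 * H), s_h),
        "dec_b": _zeros(3 * H),
        "out_W": _uniform(rng, (H, V), s_h),
        "out_b": _zeros(V),
    }
    return ParaphraserState(
        params=params,
        vocab=vocab,
        embed_dim=embed_dim,
        hidden=hidden,
        min_len=min_len,
        max_len=max_len,
    )


def _gru_step(
    params: Params, prefix: str, x: Tensor, h: Tensor, H: int
) -> Tensor:
    gx = ad.matmul(x, params[prefix + "_Wx"])
    gh = ad.matmul(h, params[prefix + "_Wh"])
    b = params[prefix + "_b"]
    z = ad.sigmoid(gx[:, :H] + gh[:, :H] + b[:H])
    r = ad.sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H] + b[H : 2 * H])
    n = ad.tanh(
        gx[:, 2 * H :] + ad.mul(r, gh[:, 2 * H :]) + b[2 * H :]
    )
    return (1.0 - z) * h + z * n


def _masked(h_new: Tensor, h_old: Tensor, m: Tensor) -> Tensor:
    return m * h_new + (1.0 - m) * h_old


def _embed(params_key: Tensor, ids: np.ndarray) -> Tensor:
    B, T = ids.shape
    E = params_key.shape[1]
    flat = ad.gather_rows(params_key, ids.ravel())
    return ad.reshape(flat, (B, T, E))


def encode_source(
    params: Params, src_ids: np.ndarray, src_mask: np.ndarray, hidden: int
) -> Tensor:
    """Run the encoder GRU; return the final hidden state (B, H)."""
    B, T = src_ids.shape
    X = _embed(params["emb"], src_ids)
    h = Tensor(np.zeros((B, hidden)))
    for t in range(T):
        m = Tensor(src_mask[:, t : t + 1])
        h = _masked(_gru_step(params, "enc", X[:, t, :], h, hidden), h, m)
    return h


def _aligned_source(src_ids: np.ndarray, T: int, pad_id: int) -> np.ndarray:
    """Source ids aligned to decode positions, padded beyond the source."""
    B, Ts = src_ids.shape
    out = np.full((B, T), pad_id, dtype=np.int64)
    keep = min(T, Ts)
    out[:, :keep] = src_ids[:, :keep]
    return out


def decoder_logits(
    params: Params,
    h0: Tensor,
    tgt_ids: np.ndarray,
    hidden: int,
    bos_id: int,
    src_ids: np.ndarray,
    pad_id: int,
) -> Tensor:
    """Teacher-forced decoder logits (B, T, V) for target token arrays.

    Each step consumes the previous target token's embedding concatenated
    with the same-position source-token embedding.
    """
    B, T = tgt_ids.shape
    inputs = np.concatenate(
        [np.full((B, 1), bos_id, dtype=np.int64), tgt_ids[:, :-1]], axis=1
    )
    X = _embed(params["emb"], inputs)
    A = _embed(params["emb"], _aligned_source(src_ids, T, pad_id))
    h = h0
    outs = []
    for t in range(T):
        x = ad.concat([X[:, t, :], A[:, t, :]], axis=1)
        h = _gru_step(params, "dec", x, h, hidden)
        outs.append(ad.matmul(h, params["out_W"]) + params["out_b"])
    return ad.stack(outs, axis=1)


def _masked_token_nll(
    logits: Tensor, tgt_ids: np.ndarray, mask: np.ndarray
) -> Tensor:
    """Per-example mean negative log-likelihood over unpadded positions."""
    B, T, V = logits.shape
    logp = ad.log_softmax(ad.reshape(logits, (B * T, V)), axis=-1)
    nll = ad.neg(ad.take_rowwise(logp, tgt_ids.ravel()))
    nll = ad.reshape(nll, (B, T)) * Tensor(mask)
    lengths = Tensor(mask.sum(axis=1))
    return ad.tsum(nll, axis=1) / lengths


def paraphrase_loss_vector(
    state: ParaphraserState,
    pairs: Sequence,
    params: Optional[Params] = None,
) -> Tensor:
    """Teacher-forcing loss l(S, t_i, s_i) for each pair; shape (M,).

    Each entry is a per-token mean so losses are comparable across target
    lengths.  Differentiable in the (possibly substituted) parameters.
    """
    if not pairs:
        raise ValueError("empty paraphrase batch")
    p = state.params if params is None else params
    vocab = state.vocab
    src = [vocab.encode(pr.source_text) for pr in pairs]
    tgt = [vocab.encode(pr.target_text) + [vocab.eos_id] for pr in pairs]
    for pr, t in zip(pairs, tgt):
        if len(t) <= 1 and not pr.target_text.split():
            raise ValueError(f"pair {pr.id!r}: target tokenizes to length 0")
    src_ids, src_mask = _pad_batch(src, vocab.pad_id)
    tgt_ids, tgt_mask = _pad_batch(tgt, vocab.pad_id)
    h = encode_source(p, src_ids, src_mask, state.hidden)
    logits = decoder_logits(
        p, h, tgt_ids, state.hidden, vocab.bos_id, src_ids, vocab.pad_id
    )
    return _masked_token_nll(logits, tgt_ids, tgt_mask)


def teacher_forcing_loss(state: ParaphraserState, pair) -> Tensor:
    """Mean per-token NLL of the target given the source (scalar tensor)."""
    return paraphrase_loss_vector(state, [pair])[0:1].sum()


def weighted_paraphrase_loss(
    state: ParaphraserState,
    mwn,
    pairs: Sequence,
    params: Optional[Params] = None,
    reduction: str = "sum",
    detach_mwn_input: bool = False,
    standardize: bool = False,
    stats: Optional[tuple] = None,
) -> Tuple[Tensor, Tensor, Tensor]:
    """Sum_i W(l_i) * l_i.  Returns (total, per-pair losses, weights).

    ``reduction="mean"`` divides by the batch size.  With
    ``detach_mwn_input`` the loss fed to the weight network is treated as a
    constant, so model gradients flow only through the W(l)*l product's
    second factor.  ``standardize``/``stats`` control z-scoring of the
    weight-network input.
    """
    from .mwn import mwn_forward  # local import to avoid a cycle

    losses = paraphrase_loss_vector(state, pairs, params=params)
    w_in = losses.detach() if detach_mwn_input else losses
    weights = mwn_forward(
        mwn, w_in, mode="eval", standardize=standardize, stats=stats
    )
    total = ad.tsum(weights * losses)
    if reduction == "mean":
        total = total * (1.0 / len(pairs))
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return total, losses, weights


# -- generation -------------------------------------------------------------


def _decode_allowed(logits_row: np.ndarray, vocab: Vocabulary, allow_eos: bool):
    row = logits_row.copy()
    row[vocab.pad_id] = -np.inf
    row[vocab.bos_id] = -np.inf
    row[vocab.unk_id] = -np.inf
    if not allow_eos:
        row[vocab.eos_id] = -np.inf
    return row


def generate_ids(
    state: ParaphraserState,
    text: str,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
    strategy: str = "greedy",
    seed: int = 0,
    beam_width: int = 4,
) -> List[int]:
    """Decode token ids for one input; content length in [min_len, max_len]."""
    if not text.split():
        raise ValueError("cannot generate from an empty input text")
    lo = state.min_len if min_len is None else min_len
    hi = state.max_len if max_len is None else max_len
    if not (1 <= lo <= hi):
        raise ValueError("decode bounds must satisfy 1 <= min_len <= max_len")
    vocab = state.vocab
    src = [vocab.encode(text)]
    src_ids, src_mask = _pad_batch(src, vocab.pad_id)
    h0 = encode_source(state.params, src_ids, src_mask, state.hidden)
    src_row = src_ids[0]

    def step(h: Tensor, token: int, pos: int) -> Tuple[Tensor, np.ndarray]:
        aligned = src_row[pos] if pos < len(src_row) else vocab.pad_id
        x = ad.gather_rows(state.params["emb"], np.array([token, aligned]))
        x = ad.reshape(x, (1, 2 * state.embed_dim))
        h2 = _gru_step(state.params, "dec", x, h, state.hidden)
        logits = (ad.matmul(h2, state.params["out_W"]) + state.params["out_b"]).data[0]
        return h2, logits

    if strategy == "greedy":
        out: List[int] = []
        h, token = h0, vocab.bos_id
        while len(out) < hi:
            h, logits = step(h, token, len(out))
            allow_eos = len(out) >= lo
            row = _decode_allowed(logits, vocab, allow_eos)
            token = int(np.argmax(row))
            if token == vocab.eos_id:
                break
            out.append(token)
        return out
    if strategy == "beam":
        # deterministic small-width beam search under the same length bounds
        beams: List[Tuple[float, List[int], Tensor, bool]] = [
            (0.0, [], h0, False)
        ]
        for _ in range(hi + 1):
            nxt: List[Tuple[float, List[int], Tensor, bool]] = []
            for lp, seq, h, done in beams:
                if done:
                    nxt.append((lp, seq, h, True))
                    continue
                prev = seq[-1] if seq else vocab.bos_id
                h2, logits = step(h, prev, len(seq))
                allow_eos = len(seq) >= lo
                row = _decode_allowed(logits, vocab, allow_eos)
                logp = row - _logsumexp(row)
                order = np.argsort(-logp, kind="stable")[:beam_width]
                for tok in order:
                    tok = int(tok)
                    if not np.isfinite(logp[tok]):
                        continue
                    if tok == vocab.eos_id or len(seq) + 1 >= hi:
                        ended = tok == vocab.eos_id
                        new_seq = seq if ended else seq + [tok]
                        nxt.append((lp + float(logp[tok]), new_seq, h2, True))
                    else:
                        nxt.append((lp + float(logp[tok]), seq + [tok], h2, False))
            nxt.sort(key=lambda b: (-b[0], b[1]))
            beams = nxt[:beam_width]
            if all(b[3] for b in beams):
                break
        return beams[0][1]
    raise ValueError(f"unknown decode strategy {strategy!r}")


def _logsumexp(row: np.ndarray) -> float:
    m = np.max(row[np.isfinite(row)])
    return m + np.log(np.sum(np.exp(row[np.isfinite(row)] - m)))


def generate(
    state: ParaphraserState,
    text: str,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
    strategy: str = "greedy",
    seed: int = 0,
) -> str:
    """Decode a paraphrase of ``text``; deterministic for greedy and beam."""
    ids = generate_ids(
        state, text, min_len=min_len, max_len=max_len, strategy=strategy, seed=seed
    )
    return state.vocab.decode(ids)


def decoder_distributions(
    state: ParaphraserState,
    src_texts: Sequence[str],
    decoded_ids: Sequence[Sequence[int]],
    params: Optional[Params] = None,
) -> Tuple[Tensor, np.ndarray]:
    """Per-position output distributions over V for given decodes.

    Re-runs the decoder with teacher forcing on the decoded tokens and
    returns (probs (B, T, V), mask (B, T)).  Differentiable in ``params``.
    """
    p = state.params if params is None else params
    vocab = state.vocab
    src = [vocab.encode(t) for t in src_texts]
    src_ids, src_mask = _pad_batch(src, vocab.pad_id)
    dec_ids, dec_mask = _pad_batch(list(decoded_ids), vocab.pad_id)
    h = encode_source(p, src_ids, src_mask, state.hidden)
    logits = decoder_logits(
        p, h, dec_ids, state.hidden, vocab.bos_id, src_ids, vocab.pad_id
    )
    return ad.softmax(logits, axis=-1), dec_mask


# ---------------------------------------------------------------------------
# classifier: embedding -> bi-LSTM -> dropout -> bi-LSTM -> dropout ->
#             ReLU dense -> softmax
# ---------------------------------------------------------------------------


@dataclass
class ClassifierState:
    params: Params
    vocab: Vocabulary
    label_count: int
    embed_dim: int
    hidden1: int
    hidden2: int
    dense: int = 20
    dropout1: float = 0.5
    dropout2: float = 0.5
    max_input_len: int = 128
    # "relu" is the reference stack; "tanh" keeps the loss surface smooth,
    # which the finite-difference meta-gradient prefers at desk scale
    dense_activation: str = "relu"

    def with_params(self, params: Params) -> "ClassifierState":
        return replace(self, params=params)

    def arch_spec(self) -> dict:
        return {
            "model": "bilstm_classifier",
            "vocab": self.vocab.size,
            "embed": self.embed_dim,
            "hidden1": self.hidden1,
            "hidden2": self.hidden2,
            "dense": self.dense,
            "labels": self.label_count,
        }


def init_classifier(
    vocab: Vocabulary,
    label_count: int,
    embed_dim: int = 64,
    hidden1: int = 64,
    hidden2: int = 32,
    dense: int = 20,
    dropout1: float = 0.5,
    dropout2: float = 0.5,
    max_input_len: int = 128,
    dense_activation: str = "relu",
    seed: int = 0,
) -> ClassifierState:
    if label_count < 2:
        raise ValueError("label_count must be >= 2")
    rng = np.random.default_rng(seed)
    V, E = vocab.size, embed_dim
    params: Params = {
        "emb": Tensor(rng.normal(0.0, 0.1, size=(V, E)), requires_grad=True)
    }
    for direction in ("f", "b"):
        params[f"l1{direction}_Wx"] = _uniform(rng, (E, 4 * hidden1), 1 / np.sqrt(E))
        params[f"l1{direction}_Wh"] = _uniform(
            rng, (hidden1, 4 * hidden1), 1 / np.sqrt(hidden1)
        )
        params[f"l1{direction}_b"] = _zeros(4 * hidden1)
        params[f"l2{direction}_Wx"] = _uniform(
            rng, (2 * hidden1, 4 * hidden2), 1 / np.sqrt(2 * hidden1)
        )
        params[f"l2{direction}_Wh"] = _uniform(
            rng, (hidden2, 4 * hidden2), 1 / np.sqrt(hidden2)
        )
        params[f"l2{direction}_b"] = _zeros(4 * hidden2)
    params["d_W"] = _uniform(rng, (2 * hidden2, dense), 1 / np.sqrt(2 * hidden2))
    params["d_b"] = _zeros(dense)
    params["o_W"] = _uniform(rng, (dense, label_count), 1 / np.sqrt(dense))
    params["o_b"] = _zeros(label_count)
    return ClassifierState(
        params=params,
        vocab=vocab,
        label_count=label_count,
        embed_dim=embed_dim,
        hidden1=hidden1,
        hidden2=hidden2,
        dense=dense,
        dropout1=dropout1,
        dropout2=dropout2,
        max_input_len=max_input_len,
        dense_activation=dense_activation,
    )


def _lstm_step(
    params: Params, prefix: str, x: Tensor, h: Tensor, c: Tensor, H: int
) -> Tuple[Tensor, Tensor]:
    g = ad.matmul(x, params[prefix + "_Wx"]) + ad.matmul(
        h, params[prefix + "_Wh"]
    ) + params[prefix + "_b"]
    i = ad.sigmoid(g[:, :H])
    f = ad.sigmoid(g[:, H : 2 * H])
    gg = ad.tanh(g[:, 2 * H : 3 * H])
    o = ad.sigmoid(g[:, 3 * H :])
    c2 = f * c + i * gg
    h2 = o * ad.tanh(c2)
    return h2, c2


def _bilstm_sequence(
    params: Params,
    layer: str,
    X: List[Tensor],
    mask: np.ndarray,
    H: int,
) -> Tuple[List[Tensor], Tensor]:
    """Run both directions over a list of (B, E) inputs.

    Returns per-step concatenated outputs and the concatenated final states
    (forward state after the last valid token, backward state after
    position 0).
    """
    B = X[0].shape[0]
    T = len(X)
    hf = cf = Tensor(np.zeros((B, H)))
    fwd: List[Tensor] = []
    for t in range(T):
        m = Tensor(mask[:, t : t + 1])
        h2, c2 = _lstm_step(params, layer + "f", X[t], hf, cf, H)
        hf, cf = _masked(h2, hf, m), _masked(c2, cf, m)
        fwd.append(hf)
    hb = cb = Tensor(np.zeros((B, H)))
    bwd: List[Optional[Tensor]] = [None] * T
    for t in reversed(range(T)):
        m = Tensor(mask[:, t : t + 1])
        h2, c2 = _lstm_step(params, layer + "b", X[t], hb, cb, H)
        hb, cb = _masked(h2, hb, m), _masked(c2, cb, m)
        bwd[t] = hb
    seq = [ad.concat([fwd[t], bwd[t]], axis=1) for t in range(T)]
    final = ad.concat([fwd[-1], bwd[0]], axis=1)
    return seq, final


def _classifier_logits_from_embedded(
    state: ClassifierState,
    X: List[Tensor],
    mask: np.ndarray,
    params: Params,
    mode: str,
    rng: Optional[np.random.Generator],
) -> Tensor:
    training = mode == "train"
    if training and rng is None:
        raise ValueError("training-mode forward requires an rng for dropout")
    seq1, _ = _bilstm_sequence(params, "l1", X, mask, state.hidden1)
    seq1 = [ad.dropout(h, state.dropout1, rng, training) for h in seq1]
    _, final = _bilstm_sequence(params, "l2", seq1, mask, state.hidden2)
    final = ad.dropout(final, state.dropout2, rng, training)
    act = ad.relu if state.dense_activation == "relu" else ad.tanh
    hidden = act(ad.matmul(final, params["d_W"]) + params["d_b"])
    return ad.matmul(hidden, params["o_W"]) + params["o_b"]


def classifier_logits(
    state: ClassifierState,
    texts: Sequence[str],
    params: Optional[Params] = None,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    p = state.params if params is None else params
    vocab = state.vocab
    enc = [vocab.encode(t)[: state.max_input_len] or [vocab.unk_id] for t in texts]
    ids, mask = _pad_batch(enc, vocab.pad_id)
    X_all = _embed(p["emb"], ids)
    X = [X_all[:, t, :] for t in range(ids.shape[1])]
    return _classifier_logits_from_embedded(state, X, mask, p, mode, rng)


def classifier_logits_soft(
    state: ClassifierState,
    probs: Tensor,
    mask: np.ndarray,
    params: Optional[Params] = None,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """Forward from per-position token distributions (B, T, V).

    The embedding lookup is replaced by the expectation of the embedding
    rows under each distribution, so the result is differentiable in
    whatever produced ``probs`` (the paraphraser) as well as in the
    classifier parameters.
    """
    p = state.params if params is None else params
    B, T, V = probs.shape
    if V != state.vocab.size:
        raise ValueError("distribution width does not match classifier vocabulary")
    flat = ad.reshape(probs, (B * T, V))
    X_all = ad.reshape(ad.matmul(flat, p["emb"]), (B, T, state.embed_dim))
    X = [X_all[:, t, :] for t in range(T)]
    return _classifier_logits_from_embedded(state, X, mask, p, mode, rng)


def _ce_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = ad.log_softmax(logits, axis=-1)
    return ad.neg(ad.tmean(ad.take_rowwise(logp, labels)))


def classifier_loss(
    state: ClassifierState,
    data: Sequence[Tuple[str, int]],
    params: Optional[Params] = None,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """Mean cross-entropy of (text, label) records; differentiable in C."""
    if not data:
        raise ValueError("empty classification batch")
    texts = [t for t, _ in data]
    labels = np.array([y for _, y in data], dtype=np.int64)
    if labels.min() < 0 or labels.max() >= state.label_count:
        raise ValueError("label out of range for this classifier")
    logits = classifier_logits(state, texts, params=params, mode=mode, rng=rng)
    return _ce_from_logits(logits, labels)


def soft_classifier_loss_from_probs(
    state: ClassifierState,
    probs: Tensor,
    mask: np.ndarray,
    labels: Sequence[int],
    params: Optional[Params] = None,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    labels = np.asarray(labels, dtype=np.int64)
    logits = classifier_logits_soft(
        state, probs, mask, params=params, mode=mode, rng=rng
    )
    return _ce_from_logits(logits, labels)


def soft_generated_loss(
    C: ClassifierState,
    S: ParaphraserState,
    examples: Sequence,
    c_params: Optional[Params] = None,
    s_params: Optional[Params] = None,
    decoded_ids: Optional[List[List[int]]] = None,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """Classifier loss on paraphrased examples, differentiable in C *and* S.

    Greedy-decodes each example (unless decodes are supplied), re-runs the
    decoder with teacher forcing on the decoded tokens, and feeds the
    resulting per-position distributions to the classifier through the
    expected-embedding path.  Labels are inherited from the sources.
    """
    if C.vocab is not S.vocab and C.vocab.content_hash() != S.vocab.content_hash():
        raise ValueError("paraphraser and classifier must share a vocabulary")
    texts = [ex.text for ex in examples]
    labels = [ex.label for ex in examples]
    if decoded_ids is None:
        decoded_ids = [generate_ids(S, t) for t in texts]
    probs, mask = decoder_distributions(S, texts, decoded_ids, params=s_params)
    return soft_classifier_loss_from_probs(
        C, probs, mask, labels, params=c_params, mode=mode, rng=rng
    )


def combined_classifier_loss(
    C: ClassifierState,
    train_data: Sequence[Tuple[str, int]],
    generated_loss: Tensor,
    gamma: float = 0.85,
    only_aug: bool = False,
    params: Optional[Params] = None,
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """L(C, D) + gamma * L(C, G(D, S')) — the stage-II objective.

    In the generated-data-only ablation the original-data term (and its
    gamma tradeoff) is dropped and the generated loss stands alone.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if only_aug:
        return generated_loss
    base = classifier_loss(C, train_data, params=params, mode=mode, rng=rng)
    return base + gamma * generated_loss


def predict_proba(
    state: ClassifierState, texts: Sequence[str], batch_size: int = 64
) -> np.ndarray:
    out = []
    for i in range(0, len(texts), batch_size):
        logits = classifier_logits(state, texts[i : i + batch_size])
        out.append(ad.softmax(logits, axis=-1).data)
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def _params_to_json(params: Params) -> dict:
    return {k: v.data.tolist() for k, v in params.items()}


def _params_from_json(d: dict) -> Params:
    return {k: Tensor(np.array(v), requires_grad=True) for k, v in d.items()}


def save_paraphraser(state: ParaphraserState, path) -> None:
    spec = state.arch_spec()
    payload = {
        "version": CHECKPOINT_VERSION,
        "kind": "paraphraser",
        "arch": spec,
        "arch_hash": _arch_hash(spec),
        "vocab_hash": state.vocab.content_hash(),
        "vocab_tokens": state.vocab._id_to_token[4:],
        "min_len": state.min_len,
        "max_len": state.max_len,
        "params": _params_to_json(state.params),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_paraphraser(path) -> ParaphraserState:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("kind") != "paraphraser":
        raise ValueError("not a paraphraser checkpoint")
    vocab = Vocabulary(payload["vocab_tokens"])
    if vocab.content_hash() != payload["vocab_hash"]:
        raise ValueError("vocabulary hash mismatch in checkpoint")
    arch = payload["arch"]
    return ParaphraserState(
        params=_params_from_json(payload["params"]),
        vocab=vocab,
        embed_dim=arch["embed"],
        hidden=arch["hidden"],
        min_len=payload["min_len"],
        max_len=payload["max_len"],
    )


def save_classifier(state: ClassifierState, path) -> None:
    spec = state.arch_spec()
    payload = {
        "version": CHECKPOINT_VERSION,
        "kind": "classifier",
        "arch": spec,
        "arch_hash": _arch_hash(spec),
        "vocab_hash": state.vocab.content_hash(),
        "vocab_tokens": state.vocab._id_to_token[4:],
        "dropout1": state.dropout1,
        "dropout2": state.dropout2,
        "max_input_len": state.max_input_len,
        "dense_activation": state.dense_activation,
        "params": _params_to_json(state.params),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_classifier(path) -> ClassifierState:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("kind") != "classifier":
        raise ValueError("not a classifier checkpoint")
    vocab = Vocabulary(payload["vocab_tokens"])
    if vocab.content_hash() != payload["vocab_hash"]:
        raise ValueError("vocabulary hash mismatch in checkpoint")
    arch = payload["arch"]
    return ClassifierState(
        params=_params_from_json(payload["params"]),
        vocab=vocab,
        label_count=arch["labels"],
        embed_dim=arch["embed"],
        hidden1=arch["hidden1"],
        hidden2=arch["hidden2"],
        dense=arch["dense"],
        dropout1=payload["dropout1"],
        dropout2=payload["dropout2"],
        max_input_len=payload["max_input_len"],
        dense_activation=payload.get("dense_activation", "relu"),
    )
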