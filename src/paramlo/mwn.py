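"""Meta-weight network: a scalar-loss -> data-weight MLP.

The network maps the teacher-forcing loss of one paraphrase training pair
to a weight in (0, 1) that scales that pair's contribution to the
paraphraser's training objective.  Architecture: 1 -> h -> h -> 1 with
dropout after the second hidden layer and a terminal sigmoid bounding the
output; default h = 25, dropout 0.2.  Hidden activations default to tanh
(smooth everywhere, so the symmetric-perturbation meta-gradient sees the
curvature it is estimating); ReLU is available behind a flag.

Initialisation uses small random weights and zero biases, so initial
weights cluster at 0.5: no training pair is favoured before any feedback
has been observed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Dict, Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

CHECKPOINT_VERSION = 1


@dataclass
class MWNParams:
    params: Dict[str, Tensor]
    hidden: int
    dropout_rate: float = 0.2
    mode: str = "eval"
    # tanh keeps the weight map twice differentiable, which the
    # finite-difference meta-gradient relies on; relu is available
    hidden_activation: str = "tanh"

    def with_params(self, params: Dict[str, Tensor]) -> "MWNParams":
        return replace(self, params=params)

    def parameter_count(self) -> int:
        return sum(int(v.data.size) for v in self.params.values())


def mwn_init(
    hidden: int = 25,
    dropout: float = 0.2,
    seed: int = 0,
    hidden_activation: str = "tanh",
    init_scale: float = 0.01,
) -> MWNParams:
    """Deterministically initialise a 1 -> hidden -> hidden -> 1 network.

    Biases start at zero so the map outputs exactly 0.5 at a zero input
    (no example favoured a priori).  ``init_scale`` sets the weight std;
    a very small scale makes the initial parameter-gradient almost
    input-independent (the network can then learn a constant shift long
    before any input-dependent profile), so meta-training profiles may
    prefer a larger value.
    """
    if hidden < 1:
        raise ValueError("hidden width must be >= 1")
    if not (0.0 <= dropout < 1.0):
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    scale = init_scale
    params = {
        "W1": Tensor(rng.normal(0, scale, size=(1, hidden)), requires_grad=True),
        "b1": Tensor(np.zeros(hidden), requires_grad=True),
        "W2": Tensor(rng.normal(0, scale, size=(hidden, hidden)), requires_grad=True),
        "b2": Tensor(np.zeros(hidden), requires_grad=True),
        "W3": Tensor(rng.normal(0, scale, size=(hidden, 1)), requires_grad=True),
        "b3": Tensor(np.zeros(1), requires_grad=True),
    }
    if hidden_activation not in ("tanh", "relu"):
        raise ValueError("hidden_activation must be 'tanh' or 'relu'")
    return MWNParams(
        params=params,
        hidden=hidden,
        dropout_rate=dropout,
        hidden_activation=hidden_activation,
    )


def loss_stats(losses: np.ndarray) -> tuple:
    """(mean, std) used to standardize weight-network inputs.

    The std is floored at 0.1 nat: when a batch's losses are nearly
    identical their ordering is noise, and an unfloored denominator would
    amplify that noise (and the gradients flowing through it) without
    bound.
    """
    a = np.asarray(losses, dtype=np.float64)
    return float(a.mean()), float(max(a.std(), 0.1))


def mwn_forward(
    mwn: MWNParams,
    losses: Union[Tensor, np.ndarray],
    mode: str = "eval",
    rng: Optional[np.random.Generator] = None,
    params: Optional[Dict[str, Tensor]] = None,
    standardize: bool = False,
    stats: Optional[tuple] = None,
) -> Tensor:
    """Map a vector of per-example losses to weights in (0, 1).

    In eval mode the map is deterministic and element-wise: the i-th weight
    depends only on the i-th loss.  Train mode applies dropout and needs an
    rng.

    With ``standardize`` the input is z-scored first, using ``stats`` (a
    (mean, std) pair) or, if absent, the batch's own statistics treated as
    constants.  Standardization removes the common-mode component of the
    meta-gradient — the raw losses of a batch cluster tightly around their
    mean, so without it every parameter's gradient is dominated by the
    shared "average usefulness" signal and the network can only learn a
    constant shift, never the loss-dependent profile.
    """
    if not isinstance(losses, Tensor):
        losses = Tensor(np.asarray(losses, dtype=np.float64))
    if not np.all(np.isfinite(losses.data)):
        raise ValueError("losses fed to the weight network must be finite")
    p = mwn.params if params is None else params
    n = losses.data.size
    act = ad.tanh if mwn.hidden_activation == "tanh" else ad.relu
    if standardize:
        mu, sd = loss_stats(losses.data) if stats is None else stats
        losses = (losses - mu) * (1.0 / sd)
    x = ad.reshape(losses, (n, 1))
    h1 = act(ad.matmul(x, p["W1"]) + p["b1"])
    h2 = act(ad.matmul(h1, p["W2"]) + p["b2"])
    training = mode == "train"
    if training and rng is None:
        raise ValueError("train-mode forward requires an rng for dropout")
    h2 = ad.dropout(h2, mwn.dropout_rate, rng, training)
    out = ad.sigmoid(ad.matmul(h2, p["W3"]) + p["b3"])
    return ad.reshape(out, (n,))


def save_mwn(mwn: MWNParams, path) -> None:
    payload = {
        "version": CHECKPOINT_VERSION,
        "kind": "mwn",
        "hidden": mwn.hidden,
        "dropout": mwn.dropout_rate,
        "hidden_activation": mwn.hidden_activation,
        "params": {k: v.data.tolist() for k, v in mwn.params.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_mwn(path) -> MWNParams:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("kind") != "mwn":
        raise ValueError("not a meta-weight-network checkpoint")
    params = {
        k: Tensor(np.array(v), requires_grad=True)
        for k, v in payload["params"].items()
    }
    return MWNParams(
        params=params,
        hidden=payload["hidden"],
        dropout_rate=payload["dropout"],
        hidden_activation=payload.get("hidden_activation", "tanh"),
    )
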