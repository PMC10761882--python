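"""Shared fixtures: the synthetic task and tiny model instances."""

import numpy as np
import pytest

from paramlo.config import MLOConfig
from paramlo.data import split_mlo
from paramlo.models import init_classifier, init_paraphraser
from paramlo.mwn import mwn_init
from paramlo.synthetic import SyntheticSpec, make_synthetic_task


@pytest.fixture(scope="session")
def task():
    """Default synthetic two-domain task (paraphrase corpus, splits, vocab)."""
    spec = SyntheticSpec(seed=0)
    pcorp, corpora, vocab = make_synthetic_task(spec)
    return {"spec": spec, "pairs": pcorp, "corpora": corpora, "vocab": vocab}


@pytest.fixture(scope="session")
def test_config():
    return MLOConfig.test_profile(seed=0)


@pytest.fixture(scope="session")
def mlo_split(task):
    tr, va = split_mlo(task["corpora"]["train"], seed=0)
    return tr, va


@pytest.fixture()
def tiny_models(task, test_config):
    """Fresh tiny paraphraser/classifier/weight-network triple."""
    cfg = test_config
    vocab = task["vocab"]
    S = init_paraphraser(
        vocab, cfg.s_embed, cfg.s_hidden, cfg.min_len, cfg.max_len, seed=11
    )
    C = init_classifier(
        vocab,
        label_count=2,
        embed_dim=cfg.c_embed,
        hidden1=cfg.c_hidden1,
        hidden2=cfg.c_hidden2,
        dense=cfg.c_dense,
        dense_activation="tanh",
        seed=12,
    )
    W = mwn_init(cfg.mwn_hidden, cfg.mwn_dropout, seed=13)
    return S, C, W


def random_mwn(hidden=25, seed=0, scale=0.5):
    """An MWN with O(1) random weights (a 'trained-like' random instance)."""
    from paramlo.autodiff import Tensor

    W = mwn_init(hidden, 0.2, seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    for k, v in W.params.items():
        W.params[k] = Tensor(
            rng.normal(0.0, scale, size=v.data.shape), requires_grad=True
        )
    return W
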