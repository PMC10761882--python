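"""Optimization engine: stage updates, hypergradients, training loop."""

import numpy as np
import pytest
from dataclasses import replace

import paramlo.autodiff as ad
from paramlo.autodiff import Tensor
from paramlo.config import MLOConfig, OptimizerSettings
from paramlo.engine import (
    Optimizer,
    augment_dataset,
    exact_hypergradient_oracle,
    fd_hypergradient,
    finetune,
    mwn_update,
    stage1_update,
    stage2_update,
    train_mlo,
)
from paramlo.models import (
    classifier_loss,
    flatten_params,
    generate_ids,
    params_checksum,
)
from paramlo.mwn import mwn_init


def _batches(task, n=4, seed=0):
    rng = np.random.default_rng(seed)
    pairs = list(task["pairs"])
    trn = list(task["corpora"]["train"])
    val = list(task["corpora"]["val"])
    pb = [pairs[i] for i in rng.choice(len(pairs), n, replace=False)]
    cb = [trn[i] for i in rng.choice(len(trn), n, replace=False)]
    vb = [val[i] for i in rng.choice(len(val), n, replace=False)]
    return pb, cb, vb


# -- optimizer --------------------------------------------------------------


def test_sgd_step_is_plain_arithmetic():
    opt = Optimizer(OptimizerSettings(name="sgd", lr=0.1))
    params = {"w": Tensor(np.array([1.0, 2.0]), requires_grad=True)}
    out = opt.step(params, {"w": np.array([0.5, -1.0])})
    assert np.allclose(out["w"].data, [0.95, 2.1])


def test_adamw_first_step_magnitude_and_decay():
    """First Adam step is lr * g/|g| per coordinate; decoupled decay adds
    lr * wd * w."""
    opt = Optimizer(OptimizerSettings(lr=0.01, weight_decay=0.1))
    params = {"w": Tensor(np.array([1.0]), requires_grad=True)}
    out = opt.step(params, {"w": np.array([5.0])})
    expected = 1.0 - 0.01 * (1.0 / (1.0 + 1e-8 / np.sqrt(1 - 0.999))) - 0.01 * 0.1 * 1.0
    assert out["w"].data[0] == pytest.approx(expected, rel=1e-6)


def test_default_optimizer_settings_match_protocol():
    s = OptimizerSettings()
    assert (s.beta1, s.beta2, s.eps) == (0.9, 0.999, 1e-8)


# -- stage updates ----------------------------------------------------------


def test_stage1_zero_rate_is_identity(task, tiny_models):
    S, _, W = tiny_models
    pb, _, _ = _batches(task)
    before = params_checksum(S.params)
    S1, loss, losses, weights, _ = stage1_update(S, W, pb, eta_s=0.0)
    assert params_checksum(S1.params) == before
    assert loss == pytest.approx(float((losses * weights).sum()))


def test_stage1_functional_purity_and_w_frozen(task, tiny_models):
    """Stage I must neither modify S in place nor ever touch W."""
    S, _, W = tiny_models
    pb, _, _ = _batches(task)
    s_before = params_checksum(S.params)
    w_before = params_checksum(W.params)
    S1, *_ = stage1_update(S, W, pb, eta_s=0.1)
    assert params_checksum(S.params) == s_before
    assert params_checksum(W.params) == w_before
    assert params_checksum(S1.params) != s_before


def test_stage1_matches_independent_gradient_step(task, tiny_models):
    """S' equals S - eta * g with g from a separate autodiff pass."""
    from paramlo.models import weighted_paraphrase_loss

    S, _, W = tiny_models
    pb, _, _ = _batches(task, n=1)
    eta = 0.05
    S1, *_ = stage1_update(S, W, pb, eta_s=eta)
    total, _, _ = weighted_paraphrase_loss(S, W, pb)
    keys = sorted(S.params)
    gs = ad.grad(total, [S.params[k] for k in keys])
    for k, g in zip(keys, gs):
        assert np.allclose(S1.params[k].data, S.params[k].data - eta * g.data)


def test_stage2_zero_rate_and_gamma_zero(task, tiny_models):
    S, C, _ = tiny_models
    _, cb, _ = _batches(task)
    C_id, *_ = stage2_update(C, S, cb, gamma=0.85, eta_c=0.0)
    assert params_checksum(C_id.params) == params_checksum(C.params)

    # gamma=0 reduces to a plain supervised step
    C0, *_ = stage2_update(C, S, cb, gamma=0.0, eta_c=0.2)
    records = [(ex.text, ex.label) for ex in cb]
    loss = classifier_loss(C, records)
    keys = sorted(C.params)
    gs = ad.grad(loss, [C.params[k] for k in keys])
    for k, g in zip(keys, gs):
        assert np.allclose(C0.params[k].data, C.params[k].data - 0.2 * g.data)


def test_stage2_matches_independent_combined_gradient(task, tiny_models):
    from paramlo.models import soft_generated_loss

    S, C, _ = tiny_models
    _, cb, _ = _batches(task, n=2)
    dec = [generate_ids(S, ex.text) for ex in cb]
    C1, _, _, _ = stage2_update(C, S, cb, gamma=0.85, eta_c=0.1, decoded_ids=dec)
    records = [(ex.text, ex.label) for ex in cb]
    total = classifier_loss(C, records) + 0.85 * soft_generated_loss(
        C, S, cb, decoded_ids=dec
    )
    keys = sorted(C.params)
    gs = ad.grad(total, [C.params[k] for k in keys])
    for k, g in zip(keys, gs):
        assert np.allclose(C1.params[k].data, C.params[k].data - 0.1 * g.data)


# -- hypergradients ---------------------------------------------------------


def test_fd_gamma_zero_gives_zero_gradient(task, tiny_models, test_config):
    S, C, W = tiny_models
    pb, cb, vb = _batches(task)
    cfg = replace(test_config, gamma=0.0)
    res = fd_hypergradient(W, S, C, pb, cb, vb, cfg)
    assert not res.degenerate
    assert np.allclose(res.flat(), 0.0)


def test_fd_vanishing_val_gradient_flags_degenerate(task, tiny_models, test_config):
    """A saturated (perfectly fit) meta-val batch must yield a flagged
    zero hypergradient, never a division error."""
    S, C, W = tiny_models
    pb, cb, vb = _batches(task)
    # saturate the output layer so softmax gradients underflow to zero
    C.params["o_b"] = Tensor(np.array([1e4, -1e4]), requires_grad=True)
    C.params["o_W"] = Tensor(np.zeros_like(C.params["o_W"].data), requires_grad=True)
    vb0 = [ex for ex in vb if ex.label == 0] or vb[:1]
    res = fd_hypergradient(W, S, C, pb, cb, vb0, test_config)
    assert res.degenerate
    assert np.allclose(res.flat(), 0.0)


def test_oracle_gamma_zero_and_eta_s_zero_are_zero(task, tiny_models, test_config):
    S, C, W = tiny_models
    pb, cb, vb = _batches(task)
    for cfg in (replace(test_config, gamma=0.0), replace(test_config, eta_s=0.0)):
        g = exact_hypergradient_oracle(W, S, C, pb, cb, vb, cfg)
        flat = np.concatenate([np.ravel(g[k]) for k in sorted(g)])
        assert np.allclose(flat, 0.0, atol=1e-18)


def test_oracle_size_guard(task, tiny_models, test_config):
    S, C, W = tiny_models
    pb, cb, vb = _batches(task)
    with pytest.raises(ValueError, match="guard"):
        exact_hypergradient_oracle(
            W, S, C, pb, cb, vb, test_config, size_guard=10
        )


def test_fd_agrees_with_oracle_on_one_instance(task, test_config):
    from tests.conftest import random_mwn
    from paramlo.models import init_classifier, init_paraphraser

    cfg = test_config
    vocab = task["vocab"]
    S = init_paraphraser(vocab, cfg.s_embed, cfg.s_hidden, cfg.min_len, cfg.max_len, seed=21)
    C = init_classifier(
        vocab, 2, cfg.c_embed, cfg.c_hidden1, cfg.c_hidden2, cfg.c_dense,
        dense_activation="tanh", seed=22,
    )
    W = random_mwn(seed=23)
    pb, cb, vb = _batches(task, seed=24)
    S1, *_ = stage1_update(S, W, pb, cfg.eta_s)
    dec = [generate_ids(S1, ex.text) for ex in cb]
    res = fd_hypergradient(W, S, C, pb, cb, vb, cfg, decoded_ids=dec)
    oracle = exact_hypergradient_oracle(W, S, C, pb, cb, vb, cfg, decoded_ids=dec)
    f = res.flat()
    o = np.concatenate([np.ravel(oracle[k]) for k in sorted(oracle)])
    cos = f @ o / (np.linalg.norm(f) * np.linalg.norm(o))
    assert cos > 0.99


def test_printed_prefactor_doubles_the_estimate(task, test_config):
    from tests.conftest import random_mwn
    from paramlo.models import init_classifier, init_paraphraser

    cfg = test_config
    vocab = task["vocab"]
    S = init_paraphraser(vocab, cfg.s_embed, cfg.s_hidden, cfg.min_len, cfg.max_len, seed=31)
    C = init_classifier(
        vocab, 2, cfg.c_embed, cfg.c_hidden1, cfg.c_hidden2, cfg.c_dense,
        dense_activation="tanh", seed=32,
    )
    W = random_mwn(seed=33)
    pb, cb, vb = _batches(task, seed=34)
    S1, *_ = stage1_update(S, W, pb, cfg.eta_s)
    dec = [generate_ids(S1, ex.text) for ex in cb]
    central = fd_hypergradient(W, S, C, pb, cb, vb, cfg, decoded_ids=dec).flat()
    printed = fd_hypergradient(
        W, S, C, pb, cb, vb, replace(cfg, fd_prefactor="printed"), decoded_ids=dec
    ).flat()
    assert np.allclose(printed, 2.0 * central, rtol=1e-9)


def test_mwn_update_sgd_arithmetic_and_zero_rate():
    W = mwn_init(hidden=3, seed=0)
    grads = {k: np.ones_like(v.data) for k, v in W.params.items()}
    before = {k: v.data.copy() for k, v in W.params.items()}
    W2 = mwn_update(W, grads, Optimizer(OptimizerSettings(name="sgd", lr=0.5)))
    for k in before:
        assert np.allclose(W2.params[k].data, before[k] - 0.5)
    W3 = mwn_update(W, grads, Optimizer(OptimizerSettings(name="sgd", lr=0.0)))
    for k in before:
        assert np.allclose(W3.params[k].data, before[k])
    with pytest.raises(FloatingPointError):
        mwn_update(W, {k: g * np.nan for k, g in grads.items()},
                   Optimizer(OptimizerSettings(name="sgd", lr=0.1)))


# -- training loop ----------------------------------------------------------


def _short_cfg(seed=0, **kw):
    return MLOConfig.test_profile(seed=seed, mlo_epochs=2, finetune_epochs=2, **kw)


def test_para_sep_freezes_weight_network(task, mlo_split):
    tr, va = mlo_split
    cfg = _short_cfg(para_sep=True)
    _, _, W, hist = train_mlo(
        cfg, task["pairs"], tr, va, task["corpora"]["train"], vocab=task["vocab"]
    )
    fresh = train_mlo(
        cfg, task["pairs"], tr, va, task["corpora"]["train"], vocab=task["vocab"]
    )[2]
    assert params_checksum(W.params) == params_checksum(fresh.params)
    # and it matches a freshly initialised network under the same seed
    assert all(r["hypergrad_norm"] == 0.0 for r in hist.records)


def test_only_aug_drops_original_term(task, mlo_split, tiny_models):
    S, C, _ = tiny_models
    _, cb, _ = _batches(task, n=3)
    dec = [generate_ids(S, ex.text) for ex in cb]
    from paramlo.models import soft_generated_loss

    _, loss_only, _, _ = stage2_update(
        C, S, cb, gamma=0.85, eta_c=0.1, only_aug=True, decoded_ids=dec
    )
    gen = soft_generated_loss(C, S, cb, decoded_ids=dec).item()
    assert loss_only == pytest.approx(gen, rel=1e-10)


def test_training_history_is_complete_and_monotone(task, mlo_split):
    tr, va = mlo_split
    cfg = _short_cfg()
    _, _, _, hist = train_mlo(
        cfg, task["pairs"], tr, va, task["corpora"]["train"], vocab=task["vocab"]
    )
    its = [r["iteration"] for r in hist.records]
    assert its == list(range(len(its)))
    required = {
        "stage1_loss", "stage2_loss", "mlo_val_loss",
        "mwn_weight_mean", "mwn_weight_min", "mwn_weight_max",
        "hypergrad_norm",
    }
    assert all(required <= set(r) for r in hist.records)


def test_train_mlo_seeded_determinism_short(task, mlo_split):
    tr, va = mlo_split
    cfg = _short_cfg(seed=3)
    h1 = train_mlo(
        cfg, task["pairs"], tr, va, task["corpora"]["train"], vocab=task["vocab"]
    )[3]
    h2 = train_mlo(
        cfg, task["pairs"], tr, va, task["corpora"]["train"], vocab=task["vocab"]
    )[3]
    assert h1.to_json() == h2.to_json()


def test_candidate_commit_mode_runs(task, mlo_split):
    tr, va = mlo_split
    cfg = _short_cfg(commit="candidate", eta_c=0.3)
    C, S, W, hist = train_mlo(
        cfg, task["pairs"], tr, va, task["corpora"]["train"], vocab=task["vocab"]
    )
    assert len(hist.records) > 0


# -- augmentation and fine-tuning ------------------------------------------


def test_augment_cardinality_labels_and_determinism(task, tiny_models):
    S, _, _ = tiny_models
    corpus = task["corpora"]["val"]
    gen = augment_dataset(S, corpus)
    assert len(gen) == len(corpus)
    by_id = {ex.id: ex.label for ex in corpus}
    for g in gen:
        assert g.label == by_id[g.source_id]
    again = augment_dataset(S, corpus)
    assert [g.text for g in gen] == [g.text for g in again]


def test_finetune_zero_epochs_identity_and_loss_decreases(task, tiny_models):
    _, C, _ = tiny_models
    train = task["corpora"]["train"]
    same = finetune(C, train, epochs=0)
    assert same is C
    from paramlo.engine import TrainingHistory

    hist = TrainingHistory()
    rng = np.random.default_rng(0)
    finetune(C, train, epochs=5, batch_size=8, rng=rng, history=hist)
    means = [r["mean_train_loss"] for r in hist.epoch_records]
    assert means[-1] < means[0]


def test_finetune_default_epoch_count():
    import inspect

    from paramlo.engine import finetune as ft

    assert inspect.signature(ft).parameters["epochs"].default == 20
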