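"""Model contracts: losses, generation bounds, the soft decode path."""

import numpy as np
import pytest

import paramlo.autodiff as ad
from paramlo.autodiff import Tensor
from paramlo.data import LabeledExample, ParaphrasePair
from paramlo.models import (
    Vocabulary,
    classifier_logits,
    classifier_loss,
    combined_classifier_loss,
    decoder_distributions,
    generate,
    generate_ids,
    init_classifier,
    init_paraphraser,
    load_classifier,
    load_paraphraser,
    paraphrase_loss_vector,
    predict_proba,
    save_classifier,
    save_paraphraser,
    soft_classifier_loss_from_probs,
    soft_generated_loss,
    teacher_forcing_loss,
    weighted_paraphrase_loss,
)
from paramlo.mwn import mwn_init


@pytest.fixture(scope="module")
def vocab():
    return Vocabulary([f"w{i:02d}" for i in range(26)])


@pytest.fixture()
def tiny_s(vocab):
    return init_paraphraser(vocab, embed_dim=6, hidden=8, min_len=1, max_len=8, seed=0)


@pytest.fixture()
def tiny_c(vocab):
    return init_classifier(
        vocab, label_count=2, embed_dim=6, hidden1=5, hidden2=4, dense=7, seed=1
    )


# -- vocabulary -------------------------------------------------------------


def test_vocabulary_bijective_with_distinct_specials(vocab):
    ids = [vocab.encode(vocab.token(i))[0] for i in range(4, vocab.size)]
    assert ids == list(range(4, vocab.size))
    assert len({vocab.pad_id, vocab.bos_id, vocab.eos_id, vocab.unk_id}) == 4
    assert vocab.encode("never-seen-token") == [vocab.unk_id]


# -- teacher forcing --------------------------------------------------------


def test_uniform_model_loss_is_log_vocab(vocab, tiny_s):
    """Zeroed parameters give a uniform softmax, so the loss is ln V."""
    for k, v in tiny_s.params.items():
        tiny_s.params[k] = Tensor(np.zeros_like(v.data), requires_grad=True)
    pair = ParaphrasePair("p", "w00 w01", "w02 w03")
    loss = teacher_forcing_loss(tiny_s, pair)
    assert loss.item() == pytest.approx(np.log(vocab.size), abs=1e-6)


def test_teacher_forcing_matches_enumerated_softmax_terms(vocab, tiny_s):
    """Per-token NLL equals a hand-computed -(1/T) sum log p on 3 tokens."""
    pair = ParaphrasePair("p", "w00 w05 w09", "w01 w06 w10")
    loss = teacher_forcing_loss(tiny_s, pair).item()

    from paramlo.models import decoder_logits, encode_source, _pad_batch

    src_ids, src_mask = _pad_batch([vocab.encode(pair.source_text)], vocab.pad_id)
    tgt = vocab.encode(pair.target_text) + [vocab.eos_id]
    tgt_ids, _ = _pad_batch([tgt], vocab.pad_id)
    h = encode_source(tiny_s.params, src_ids, src_mask, tiny_s.hidden)
    logits = decoder_logits(
        tiny_s.params, h, tgt_ids, tiny_s.hidden, vocab.bos_id, src_ids, vocab.pad_id
    ).data[0]
    expected = 0.0
    for t, tok in enumerate(tgt):
        z = logits[t] - logits[t].max()
        p = np.exp(z) / np.exp(z).sum()
        expected -= np.log(p[tok])
    assert loss == pytest.approx(expected / len(tgt), rel=1e-10)


def test_loss_vector_matches_single_pair_calls(vocab, tiny_s):
    pairs = [
        ParaphrasePair("a", "w00 w01 w02", "w03 w04"),
        ParaphrasePair("b", "w10", "w11 w12 w13 w14"),
    ]
    batched = paraphrase_loss_vector(tiny_s, pairs).data
    singles = [teacher_forcing_loss(tiny_s, p).item() for p in pairs]
    assert np.allclose(batched, singles, rtol=1e-10)


def test_weighted_loss_is_weight_dot_loss(vocab, tiny_s):
    pairs = [
        ParaphrasePair("a", "w00 w01", "w02"),
        ParaphrasePair("b", "w03 w04", "w05 w06"),
    ]
    W = mwn_init(hidden=5, seed=2)
    total, losses, weights = weighted_paraphrase_loss(tiny_s, W, pairs)
    assert total.item() == pytest.approx(
        float((losses.data * weights.data).sum()), rel=1e-12
    )
    total_mean, _, _ = weighted_paraphrase_loss(
        tiny_s, W, pairs, reduction="mean"
    )
    assert total_mean.item() == pytest.approx(total.item() / 2, rel=1e-12)


def test_zero_losses_give_zero_weighted_total(vocab, tiny_s):
    """If every per-pair loss is 0 the weighted sum is 0 regardless of W."""
    W = mwn_init(hidden=5, seed=2)
    losses = Tensor(np.zeros(3))
    from paramlo.mwn import mwn_forward

    weights = mwn_forward(W, losses)
    assert float(ad.tsum(weights * losses).item()) == 0.0


def test_stage1_gradient_treats_weights_as_data_dependent(vocab, tiny_s):
    """Gradient of sum W(l)*l w.r.t. S matches numerical differentiation."""
    pairs = [ParaphrasePair("a", "w00 w01 w02", "w03 w04 w05")]
    W = mwn_init(hidden=4, seed=3)
    leaf = tiny_s.params["out_b"]

    def f():
        total, _, _ = weighted_paraphrase_loss(tiny_s, W, pairs)
        return total

    (g,) = ad.grad(f(), [leaf])
    num = ad.numerical_gradient(f, leaf)
    assert np.allclose(g.data, num, atol=1e-7)


# -- generation -------------------------------------------------------------


@pytest.mark.parametrize("strategy", ["greedy", "beam"])
def test_generation_length_bounds_and_determinism(vocab, tiny_s, strategy):
    rng = np.random.default_rng(0)
    for _ in range(25):
        toks = rng.choice([f"w{i:02d}" for i in range(26)], size=rng.integers(1, 9))
        text = " ".join(toks)
        ids = generate_ids(tiny_s, text, min_len=3, max_len=6, strategy=strategy)
        assert 3 <= len(ids) <= 6
        again = generate_ids(tiny_s, text, min_len=3, max_len=6, strategy=strategy)
        assert ids == again


def test_generation_single_token_bounds(vocab, tiny_s):
    ids = generate_ids(tiny_s, "w00 w01", min_len=1, max_len=1)
    assert len(ids) == 1


def test_generation_rejects_empty_and_bad_bounds(vocab, tiny_s):
    with pytest.raises(ValueError):
        generate(tiny_s, "   ")
    with pytest.raises(ValueError):
        generate_ids(tiny_s, "w00", min_len=5, max_len=2)


def test_generated_text_decodes_real_tokens(vocab, tiny_s):
    text = generate(tiny_s, "w00 w01 w02", min_len=2, max_len=5)
    toks = text.split()
    assert 2 <= len(toks) <= 5
    assert all(t != "<unk>" for t in toks)


# -- classifier -------------------------------------------------------------


def test_uniform_classifier_loss_is_log_k(vocab, tiny_c):
    for k, v in tiny_c.params.items():
        tiny_c.params[k] = Tensor(np.zeros_like(v.data), requires_grad=True)
    loss = classifier_loss(tiny_c, [("w00 w01", 0), ("w02", 1)])
    assert loss.item() == pytest.approx(np.log(2), abs=1e-6)


def test_batch_loss_is_mean_of_singles(vocab, tiny_c):
    data = [("w00 w01 w02", 0), ("w05 w06", 1)]
    batched = classifier_loss(tiny_c, data).item()
    singles = [classifier_loss(tiny_c, [d]).item() for d in data]
    assert batched == pytest.approx(np.mean(singles), rel=1e-10)


def test_label_out_of_range_rejected(vocab, tiny_c):
    with pytest.raises(ValueError):
        classifier_loss(tiny_c, [("w00", 5)])


def test_predict_proba_rows_sum_to_one(vocab, tiny_c):
    probs = predict_proba(tiny_c, ["w00 w01", "w02", "w03 w04 w05"])
    assert probs.shape == (3, 2)
    assert np.allclose(probs.sum(axis=1), 1.0)


def test_reference_classifier_layer_stack_shapes(vocab):
    """Parameter-shape audit of the reference stack:
    embedding -> bi-LSTM(64) -> dropout .5 -> bi-LSTM(32) -> dropout .5
    -> ReLU dense(20) -> softmax(K)."""
    C = init_classifier(vocab, label_count=2)
    V, E = vocab.size, 64
    p = {k: v.shape for k, v in C.params.items()}
    assert p["emb"] == (V, E)
    for d in ("f", "b"):  # both directions present
        assert p[f"l1{d}_Wx"] == (E, 4 * 64)
        assert p[f"l1{d}_Wh"] == (64, 4 * 64)
        assert p[f"l2{d}_Wx"] == (2 * 64, 4 * 32)
        assert p[f"l2{d}_Wh"] == (32, 4 * 32)
    assert p["d_W"] == (2 * 32, 20)
    assert p["o_W"] == (20, 2)
    assert C.dropout1 == C.dropout2 == 0.5
    assert C.dense_activation == "relu"
    assert C.max_input_len == 128


# -- soft generated path ----------------------------------------------------


def _examples():
    return [
        LabeledExample("x", "w00 w01 w02 w03", 0),
        LabeledExample("y", "w05 w06 w07", 1),
    ]


def test_soft_path_with_onehot_probs_equals_hard_loss(vocab, tiny_s, tiny_c):
    """Collapsing the decoder distributions to one-hot recovers the plain
    classifier loss on the hard-decoded texts."""
    decoded = [generate_ids(tiny_s, ex.text) for ex in _examples()]
    T = max(len(d) for d in decoded)
    B, V = len(decoded), vocab.size
    probs = np.zeros((B, T, V))
    mask = np.zeros((B, T))
    for i, d in enumerate(decoded):
        probs[i, np.arange(len(d)), d] = 1.0
        probs[i, len(d):, vocab.pad_id] = 1.0
        mask[i, : len(d)] = 1.0
    labels = [ex.label for ex in _examples()]
    soft = soft_classifier_loss_from_probs(
        tiny_c, Tensor(probs), mask, labels
    ).item()
    hard_records = [
        (vocab.decode(d), ex.label) for d, ex in zip(decoded, _examples())
    ]
    hard = classifier_loss(tiny_c, hard_records).item()
    assert soft == pytest.approx(hard, abs=1e-6)


def test_soft_generated_loss_nonneg_and_differentiable_in_s(vocab, tiny_s, tiny_c):
    examples = _examples()
    s_leaves = {
        k: Tensor(v.data, requires_grad=True) for k, v in tiny_s.params.items()
    }
    loss = soft_generated_loss(tiny_c, tiny_s, examples, s_params=s_leaves)
    assert loss.item() >= 0.0
    gs = ad.grad(loss, list(s_leaves.values()))
    total = sum(float(np.abs(g.data).sum()) for g in gs)
    assert total > 0.0  # the paraphraser genuinely receives gradient

    # spot-check one parameter against numerical differentiation
    leaf = s_leaves["dec_b"]
    dec = [generate_ids(tiny_s, ex.text) for ex in examples]

    def f():
        return soft_generated_loss(
            tiny_c, tiny_s, examples, s_params=s_leaves, decoded_ids=dec
        )

    (g,) = ad.grad(f(), [leaf])
    num = ad.numerical_gradient(f, leaf)
    assert np.allclose(g.data, num, atol=1e-7)


def test_soft_path_rejects_vocabulary_mismatch(tiny_c):
    other_vocab = Vocabulary(["z1", "z2"])
    S2 = init_paraphraser(other_vocab, 4, 4, 1, 4, seed=0)
    with pytest.raises(ValueError, match="vocabulary"):
        soft_generated_loss(tiny_c, S2, _examples())


def test_decoder_distributions_are_stochastic(vocab, tiny_s):
    texts = ["w00 w01", "w02 w03 w04"]
    decoded = [generate_ids(tiny_s, t) for t in texts]
    probs, mask = decoder_distributions(tiny_s, texts, decoded)
    sums = probs.data.sum(axis=-1)
    assert np.allclose(sums[mask > 0], 1.0)


# -- combined stage-II loss -------------------------------------------------


def test_combined_loss_limits(vocab, tiny_c):
    data = [("w00 w01", 0), ("w02", 1)]
    gen = Tensor(0.37)
    base = classifier_loss(tiny_c, data).item()
    assert combined_classifier_loss(tiny_c, data, gen, gamma=0.0).item() == (
        pytest.approx(base)
    )
    l = classifier_loss(tiny_c, data)
    both = combined_classifier_loss(tiny_c, data, l, gamma=1.0).item()
    assert both == pytest.approx(2 * base, rel=1e-10)
    only = combined_classifier_loss(tiny_c, data, gen, gamma=0.85, only_aug=True)
    assert only.item() == pytest.approx(0.37)
    with pytest.raises(ValueError):
        combined_classifier_loss(tiny_c, data, gen, gamma=-0.1)


def test_default_gamma_is_085():
    import inspect

    sig = inspect.signature(combined_classifier_loss)
    assert sig.parameters["gamma"].default == 0.85


# -- checkpoints ------------------------------------------------------------


def test_paraphraser_checkpoint_round_trip(tmp_path, vocab, tiny_s):
    path = tmp_path / "s.json"
    save_paraphraser(tiny_s, path)
    back = load_paraphraser(path)
    assert generate(back, "w00 w01 w02") == generate(tiny_s, "w00 w01 w02")


def test_classifier_checkpoint_round_trip(tmp_path, vocab, tiny_c):
    path = tmp_path / "c.json"
    save_classifier(tiny_c, path)
    back = load_classifier(path)
    a = predict_proba(tiny_c, ["w00 w01"])
    b = predict_proba(back, ["w00 w01"])
    assert np.allclose(a, b)


def test_checkpoint_kind_mismatch_rejected(tmp_path, vocab, tiny_s):
    path = tmp_path / "s.json"
    save_paraphraser(tiny_s, path)
    with pytest.raises(ValueError):
        load_classifier(path)
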