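"""Metric protocol: confusion arithmetic, AUC = Mann-Whitney, invariances."""

import json

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from paramlo.metrics import MetricsReport, compute_metrics


def _scores_for(preds, K=2, conf=0.9):
    s = np.full((len(preds), K), (1 - conf) / (K - 1))
    s[np.arange(len(preds)), preds] = conf
    return s


def test_perfect_predictions():
    y = np.array([0, 1, 0, 1, 1])
    rep = compute_metrics(y, y, _scores_for(y))
    assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
    assert rep.auc == 1.0


def test_confusion_matrix_arithmetic():
    """TP=3, FP=1, FN=1, TN=5 -> P=R=F1=0.75, acc=0.8."""
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    p = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
    rep = compute_metrics(y, p, _scores_for(p))
    assert rep.accuracy == pytest.approx(0.8)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.75)
    assert rep.f1 == pytest.approx(0.75)


def test_constant_scores_give_auc_half():
    y = np.array([0, 1, 0, 1])
    p = np.zeros(4, dtype=int)
    scores = np.full((4, 2), 0.5)
    rep = compute_metrics(y, p, scores)
    assert rep.auc == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(5))
def test_binary_auc_equals_normalized_mann_whitney(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=40)
    y[:2] = [0, 1]  # both classes present
    pos_score = rng.random(40)
    scores = np.stack([1 - pos_score, pos_score], axis=1)
    rep = compute_metrics(y, (pos_score > 0.5).astype(int), scores)
    u, _ = mannwhitneyu(pos_score[y == 1], pos_score[y == 0])
    expected = u / ((y == 1).sum() * (y == 0).sum())
    assert rep.auc == pytest.approx(expected, abs=1e-12)


def test_macro_f1_invariant_to_class_relabeling():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 3, size=60)
    p = rng.integers(0, 3, size=60)
    rep = compute_metrics(y, p, averaging="macro", auc_mode="one_vs_one")
    perm = np.array([2, 0, 1])
    rep2 = compute_metrics(
        perm[y], perm[p], averaging="macro", auc_mode="one_vs_one"
    )
    assert rep.f1 == pytest.approx(rep2.f1)
    assert rep.accuracy == pytest.approx(rep2.accuracy)


def test_one_vs_one_auc_averages_pairwise():
    rng = np.random.default_rng(2)
    K, n = 3, 90
    y = rng.integers(0, K, size=n)
    raw = rng.random((n, K))
    scores = raw / raw.sum(axis=1, keepdims=True)
    rep = compute_metrics(y, scores.argmax(1), scores, averaging="macro",
                          auc_mode="one_vs_one")
    # independent pairwise computation: mean over unordered pairs of the
    # average of the two directional ranking AUCs
    from sklearn.metrics import roc_auc_score

    pair_aucs = []
    for a in range(K):
        for b in range(a + 1, K):
            mask = np.isin(y, [a, b])
            ya = (y[mask] == a).astype(int)
            auc_a = roc_auc_score(ya, scores[mask, a])
            yb = (y[mask] == b).astype(int)
            auc_b = roc_auc_score(yb, scores[mask, b])
            pair_aucs.append((auc_a + auc_b) / 2)
    assert rep.auc == pytest.approx(np.mean(pair_aucs))


def test_zero_division_resolves_to_zero_with_warning(caplog):
    y = np.array([1, 1, 1, 0])
    p = np.zeros(4, dtype=int)  # no positive predictions
    with caplog.at_level("WARNING", logger="paramlo.metrics"):
        rep = compute_metrics(y, p, _scores_for(p))
    assert rep.precision == 0.0
    assert any("zero-division" in r.message for r in caplog.records)


def test_length_mismatch_and_bad_scores_rejected():
    with pytest.raises(ValueError):
        compute_metrics([0, 1], [0])
    with pytest.raises(ValueError):
        compute_metrics([0, 1], [0, 1], np.array([[0.9, 0.3], [0.5, 0.5]]))


def test_binary_averaging_requires_two_classes():
    with pytest.raises(ValueError):
        compute_metrics([0, 1, 2], [0, 1, 2], averaging="binary")


def test_report_json_round_trip():
    y = np.array([0, 1, 1, 0, 1])
    p = np.array([0, 1, 0, 0, 1])
    rep = compute_metrics(y, p, _scores_for(p))
    back = MetricsReport.from_json(rep.to_json())
    assert back.to_json() == rep.to_json()
    assert json.loads(rep.to_json())["n"] == 5


def test_percent_table_formatting():
    rep = compute_metrics([0, 1], [0, 1], _scores_for(np.array([0, 1])))
    table = rep.as_percent_table()
    assert "100.00%" in table


# -- sweep drivers ----------------------------------------------------------


def test_seed_sweep_table_and_population_std(task):
    """A two-seed sweep yields per-seed rows plus mean/std aggregates."""
    from paramlo.config import MLOConfig
    from paramlo.metrics import seed_sweep

    cfg = MLOConfig.test_profile(
        mlo_epochs=1, finetune_epochs=1, s_warmup_steps=0
    )
    table = seed_sweep(
        cfg, [0, 1], task["pairs"], task["corpora"]["train"],
        task["corpora"]["test"], vocab=task["vocab"],
    )
    assert list(table["seed"]) == [0, 1, "mean", "std"]
    accs = table["accuracy"].iloc[:2].to_numpy(dtype=float)
    mean_row = float(table[table["seed"] == "mean"]["accuracy"].iloc[0])
    std_row = float(table[table["seed"] == "std"]["accuracy"].iloc[0])
    assert mean_row == pytest.approx(accs.mean())
    assert std_row == pytest.approx(np.std(accs, ddof=0))


def test_gamma_sweep_grid_and_single_row(task):
    from paramlo.config import MLOConfig
    from paramlo.metrics import DEFAULT_GAMMA_GRID, gamma_sweep

    assert DEFAULT_GAMMA_GRID == (0.01, 0.85, 3.0, 5.0)
    cfg = MLOConfig.test_profile(
        mlo_epochs=1, finetune_epochs=1, s_warmup_steps=0
    )
    table = gamma_sweep(
        cfg, [0.85], [0], task["pairs"], task["corpora"]["train"],
        task["corpora"]["test"], vocab=task["vocab"],
    )
    assert len(table) == 1
    assert table["gamma"].iloc[0] == 0.85
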