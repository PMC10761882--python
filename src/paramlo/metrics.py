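"""Evaluation metrics and sweep drivers.

Accuracy, precision, recall, F1 and ranking AUC with the averaging
protocol used throughout: binary tasks report positive-class
precision/recall/F1 and the positive-score ranking AUC; multi-class tasks
report macro averages and one-vs-one AUC (the mean of pairwise binary
ranking AUCs).  Ties are handled by midranks, so uninformative scores give
AUC 0.5.  Seed sweeps aggregate with the population standard deviation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

logger = logging.getLogger("paramlo.metrics")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    averaging: str  # "binary" | "macro"
    auc_mode: str  # "binary" | "one_vs_one"
    n: int
    per_class: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("accuracy", "precision", "recall", "f1", "auc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        return cls.from_dict(json.loads(s))

    def as_percent_table(self) -> str:
        rows = [
            f"{name:<10}{100 * getattr(self, name):6.2f}%"
            for name in ("accuracy", "f1", "precision", "recall", "auc")
        ]
        return "\n".join(rows)


def compute_metrics(
    labels: Sequence[int],
    predictions: Sequence[int],
    scores: Optional[np.ndarray] = None,
    averaging: Optional[str] = None,
    auc_mode: Optional[str] = None,
) -> MetricsReport:
    """Classification metrics under the reporting protocol.

    ``scores`` is an (n, K) row-stochastic probability matrix; when it is
    omitted the AUC falls back to 0.5.  Zero-division in a class's
    precision or recall resolves to 0 with a warning.
    """
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(predictions, dtype=np.int64)
    if y.shape != p.shape:
        raise ValueError("labels and predictions have different lengths")
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.ndim != 2 or scores.shape[0] != len(y):
            raise ValueError("scores must be an (n, K) matrix")
        if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("score rows must sum to 1")
    K = int(max(y.max(), p.max())) + 1
    if scores is not None:
        K = max(K, scores.shape[1])
    if averaging is None:
        averaging = "binary" if K == 2 else "macro"
    if averaging == "binary" and K != 2:
        raise ValueError("binary averaging requires exactly two classes")
    if auc_mode is None:
        auc_mode = "binary" if K == 2 else "one_vs_one"

    acc = float(accuracy_score(y, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if averaging == "binary":
            prec, rec, f1, _ = precision_recall_fscore_support(
                y, p, average="binary", pos_label=1, zero_division=0
            )
        else:
            prec, rec, f1, _ = precision_recall_fscore_support(
                y, p, average="macro", labels=np.arange(K), zero_division=0
            )
        pc_p, pc_r, pc_f, pc_s = precision_recall_fscore_support(
            y, p, labels=np.arange(K), zero_division=0
        )
    if np.any((pc_s > 0) & (pc_p == 0) & (pc_r == 0)):
        logger.warning("zero-division in a class's precision/recall; reported as 0")

    per_class = {
        str(k): dict(
            precision=float(pc_p[k]),
            recall=float(pc_r[k]),
            f1=float(pc_f[k]),
            support=int(pc_s[k]),
        )
        for k in range(K)
    }

    if scores is None or len(np.unique(y)) < 2:
        auc = 0.5
        if scores is not None:
            logger.warning("AUC undefined with a single observed class; using 0.5")
    elif auc_mode == "binary":
        auc = float(roc_auc_score(y, scores[:, 1]))
    elif auc_mode == "one_vs_one":
        auc = float(
            roc_auc_score(
                y, scores, multi_class="ovo", average="macro", labels=np.arange(K)
            )
        )
    else:
        raise ValueError(f"unknown auc_mode {auc_mode!r}")

    return MetricsReport(
        accuracy=acc,
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        auc=auc,
        averaging=averaging,
        auc_mode=auc_mode,
        n=len(y),
        per_class=per_class,
    )


def evaluate_classifier(classifier, corpus) -> MetricsReport:
    """Run a classifier over a labeled corpus and compute the report."""
    from .models import predict_proba

    texts = [ex.text for ex in corpus]
    labels = [ex.label for ex in corpus]
    scores = predict_proba(classifier, texts)
    preds = scores.argmax(axis=1)
    return compute_metrics(labels, preds, scores)


METRIC_NAMES = ("accuracy", "f1", "precision", "recall", "auc")


def seed_sweep(
    config,
    seeds: Sequence[int],
    paraphrase_corpus,
    train_corpus,
    test_corpus,
    vocab=None,
) -> pd.DataFrame:
    """Train per seed, evaluate on the test corpus, aggregate mean/std.

    The aggregate rows use the population standard deviation.  Per-seed
    failures are recorded as rows flagged ``failed`` and excluded from the
    aggregates.
    """
    if not seeds:
        raise ValueError("at least one seed required")
    from dataclasses import replace

    from .data import split_mlo
    from .engine import train_mlo

    rows = []
    for seed in seeds:
        cfg = replace(config, seed=int(seed))
        try:
            mlo_tr, mlo_va = split_mlo(train_corpus, seed=int(seed))
            C, _, _, _ = train_mlo(
                cfg, paraphrase_corpus, mlo_tr, mlo_va, train_corpus, vocab=vocab
            )
            report = evaluate_classifier(C, test_corpus)
            row = {"seed": seed, "failed": False}
            row.update({m: getattr(report, m) for m in METRIC_NAMES})
        except Exception as err:  # noqa: BLE001 - per-seed isolation
            logger.warning("seed %s failed: %s", seed, err)
            row = {"seed": seed, "failed": True}
            row.update({m: np.nan for m in METRIC_NAMES})
        rows.append(row)

    df = pd.DataFrame(rows)
    ok = df[~df["failed"]]
    agg = []
    for stat, fn in (("mean", np.mean), ("std", lambda x: np.std(x, ddof=0))):
        rec = {"seed": stat, "failed": bool(ok.empty)}
        rec.update(
            {m: float(fn(ok[m])) if not ok.empty else np.nan for m in METRIC_NAMES}
        )
        agg.append(rec)
    return pd.concat([df, pd.DataFrame(agg)], ignore_index=True)


DEFAULT_GAMMA_GRID = (0.01, 0.85, 3.0, 5.0)


def gamma_sweep(
    config,
    gammas: Sequence[float] = DEFAULT_GAMMA_GRID,
    seeds: Sequence[int] = (0,),
    paraphrase_corpus=None,
    train_corpus=None,
    test_corpus=None,
    vocab=None,
) -> pd.DataFrame:
    """One seed sweep per trade-off value; rows of (gamma, mean, std)."""
    from dataclasses import replace

    if any(g < 0 for g in gammas):
        raise ValueError("gamma values must be >= 0")
    rows = []
    for g in gammas:
        cfg = replace(config, gamma=float(g))
        table = seed_sweep(
            cfg, seeds, paraphrase_corpus, train_corpus, test_corpus, vocab=vocab
        )
        mean_row = table[table["seed"] == "mean"].iloc[0]
        std_row = table[table["seed"] == "std"].iloc[0]
        rows.append(
            {
                "gamma": g,
                "mean_accuracy": float(mean_row["accuracy"]),
                "std_accuracy": float(std_row["accuracy"]),
            }
        )
    return pd.DataFrame(rows)
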