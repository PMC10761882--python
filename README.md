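# paramlo

Learned reweighting of paraphrase training data for low-resource text
classification, via three-level optimization with a meta-weight
network.

## The problem

Classifying scientific articles in a narrow domain (the motivating
application is identifying long-COVID literature from titles and
abstracts) is starved for labeled data.  Paraphrase augmentation helps:
a sequence-to-sequence model S rewrites each training text, and the
rewrite inherits the original label.  But S must be trained on whatever
generic paraphrase corpus exists, and out-of-domain pairs teach it the
wrong register — its rewrites then hurt the very classifier they were
meant to help.

`paramlo` implements an end-to-end answer: a small meta-weight network
W maps each paraphrase pair's teacher-forcing loss l(S, t_i, s_i) to a
weight a_i ∈ (0, 1), and the weights are *learned* from the downstream
classifier's validation loss through a three-level program

    min_W   L(C*(S*(W)), D_meta-val)
    s.t.    C*(S*(W)) = argmin_C  L(C, D_meta-tr) + γ·L(C, G(D_meta-tr, S*(W)))
            S*(W)     = argmin_S  Σ_i W(l(S, t_i, s_i)) · l(S, t_i, s_i)

solved by one-step unrolls and a two-level symmetric-perturbation
(finite-difference) approximation of the meta-gradient ∇_W L.  Pairs
that help the downstream task float up; off-domain pairs sink.  An
exact double-backward oracle (built on the package's own higher-order
reverse-mode autodiff engine) validates the finite-difference scheme.

The library is model-agnostic: any paraphraser exposing losses,
generation and decoder distributions, and any classifier exposing a
loss and class probabilities, can be plugged in.  Reference tiny
implementations (GRU seq2seq with aligned source conditioning; a
two-layer bi-LSTM classifier) plus a synthetic two-domain corpus
generator make every stage testable on one CPU with no downloads.

## Worked example

```python
import numpy as np
from paramlo import (
    MLOConfig, SyntheticSpec, make_synthetic_task, split_mlo,
    train_mlo, evaluate_classifier, pair_weights,
)

spec = SyntheticSpec(seed=0)          # two token domains, 60 pairs, 50% in-domain
pairs, corpora, vocab = make_synthetic_task(spec)
mlo_tr, mlo_val = split_mlo(corpora["train"], seed=0)

cfg = MLOConfig.test_profile(seed=0)  # desk-scale profile (~90 s, one CPU)
C, S, W, history = train_mlo(cfg, pairs, mlo_tr, mlo_val,
                             corpora["train"], vocab=vocab)

report = evaluate_classifier(C, corpora["test"])
print(report.as_percent_table())
w = pair_weights(W, S, pairs, standardize=True)
tags = np.array([p.domain_tag == "in_domain" for p in pairs])
print(f"mean weight  in-domain: {w[tags].mean():.3f}")
print(f"mean weight off-domain: {w[~tags].mean():.3f}")
```

prints

```
accuracy   90.00%
f1         90.00%
precision  90.00%
recall     90.00%
auc        93.62%
mean weight  in-domain: 0.733
mean weight off-domain: 0.368
```

The classifier reaches 90% test accuracy (the generating rule itself
scores 90% on this noised test split), and the learned weights separate
the paraphrase corpus by domain: pairs drawn from the downstream
domain carry roughly twice the weight of off-domain pairs, although no
domain label was ever shown to the trainer.

## Command line

```
paramlo synth       --out-dir data --seed 1          # synthetic corpora
paramlo train       --paraphrase-corpus data/paraphrase.tsv \
                    --train-corpus data/train.csv \
                    --test-corpus data/test.csv \
                    --profile test --out-dir run      # full pipeline
paramlo augment     --paraphraser run/paraphraser.json \
                    --corpus data/val.csv --out aug.jsonl
paramlo evaluate    --classifier run/classifier.json --corpus data/test.csv
paramlo sweep-seeds --seeds 0,1,2,3,4 ...             # mean ± std tables
paramlo sweep-gamma --gammas 0.01,0.85,3,5 ...        # trade-off sweep
```

Corpora are plain TSV/CSV/JSONL; checkpoints are versioned JSON with
architecture and vocabulary hashes.

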