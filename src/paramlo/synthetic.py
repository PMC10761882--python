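"""Synthetic two-domain corpora for end-to-end testing of the framework.

The generator emulates the data situation the method targets: the
paraphraser's training pairs come from a mixed-domain corpus while the
downstream classifier lives in one specific domain.  Two disjoint token
domains are built (domain A carries the classification task, domain B is
off-domain noise).  Classification texts are domain-A strings whose label
is decided by which of K groups of designated *signal tokens* occurs most
often; paraphrase targets are produced by a fixed bijective synonym map
applied token-wise, so the "correct" paraphrase is exactly computable and
the teacher-forcing loss has a known floor of zero.

In-domain paraphrase pairs are drawn from the same signal-structured text
distribution as the classification corpus; off-domain pairs are uniform
strings over the domain-B vocabulary.  Because signal tokens exist only in
domain A, off-domain pairs cannot teach the classifier anything — the
ground truth the weight network is expected to discover.

The synonym map pairs consecutive tokens (2i <-> 2i+1) and each signal
group is one such pair, so the ideal paraphrase preserves per-group signal
counts and therefore the label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .data import (
    LabeledCorpus,
    LabeledExample,
    ParaphraseCorpus,
    ParaphrasePair,
)
from .models import Vocabulary


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic task.

    Defaults are the desk-scale profile: 30+30 token domains, 4 signal
    tokens in 2 groups, 60 paraphrase pairs at 50% in-domain,
    120/40/80 train/val/test, text lengths 6-12, 10% token noise.
    """

    vocab_size_per_domain: int = 30
    n_signal_tokens: int = 4
    n_paraphrase_pairs: int = 60
    in_domain_fraction: float = 0.5
    n_train: int = 120
    n_val: int = 40
    n_test: int = 80
    text_len_min: int = 6
    text_len_max: int = 12
    label_count: int = 2
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(
            self.vocab_size_per_domain,
            self.n_signal_tokens,
            self.n_paraphrase_pairs,
            self.n_train,
            self.n_val,
            self.n_test,
            self.text_len_min,
        ) < 1:
            raise ValueError("all counts must be >= 1")
        if self.text_len_max < self.text_len_min:
            raise ValueError("text length range is inverted")
        if not (0.0 <= self.in_domain_fraction <= 1.0):
            raise ValueError("in_domain_fraction must lie in [0, 1]")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must lie in [0, 1)")
        if self.label_count < 2:
            raise ValueError("label_count must be >= 2")
        if self.n_signal_tokens % self.label_count != 0:
            raise ValueError("n_signal_tokens must be divisible by label_count")
        if self.n_signal_tokens // self.label_count % 2 != 0:
            raise ValueError(
                "each label's signal group must be an even number of tokens "
                "(signal groups are synonym pairs)"
            )
        if self.vocab_size_per_domain % 2 != 0:
            raise ValueError("vocab_size_per_domain must be even (synonym pairs)")
        if self.n_signal_tokens > self.vocab_size_per_domain // 2:
            raise ValueError("too many signal tokens for the domain vocabulary")


def domain_tokens(spec: SyntheticSpec) -> Tuple[List[str], List[str]]:
    w = len(str(spec.vocab_size_per_domain - 1))
    a = [f"a{i:0{w}d}" for i in range(spec.vocab_size_per_domain)]
    b = [f"b{i:0{w}d}" for i in range(spec.vocab_size_per_domain)]
    return a, b


def signal_groups(spec: SyntheticSpec) -> List[List[str]]:
    """Group k's signal tokens (consecutive synonym pairs in domain A)."""
    a, _ = domain_tokens(spec)
    per = spec.n_signal_tokens // spec.label_count
    return [a[k * per : (k + 1) * per] for k in range(spec.label_count)]


def synonym_map(tokens: List[str]) -> Dict[str, str]:
    """Fixed involution pairing token 2i with token 2i+1."""
    m: Dict[str, str] = {}
    for i in range(0, len(tokens) - 1, 2):
        m[tokens[i]] = tokens[i + 1]
        m[tokens[i + 1]] = tokens[i]
    if len(tokens) % 2 == 1:  # odd leftover maps to itself
        m[tokens[-1]] = tokens[-1]
    return m


def _signal_text(
    spec: SyntheticSpec,
    label: int,
    rng: np.random.Generator,
    groups: List[List[str]],
    filler: List[str],
) -> List[str]:
    """A domain-A token list whose label-group count strictly dominates."""
    length = int(rng.integers(spec.text_len_min, spec.text_len_max + 1))
    c_lab = int(rng.integers(2, 4))  # 2 or 3 signal tokens of the true group
    others = [int(rng.integers(0, c_lab)) for _ in range(spec.label_count - 1)]
    tokens: List[str] = list(rng.choice(groups[label], size=c_lab))
    oi = 0
    for k in range(spec.label_count):
        if k == label:
            continue
        if others[oi] > 0:
            tokens.extend(rng.choice(groups[k], size=others[oi]))
        oi += 1
    n_fill = max(0, length - len(tokens))
    tokens.extend(rng.choice(filler, size=n_fill))
    tokens = [str(t) for t in tokens]
    rng.shuffle(tokens)
    return tokens


def _apply_noise(
    tokens: List[str], rate: float, pool: List[str], rng: np.random.Generator
) -> List[str]:
    if rate == 0.0:
        return tokens
    out = []
    for t in tokens:
        if rng.random() < rate:
            out.append(str(rng.choice(pool)))
        else:
            out.append(t)
    return out


def label_rule(spec: SyntheticSpec, text: str) -> int:
    """The generating rule: label = signal group with the highest count.

    Ties resolve to the lowest label.  This is the Bayes-optimal decision
    for the construction and the ceiling any trained classifier can reach.
    """
    groups = signal_groups(spec)
    toks = text.split()
    counts = [sum(toks.count(t) for t in g) for g in groups]
    return int(np.argmax(counts))


def make_synthetic_task(
    spec: SyntheticSpec,
) -> Tuple[ParaphraseCorpus, Dict[str, LabeledCorpus], Vocabulary]:
    """Build (paraphrase corpus, {train,val,test} corpora, shared vocab)."""
    rng = np.random.default_rng(spec.seed)
    a_tokens, b_tokens = domain_tokens(spec)
    groups = signal_groups(spec)
    signal = [t for g in groups for t in g]
    filler = [t for t in a_tokens if t not in signal]
    syn_a = synonym_map(a_tokens)
    syn_b = synonym_map(b_tokens)

    # -- classification corpora (domain A) --
    def make_split(n: int, role: str, prefix: str) -> LabeledCorpus:
        examples = []
        for i in range(n):
            y = i % spec.label_count  # balanced by construction
            toks = _signal_text(spec, y, rng, groups, filler)
            toks = _apply_noise(toks, spec.noise_rate, a_tokens, rng)
            examples.append(LabeledExample(f"{prefix}{i:04d}", " ".join(toks), y))
        return LabeledCorpus(tuple(examples), spec.label_count, role=role)

    corpora = {
        "train": make_split(spec.n_train, "train", "tr"),
        "val": make_split(spec.n_val, "val", "va"),
        "test": make_split(spec.n_test, "test", "te"),
    }

    # -- paraphrase corpus (mixed domains) --
    n_in = int(round(spec.in_domain_fraction * spec.n_paraphrase_pairs))
    pairs: List[ParaphrasePair] = []
    for i in range(spec.n_paraphrase_pairs):
        if i < n_in:
            toks = _signal_text(
                spec, i % spec.label_count, rng, groups, filler
            )
            tgt = [syn_a[t] for t in toks]
            tag = "in_domain"
        else:
            length = int(rng.integers(spec.text_len_min, spec.text_len_max + 1))
            toks = [str(t) for t in rng.choice(b_tokens, size=length)]
            tgt = [syn_b[t] for t in toks]
            tag = "off_domain"
        pairs.append(
            ParaphrasePair(f"p{i:04d}", " ".join(toks), " ".join(tgt), tag)
        )

    vocab = Vocabulary(a_tokens + b_tokens)
    return ParaphraseCorpus(tuple(pairs)), corpora, vocab


def bayes_reference_accuracy(spec: SyntheticSpec, corpus: LabeledCorpus) -> float:
    """Accuracy of the generating label rule on a (possibly noised) corpus.

    With zero noise this is exactly 1.0; as noise grows the stored labels
    decouple from the text and the value approaches chance.
    """
    if corpus.label_count != spec.label_count:
        raise ValueError("corpus label count does not match the spec")
    correct = sum(
        1 for ex in corpus if label_rule(spec, ex.text) == ex.label
    )
    return correct / len(corpus)
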