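"""Corpus types, readers/writers, and the meta-train/meta-val split.

Two corpora drive the method: a paraphrase corpus of (source, target) text
pairs used to train the paraphraser, and a labeled corpus of (text, label)
records for the downstream classifier.  The labeled training corpus is
further partitioned 80/20 into a meta-training part (used to train the
classifier inside the optimization loop) and a meta-validation part (whose
classifier loss provides the feedback signal for the weight network).

All text IO is UTF-8; leading/trailing whitespace is stripped at load.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("paramlo.data")


class CorpusFormatError(ValueError):
    """A record violates the corpus schema (missing/empty field, bad label)."""


class EmptyCorpusError(ValueError):
    """The file parsed correctly but contained no records."""


@dataclass(frozen=True)
class ParaphrasePair:
    id: str
    source_text: str
    target_text: str
    domain_tag: Optional[str] = None  # "in_domain" | "off_domain"; fixtures only

    def __post_init__(self):
        if not self.source_text.strip() or not self.target_text.strip():
            raise CorpusFormatError(
                f"pair {self.id!r}: source and target must be non-empty"
            )
        if self.domain_tag not in (None, "in_domain", "off_domain"):
            raise CorpusFormatError(
                f"pair {self.id!r}: unknown domain tag {self.domain_tag!r}"
            )


@dataclass(frozen=True)
class ParaphraseCorpus:
    pairs: Tuple[ParaphrasePair, ...]

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise EmptyCorpusError("paraphrase corpus must contain >= 1 pair")
        ids = [p.id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise CorpusFormatError("pair ids must be unique within a corpus")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


@dataclass(frozen=True)
class LabeledExample:
    id: str
    text: str
    label: int

    def __post_init__(self):
        if not self.text.strip():
            raise CorpusFormatError(f"example {self.id!r}: text must be non-empty")
        if self.label < 0:
            raise CorpusFormatError(f"example {self.id!r}: negative label")


@dataclass(frozen=True)
class LabeledCorpus:
    examples: Tuple[LabeledExample, ...]
    label_count: int
    role: str = "train"  # train | val | mlo_train | mlo_val | test

    _ROLES = ("train", "val", "mlo_train", "mlo_val", "test")

    def __post_init__(self):
        if len(self.examples) < 1:
            raise EmptyCorpusError("labeled corpus must contain >= 1 example")
        if self.label_count < 2:
            raise CorpusFormatError("label_count must be >= 2")
        if self.role not in self._ROLES:
            raise CorpusFormatError(f"unknown corpus role {self.role!r}")
        for ex in self.examples:
            if ex.label >= self.label_count:
                raise CorpusFormatError(
                    f"example {ex.id!r}: label {ex.label} >= label_count "
                    f"{self.label_count}"
                )

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self):
        return iter(self.examples)

    def __getitem__(self, i):
        return self.examples[i]

    def as_pairs(self) -> List[Tuple[str, int]]:
        return [(ex.text, ex.label) for ex in self.examples]


@dataclass(frozen=True)
class GeneratedExample:
    text: str
    label: int
    source_id: str


# ---------------------------------------------------------------------------
# paraphrase corpus IO
# ---------------------------------------------------------------------------


def load_paraphrase_corpus(path, format: str = "tsv") -> ParaphraseCorpus:
    """Read a paraphrase corpus from TSV (id/source/target) or JSONL."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: List[ParaphrasePair] = []
    if format == "tsv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"id", "source", "target"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise CorpusFormatError(
                    f"{path}: TSV header must contain columns {sorted(required)}"
                )
            for row_num, row in enumerate(reader, start=2):
                src = (row.get("source") or "").strip()
                tgt = (row.get("target") or "").strip()
                if not src or not tgt:
                    raise CorpusFormatError(
                        f"{path}: row {row_num}: empty source or target"
                    )
                pid = (row.get("id") or "").strip() or str(len(pairs))
                tag = (row.get("domain_tag") or "").strip() or None
                pairs.append(ParaphrasePair(pid, src, tgt, tag))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for row_num, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                if "source" not in rec or "target" not in rec:
                    raise CorpusFormatError(
                        f"{path}: line {row_num}: record missing source/target"
                    )
                src = str(rec["source"]).strip()
                tgt = str(rec["target"]).strip()
                if not src or not tgt:
                    raise CorpusFormatError(
                        f"{path}: line {row_num}: empty source or target"
                    )
                pid = str(rec.get("id", len(pairs)))
                pairs.append(
                    ParaphrasePair(pid, src, tgt, rec.get("domain_tag"))
                )
    else:
        raise ValueError(f"unknown paraphrase corpus format {format!r}")
    if not pairs:
        raise EmptyCorpusError(f"{path}: no records")
    return ParaphraseCorpus(tuple(pairs))


def save_paraphrase_corpus(corpus: ParaphraseCorpus, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "source", "target", "domain_tag"])
            for p in corpus:
                writer.writerow([p.id, p.source_text, p.target_text, p.domain_tag or ""])
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for p in corpus:
                rec = {"id": p.id, "source": p.source_text, "target": p.target_text}
                if p.domain_tag:
                    rec["domain_tag"] = p.domain_tag
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown paraphrase corpus format {format!r}")


# ---------------------------------------------------------------------------
# labeled corpus IO
# ---------------------------------------------------------------------------


def _map_labels(raw_labels: Sequence[str]) -> Tuple[List[int], Dict[str, int]]:
    """Integer labels pass through; string labels map by lexicographic sort."""
    try:
        ints = [int(x) for x in raw_labels]
        return ints, {}
    except ValueError:
        pass
    mapping = {lab: i for i, lab in enumerate(sorted(set(raw_labels)))}
    logger.info("string labels mapped by sorted order: %s", mapping)
    return [mapping[x] for x in raw_labels], mapping


def load_labeled_corpus(
    path,
    format: str = "csv",
    label_count: Optional[int] = None,
    role: str = "train",
) -> LabeledCorpus:
    """Read a labeled corpus from CSV (id,text,label) or JSONL.

    K is inferred as max(label)+1 when ``label_count`` is absent; string
    labels are mapped to integers by sorted order (mapping logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: List[str] = []
    texts: List[str] = []
    raw: List[str] = []
    if format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"text", "label"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise CorpusFormatError(
                    f"{path}: CSV header must contain columns {sorted(required)}"
                )
            for row_num, row in enumerate(reader, start=2):
                text = (row.get("text") or "").strip()
                if not text:
                    raise CorpusFormatError(f"{path}: row {row_num}: empty text")
                ids.append((row.get("id") or "").strip() or str(len(ids)))
                texts.append(text)
                raw.append((row.get("label") or "").strip())
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for row_num, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                if "text" not in rec or "label" not in rec:
                    raise CorpusFormatError(
                        f"{path}: line {row_num}: record missing text/label"
                    )
                text = str(rec["text"]).strip()
                if not text:
                    raise CorpusFormatError(f"{path}: line {row_num}: empty text")
                ids.append(str(rec.get("id", len(ids))))
                texts.append(text)
                raw.append(str(rec["label"]))
    else:
        raise ValueError(f"unknown labeled corpus format {format!r}")
    if not texts:
        raise EmptyCorpusError(f"{path}: no records")
    labels, _ = _map_labels(raw)
    if any(l < 0 for l in labels):
        raise CorpusFormatError(f"{path}: negative label")
    K = label_count if label_count is not None else max(labels) + 1
    K = max(K, 2)
    for i, l in enumerate(labels):
        if l >= K:
            raise CorpusFormatError(
                f"{path}: example {ids[i]!r}: label {l} >= label_count {K}"
            )
    examples = tuple(
        LabeledExample(i, t, l) for i, t, l in zip(ids, texts, labels)
    )
    return LabeledCorpus(examples, label_count=K, role=role)


def save_labeled_corpus(corpus: LabeledCorpus, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["id", "text", "label"])
            for ex in corpus:
                writer.writerow([ex.id, ex.text, ex.label])
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for ex in corpus:
                fh.write(
                    json.dumps(
                        {"id": ex.id, "text": ex.text, "label": ex.label},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown labeled corpus format {format!r}")


def save_generated(examples: Sequence[GeneratedExample], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(
                json.dumps(
                    {"text": ex.text, "label": ex.label, "source_id": ex.source_id},
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# meta split
# ---------------------------------------------------------------------------


def split_mlo(
    corpus: LabeledCorpus,
    fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> Tuple[LabeledCorpus, LabeledCorpus]:
    """Deterministic disjoint partition of a training corpus.

    Per label, round(fraction * n_k) examples go to the meta-train side
    (the larger side also receives any rounding remainder by construction);
    the rest form the meta-validation side.  A label with a single example
    under stratification goes to meta-train with a warning.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(corpus)
    indices = np.arange(n)

    train_idx: List[int] = []
    if stratified:
        labels = np.array([ex.label for ex in corpus])
        for lab in sorted(set(labels.tolist())):
            li = indices[labels == lab]
            if len(li) == 1:
                logger.warning(
                    "label %d has a single example; assigning it to mlo_train",
                    lab,
                )
                train_idx.extend(li.tolist())
                continue
            perm = rng.permutation(li)
            k = int(round(fraction * len(li)))
            k = min(max(k, 1), len(li) - 1) if len(li) > 1 else len(li)
            train_idx.extend(perm[:k].tolist())
    else:
        perm = rng.permutation(indices)
        k = int(round(fraction * n))
        train_idx.extend(perm[:k].tolist())

    train_set = set(train_idx)
    tr = tuple(corpus[i] for i in range(n) if i in train_set)
    va = tuple(corpus[i] for i in range(n) if i not in train_set)
    if not va:
        raise ValueError(
            "split produced an empty mlo_val side; corpus too small for fraction"
        )
    return (
        LabeledCorpus(tr, label_count=corpus.label_count, role="mlo_train"),
        LabeledCorpus(va, label_count=corpus.label_count, role="mlo_val"),
    )
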