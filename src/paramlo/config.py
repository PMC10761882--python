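"""Run configuration for the multi-level optimization engine.

Defaults mirror the reference experimental protocol: trade-off gamma 0.85,
meta-step scale 0.01, batch size 8, 10 alternating epochs followed by 20
supervised fine-tuning epochs, AdamW (beta1 0.9, beta2 0.999, eps 1e-8)
for the weight-network and fine-tuning updates, decode length bounds
65-128.  :meth:`MLOConfig.test_profile` returns the desk-scale profile
used with the synthetic two-domain task (tiny models, short decode
bounds), which is what the test-suite exercises.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml


@dataclass
class OptimizerSettings:
    name: str = "adamw"  # "adamw" | "sgd"
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.name not in ("adamw", "sgd"):
            raise ValueError(f"unknown optimizer {self.name!r}")
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class MLOConfig:
    # unrolled one-step learning rates (also the committed update steps)
    eta_s: float = 2e-5
    eta_c: float = 3e-3
    eta_w: float = 1e-4
    gamma: float = 0.85
    alpha_scale: float = 0.01  # numerator of every perturbation step size

    paraphrase_batch: int = 8
    class_batch: int = 8
    # batch for the meta-val loss; None evaluates the full meta-val split
    # (it is small), which reduces hypergradient variance considerably
    val_batch: Optional[int] = None
    mlo_epochs: int = 10
    finetune_epochs: int = 20
    # unweighted warm-up for the paraphraser before the alternating loop
    # (emulates starting from a pretrained seq2seq; 0 when the plugged-in
    # paraphraser is already pretrained)
    s_warmup_steps: int = 0
    s_warmup_batch: int = 32
    s_warmup_lr: Optional[float] = None  # None: use eta_s
    seed: int = 0

    # ablations and variants
    para_sep: bool = False
    only_aug: bool = False
    detach_mwn_input: bool = False
    cache_generations: bool = False
    loss_reduction: str = "sum"  # stage-I objective: "sum" | "mean"
    fd_prefactor: str = "central"  # "central" | "printed" (1/alpha_S variant)
    # how S and C are committed each iteration: "candidate" commits the
    # one-step SGD unroll states; "optimizer" feeds the same stage
    # gradients to each model's optimizer (the reference protocol)
    commit: str = "optimizer"

    # model sizes
    s_embed: int = 16
    s_hidden: int = 16
    c_embed: int = 64
    c_hidden1: int = 64
    c_hidden2: int = 32
    c_dense: int = 20
    c_dropout1: float = 0.5
    c_dropout2: float = 0.5
    mwn_hidden: int = 25
    mwn_dropout: float = 0.2
    mwn_activation: str = "tanh"
    mwn_init_scale: float = 0.01
    # z-score the weight-network input within each batch (off: raw loss)
    mwn_standardize_input: bool = False
    c_dense_activation: str = "relu"

    # decoding
    min_len: int = 65
    max_len: int = 128
    max_input_len: int = 128
    decode_strategy: str = "greedy"

    # optimizers: W meta-updates and classifier fine-tuning use AdamW by
    # default; S and C settings apply when commits go through an optimizer
    optimizer_s: OptimizerSettings = field(
        default_factory=lambda: OptimizerSettings(lr=2e-5, weight_decay=0.01)
    )
    optimizer_c: OptimizerSettings = field(
        default_factory=lambda: OptimizerSettings(lr=3e-3)
    )
    optimizer_w: OptimizerSettings = field(
        default_factory=lambda: OptimizerSettings(lr=1e-4)
    )

    # committed stage-I step: "none" applies raw weights; "mean" divides
    # by the batch-mean weight (self-normalized importance weighting), so
    # the learned relative weighting does not also rescale the global
    # step size
    commit_weight_norm: str = "none"
    # freeze weight-network updates once the epoch-mean meta-val loss
    # stops improving (the classifier has fit its meta-train split; the
    # feedback signal after that point is dominated by overfitting noise)
    meta_early_stop: bool = False
    # rescale each iteration's weight-network gradient to unit global
    # norm before the optimizer ("unit"), or leave raw ("none"); the raw
    # magnitudes span several orders and their spikes poison adaptive
    # moments
    hypergrad_norm: str = "none"

    denominator_floor: float = 1e-12

    def __post_init__(self):
        if min(self.eta_s, self.eta_c, self.eta_w) < 0:
            raise ValueError("learning rates must be >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha_scale <= 0:
            raise ValueError("alpha_scale must be > 0")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError("loss_reduction must be 'sum' or 'mean'")
        if self.fd_prefactor not in ("central", "printed"):
            raise ValueError("fd_prefactor must be 'central' or 'printed'")
        if self.commit not in ("candidate", "optimizer"):
            raise ValueError("commit must be 'candidate' or 'optimizer'")
        if self.hypergrad_norm not in ("none", "unit"):
            raise ValueError("hypergrad_norm must be 'none' or 'unit'")
        if self.commit_weight_norm not in ("none", "mean"):
            raise ValueError("commit_weight_norm must be 'none' or 'mean'")

    # -- profiles ------------------------------------------------------
    @classmethod
    def test_profile(cls, seed: int = 0, **overrides) -> "MLOConfig":
        """Desk-scale profile for the synthetic two-domain task.

        Tiny models and short decodes so the full loop runs in seconds;
        learning rates sized for plain-SGD one-step updates of the tiny
        models (the reference-scale rates are tuned to AdamW updates of
        pretrained networks and are far too small here).
        """
        base = dict(
            eta_s=0.05,
            eta_c=0.5,
            eta_w=0.05,
            class_batch=24,
            s_embed=8,
            s_hidden=12,
            c_embed=8,
            c_hidden1=8,
            c_hidden2=8,
            c_dense=20,
            c_dense_activation="tanh",
            mwn_standardize_input=True,
            detach_mwn_input=True,
            mwn_init_scale=0.3,
            s_warmup_steps=280,
            s_warmup_lr=0.02,
            meta_early_stop=True,
            commit_weight_norm="mean",
            min_len=1,
            max_len=16,
            max_input_len=16,
            optimizer_s=OptimizerSettings(name="sgd", lr=0.05),
            # eps far below the desk-scale hypergradient magnitude (~1e-9
            # per coordinate); the reference 1e-8 assumes O(1) gradients
            # and would suppress the weak differential coordinates
            optimizer_w=OptimizerSettings(lr=0.05, eps=1e-12),
            optimizer_c=OptimizerSettings(lr=0.01),
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MLOConfig":
        d = dict(d)
        for key in ("optimizer_s", "optimizer_c", "optimizer_w"):
            if key in d and isinstance(d[key], dict):
                d[key] = OptimizerSettings(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "MLOConfig":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)
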