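"""Bit-vector codec joining feature mask, learner selector and hyperparameters.

The search operates on a 0-1 vector with three segments: one bit per
candidate feature (1 = selected), a 3-bit learner selector taken modulo the
pool size, and a shared hyperparameter field sized for the largest learner.
Scalar hyperparameters use 8-bit fixed-point fractions mapped onto their
range (log10-linearly for log-scaled ones); categorical parameters use the
minimal bit width, indexed modulo the category count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HyperparamSpec",
    "LearnerSpec",
    "EncodingLayout",
    "DecodedSolution",
    "default_pool",
    "make_layout",
    "decode",
    "encode",
    "repair_mask",
]


@dataclass(frozen=True)
class HyperparamSpec:
    name: str
    kind: str  # continuous | integer | categorical
    low: float | None = None
    high: float | None = None
    categories: tuple = ()
    scale: str = "linear"
    bits: int = 8

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer", "categorical"):
            raise ValueError(f"unknown hyperparameter kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise ValueError("categorical spec requires categories")
            width = max(1, int(np.ceil(np.log2(len(self.categories)))))
            object.__setattr__(self, "bits", width)
        else:
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"{self.name}: range requires low < high")
            if self.scale == "log" and self.low <= 0:
                raise ValueError(f"{self.name}: log scale requires positive range")


@dataclass(frozen=True)
class LearnerSpec:
    id: str
    hyperparams: tuple[HyperparamSpec, ...]

    @property
    def total_bits(self) -> int:
        return sum(h.bits for h in self.hyperparams)


def default_pool() -> tuple[LearnerSpec, ...]:
    """The five-learner pool with its published search space."""
    return (
        LearnerSpec("LR", (
            HyperparamSpec("C", "continuous", 1e-3, 1e3, scale="log"),
            HyperparamSpec("penalty", "categorical", categories=("l1", "l2")),
        )),
        LearnerSpec("KNN", (
            HyperparamSpec("n_neighbors", "integer", 3, 15),
            HyperparamSpec("weights", "categorical", categories=("uniform", "distance")),
        )),
        LearnerSpec("AdaBoost", (
            HyperparamSpec("n_estimators", "integer", 50, 200),
            HyperparamSpec("learning_rate", "continuous", 0.01, 1.0),
        )),
        LearnerSpec("XGBoost", (
            HyperparamSpec("max_depth", "integer", 3, 10),
            HyperparamSpec("learning_rate", "continuous", 0.01, 0.3),
            HyperparamSpec("n_estimators", "integer", 100, 300),
        )),
        LearnerSpec("LightGBM", (
            HyperparamSpec("num_leaves", "integer", 31, 127),
            HyperparamSpec("learning_rate", "continuous", 0.01, 0.3),
            HyperparamSpec("feature_fraction", "continuous", 0.7, 1.0),
        )),
    )


@dataclass(frozen=True)
class EncodingLayout:
    n_features: int
    selector_bits: int = 3
    hp_bits: int = 0

    @property
    def total_bits(self) -> int:
        return self.n_features + self.selector_bits + self.hp_bits


def make_layout(n_features: int, pool: Sequence[LearnerSpec] | None = None) -> EncodingLayout:
    pool = tuple(pool) if pool is not None else default_pool()
    if len({l.id for l in pool}) != len(pool):
        raise ValueError("learner ids must be unique")
    return EncodingLayout(
        n_features=n_features,
        selector_bits=3,
        hp_bits=max(l.total_bits for l in pool),
    )


@dataclass(frozen=True)
class DecodedSolution:
    feature_mask: tuple[int, ...]
    learner: str
    hyperparams: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(sum(self.feature_mask))

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_mask": list(self.feature_mask),
                "learner": self.learner,
                "hyperparams": self.hyperparams,
            }
        )


def _bits_to_int(bits: np.ndarray) -> int:
    # MSB first
    return int(sum(int(b) << (len(bits) - 1 - i) for i, b in enumerate(bits)))


def _int_to_bits(value: int, width: int) -> list[int]:
    return [(value >> (width - 1 - i)) & 1 for i in range(width)]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def _decode_scalar(spec: HyperparamSpec, intval: int):
    f = intval / (2**spec.bits - 1)
    if spec.scale == "log":
        lo, hi = np.log10(spec.low), np.log10(spec.high)
        value = 10.0 ** (lo + f * (hi - lo))
    else:
        value = spec.low + f * (spec.high - spec.low)
    if spec.kind == "integer":
        return _round_half_away(value)
    return float(value)


def decode(
    bits: Sequence[int],
    layout: EncodingLayout,
    pool: Sequence[LearnerSpec],
    fallback_feature: int = 0,
) -> DecodedSolution:
    """Decode a bit vector; an all-zero feature mask is repaired."""
    bits = np.asarray(bits, dtype=np.int64)
    if bits.size != layout.total_bits:
        raise ValueError(
            f"bit vector has length {bits.size}, layout expects {layout.total_bits}"
        )
    mask = repair_mask(bits[: layout.n_features], fallback_feature)
    sel_bits = bits[layout.n_features : layout.n_features + layout.selector_bits]
    learner = pool[_bits_to_int(sel_bits) % len(pool)]
    hp_bits = bits[layout.n_features + layout.selector_bits :]
    params, offset = {}, 0
    for spec in learner.hyperparams:
        chunk = hp_bits[offset : offset + spec.bits]
        offset += spec.bits
        intval = _bits_to_int(chunk)
        if spec.kind == "categorical":
            params[spec.name] = spec.categories[intval % len(spec.categories)]
        else:
            params[spec.name] = _decode_scalar(spec, intval)
    return DecodedSolution(tuple(int(b) for b in mask), learner.id, params)


def encode(
    solution: DecodedSolution,
    layout: EncodingLayout,
    pool: Sequence[LearnerSpec],
) -> np.ndarray:
    """Inverse of ``decode`` up to scalar quantization (one step of the grid)."""
    if len(solution.feature_mask) != layout.n_features:
        raise ValueError("feature mask length does not match layout")
    ids = [l.id for l in pool]
    if solution.learner not in ids:
        raise ValueError(f"unknown learner {solution.learner!r}")
    learner_idx = ids.index(solution.learner)
    learner = pool[learner_idx]
    bits = list(solution.feature_mask)
    bits += _int_to_bits(learner_idx, layout.selector_bits)
    hp_bits: list[int] = []
    for spec in learner.hyperparams:
        value = solution.hyperparams[spec.name]
        if spec.kind == "categorical":
            intval = spec.categories.index(value)
        else:
            if not spec.low <= value <= spec.high:
                raise ValueError(f"{spec.name}={value} outside [{spec.low}, {spec.high}]")
            if spec.scale == "log":
                lo, hi = np.log10(spec.low), np.log10(spec.high)
                f = (np.log10(value) - lo) / (hi - lo)
            else:
                f = (value - spec.low) / (spec.high - spec.low)
            intval = int(round(f * (2**spec.bits - 1)))
        hp_bits += _int_to_bits(intval, spec.bits)
    hp_bits += [0] * (layout.hp_bits - len(hp_bits))
    return np.asarray(bits + hp_bits, dtype=np.int64)


def repair_mask(mask: Sequence[int], fallback_feature: int = 0) -> np.ndarray:
    """Guarantee a non-empty feature mask by setting the fallback bit."""
    mask = np.asarray(mask, dtype=np.int64).copy()
    if mask.size < 1:
        raise ValueError("mask must have length >= 1")
    if not mask.any():
        mask[fallback_feature] = 1
    return mask
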