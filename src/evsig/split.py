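"""Seeded stratified train/test splitting shared by the ML stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SplitSpec", "stratified_split"]


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]
    fraction_train: float
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")
        if not self.train_ids or not self.test_ids:
            raise ValueError("both train and test parts must be non-empty")


def stratified_split(
    sample_ids: Sequence[str],
    labels: Sequence,
    fraction_train: float = 0.7,
    seed: int = 0,
) -> SplitSpec:
    """Random class-stratified split preserving per-class proportions.

    Every class contributes at least one sample to each part; classes with a
    single sample are rejected (use a plain random split for such data).
    Deterministic for a fixed seed.
    """
    if not 0 < fraction_train < 1:
        raise ValueError("fraction_train must lie strictly between 0 and 1")
    if len(sample_ids) != len(labels):
        raise ValueError("sample_ids and labels must have equal length")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for sid, lbl in zip(sample_ids, labels):
        by_class.setdefault(lbl, []).append(sid)
    singletons = [str(lbl) for lbl, ids in by_class.items() if len(ids) < 2]
    if singletons:
        raise ValueError(
            f"class(es) with a single sample cannot be stratified: {singletons}; "
            "use a non-stratified split"
        )
    train: list[str] = []
    test: list[str] = []
    for lbl in by_class:  # insertion order: deterministic
        ids = by_class[lbl]
        perm = rng.permutation(len(ids))
        n_train = int(round(len(ids) * fraction_train))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return SplitSpec(train, test, fraction_train, True, seed)
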