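"""Dataset assembly: window trimming, merging, imbalance ratios, CV folds.

Trimming takes 398 nt windows down to a shorter symmetric window around
the junction, relocating the dimer from the 398-nt placement (donor
201-202, acceptor 198-199) to the derived placement (donor ``L/2``,
acceptor ``L/2 - 1``), which at ``L = 40`` coincides with the 40-nt
convention (20-21 / 19-20).

Imbalance subsetting follows the published protocol: 80% of the positives
are sampled for training, negatives are drawn to a fixed positive:negative
ratio (1:1, 1:3, 1:5, 1:7), and the holdout keeps the remaining 20% of
positives together with ALL remaining negatives — so the holdout is far
more imbalanced than the training pool, mimicking deployment conditions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .conventions import Label, derived_convention
from .sequences import SpliceSequence

ALLOWED_WINDOWS = (40, 80, 160, 240, 398)


@dataclass(frozen=True)
class RatioSpec:
    """A 1:n positive:negative training composition."""

    negative_parts: int = 1
    train_positive_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.negative_parts < 1:
            raise ValueError("negative_parts must be >= 1")
        if not 0.0 < self.train_positive_fraction < 1.0:
            raise ValueError("train_positive_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CVConfig:
    """Stratified k-fold cross-validation settings."""

    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def trim_window(record: SpliceSequence, length: int) -> SpliceSequence:
    """Trim a 398 nt window to ``length`` nt around the splice junction.

    ``length`` must be one of 40, 80, 160, 240 or 398; 398 is the
    identity. The slice is chosen so the dimer lands exactly at the
    derived-window position (donor ``L/2``, acceptor ``L/2 - 1``).
    """
    if length not in ALLOWED_WINDOWS:
        raise ValueError(f"target length must be one of {ALLOWED_WINDOWS}")
    src = record.convention
    if src.name != "GWH398":
        raise ValueError(
            f"can only trim 398 nt windows (GWH398 convention), "
            f"got {src.name}"
        )
    if length == 398:
        return record
    conv = derived_convention(record.site_type, length)
    # 0-based start so that src.dimer_start maps onto conv.dimer_start
    start = src.dimer_start - conv.dimer_start
    seq = record.seq[start:start + length]
    return SpliceSequence(seq, record.site_type, record.label, conv,
                          identifier=record.identifier)


def combine_datasets(a: list[SpliceSequence], b: list[SpliceSequence],
                     dedup: bool = True) -> list[SpliceSequence]:
    """Union of two datasets sharing a site type and window length.

    With ``dedup``, exact-duplicate sequences within the same label are
    kept once; a sequence appearing with both labels is a conflict and
    raises.
    """
    merged = list(a) + list(b)
    if not merged:
        return []
    site_types = {r.site_type for r in merged}
    lengths = {len(r) for r in merged}
    if len(site_types) > 1:
        raise ValueError(f"mixed site types: {sorted(s.value for s in site_types)}")
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    labels_by_seq: dict[str, set[Label]] = {}
    for r in merged:
        labels_by_seq.setdefault(r.seq, set()).add(r.label)
    conflicts = [s for s, labs in labels_by_seq.items() if len(labs) > 1]
    if conflicts:
        raise ValueError(
            f"{len(conflicts)} sequence(s) appear with both labels, "
            f"e.g. {conflicts[0]}"
        )
    if not dedup:
        return merged
    seen: set[str] = set()
    out = []
    for r in merged:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def subsample_ratio(dataset: list[SpliceSequence], ratio: RatioSpec,
                    seed: int) -> tuple[list[SpliceSequence], list[SpliceSequence]]:
    """Split into a ratio-restricted training pool and an imbalanced holdout.

    The training pool holds ``floor(f * P)`` positives (``f`` the training
    positive fraction, default 0.8) and exactly ``negative_parts`` times
    that many negatives, both sampled uniformly without replacement. The
    holdout holds every remaining record. Deterministic under ``seed``.
    """
    pos = [r for r in dataset if r.label is Label.POSITIVE]
    neg = [r for r in dataset if r.label is Label.NEGATIVE]
    n_train_pos = int(ratio.train_positive_fraction * len(pos))
    n_train_neg = ratio.negative_parts * n_train_pos
    if n_train_neg > len(neg):
        raise ValueError(
            f"ratio 1:{ratio.negative_parts} needs {n_train_neg} negatives "
            f"but only {len(neg)} are available"
        )
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    train = ([pos[i] for i in pos_idx[:n_train_pos]]
             + [neg[i] for i in neg_idx[:n_train_neg]])
    holdout = ([pos[i] for i in pos_idx[n_train_pos:]]
               + [neg[i] for i in neg_idx[n_train_neg:]])
    return train, holdout


def kfold_splits(dataset: list[SpliceSequence], cv: CVConfig
                 ) -> list[tuple[list[SpliceSequence], list[SpliceSequence]]]:
    """Stratified k-fold partition into (train, validation) record lists.

    Validation folds are disjoint, cover the dataset, differ in size by at
    most one record, and preserve the positive fraction within one record.
    """
    n = len(dataset)
    if cv.k > n:
        raise ValueError(f"k={cv.k} exceeds dataset size {n}")
    labels = [r.label.value for r in dataset]
    counts = Counter(labels)
    if min(counts.values(), default=0) < cv.k and len(counts) > 1:
        raise ValueError(
            f"each class needs at least k={cv.k} members for stratified folds"
        )
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    splits = []
    for train_idx, val_idx in skf.split(np.zeros(n), labels):
        splits.append(([dataset[i] for i in train_idx],
                       [dataset[i] for i in val_idx]))
    return splits
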