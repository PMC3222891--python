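"""Four-way decoding with leave-one-trial-out cross-validation and the
cross-classification (transfer) analyses.

The four-way analysis trains a one-vs-one linear SVM on all accurate trials
except one and predicts the held-out trial, for every trial in turn; chance
is 1/4.  The transfer analyses train a binary classifier on one pair of
conditions and test it on the disjoint pair sharing a latent factor:

* spatial context: train A vs B (same event, contexts differ), test C vs D,
  scoring a test trial correct when the predicted training condition shares
  its context (A->C, B->D);
* event content: train A vs C (same context, events differ), test B vs D,
  correct when the prediction shares the event (A->B, C->D).

Above-chance (0.5) transfer evidences a representation of the shared factor
that generalizes across memories.

Features are used raw by default: the decoding inputs are GLM t-maps, which
the beta-to-t conversion has already noise-normalized per voxel.  Optional
per-voxel z-scoring (``normalize="zscore"``) uses statistics from the
training fold only, applied unchanged to held-out trials, so neither mode
leaks held-out information into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .design import MEMORY_IDS, ConditionLabel, relation
from .exceptions import (
    InsufficientTrialsError,
    InvalidPairError,
    InvalidParameterError,
)
from .simulate import TrialPatternSet
from .svm import train_linear_svm  # noqa: F401  (re-exported API)

_CODE = {m: i for i, m in enumerate(MEMORY_IDS)}

_DEFAULT_TOL = 1e-4
_DEFAULT_MAX_ITER = 100_000


@dataclass
class DecodingResult:
    """Outcome of one participant's leave-one-trial-out four-way decoding."""

    participant_id: int
    roi_name: str
    true: np.ndarray        # memory ids, accurate trials only
    predicted: np.ndarray   # memory ids
    fold_index: np.ndarray
    accuracy: float
    confusion: np.ndarray   # 4x4 counts, rows true A-D, columns predicted
    chance: float = 0.25

    def __post_init__(self):
        total = int(self.confusion.sum())
        if total != len(self.true):
            raise InvalidParameterError("confusion total != trial count")

    @property
    def n_trials(self) -> int:
        return len(self.true)


@dataclass
class TransferResult:
    """Outcome of one participant's cross-classification analysis."""

    participant_id: int
    roi_name: str
    shared_factor: str
    train_pair: tuple
    test_pair: tuple
    accuracy: float
    n_test: int
    chance: float = 0.5


def _codes(memory_ids) -> np.ndarray:
    return np.array([_CODE[m] for m in memory_ids], dtype=np.int64)


def _prepare(patterns: TrialPatternSet, min_per_condition: int):
    acc = patterns.accurate_subset()
    mem = acc.memory_ids
    counts = {m: int(np.sum(mem == m)) for m in MEMORY_IDS}
    low = [m for m, c in counts.items() if c < min_per_condition]
    if low:
        raise InsufficientTrialsError(
            f"conditions {low} have fewer than {min_per_condition} accurate "
            f"trials (counts: {counts})"
        )
    return acc, mem


def loto_cv(
    patterns: TrialPatternSet,
    cost: float = 1.0,
    normalize: str = "none",
) -> DecodingResult:
    """Leave-one-trial-out four-way decoding of one pattern set.

    Only accurate trials are used; every accurate trial is held out exactly
    once and no information from it (values or normalization statistics)
    enters its training fold.  The default works on raw features (t-map
    features are already per-voxel noise-normalized); ``normalize="zscore"``
    adds per-voxel z-scoring with training-fold statistics.
    """
    if cost <= 0:
        raise InvalidParameterError("cost must be > 0")
    if normalize not in ("none", "zscore"):
        raise InvalidParameterError(f"unknown normalization {normalize!r}")
    acc, mem = _prepare(patterns, min_per_condition=2)
    y = _codes(mem)
    P = np.ascontiguousarray(acc.patterns)
    if normalize == "none":
        G = P @ P.T
        pred = _engine.loto_predict_raw(G, y, float(cost), _DEFAULT_TOL,
                                        _DEFAULT_MAX_ITER)
    else:
        G3 = _engine.fold_grams(P, normalize)
        pred = _engine.loto_predict(G3, y, float(cost), _DEFAULT_TOL,
                                    _DEFAULT_MAX_ITER)
    predicted = np.array(MEMORY_IDS)[pred]
    confusion = np.zeros((4, 4), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion)) / len(y)
    return DecodingResult(
        participant_id=acc.participant_id,
        roi_name=acc.roi_name,
        true=mem,
        predicted=predicted,
        fold_index=np.arange(len(y)),
        accuracy=accuracy,
        confusion=confusion,
    )


def _partner(label: ConditionLabel, rel: str) -> ConditionLabel:
    for m in MEMORY_IDS:
        other = ConditionLabel(m)
        if relation(label, other) == rel:
            return other
    raise InvalidParameterError(f"no {rel} partner for {label}")  # pragma: no cover


def transfer_pairs(shared_factor: str, train_pair=None):
    """Resolve (train_pair, test_pair) for a transfer analysis.

    The train pair must differ only in the shared factor (hold the other
    factor constant); each test condition is the train condition's partner
    under the shared factor.
    """
    if shared_factor == "context":
        default = ("A", "B")
        partner_rel = "spatial"       # same context, different event
        train_rel = "content"         # train pair shares event content
    elif shared_factor == "event":
        default = ("A", "C")
        partner_rel = "content"
        train_rel = "spatial"
    else:
        raise InvalidParameterError(
            "shared_factor must be 'context' or 'event'"
        )
    pair = tuple(train_pair) if train_pair is not None else default
    if len(pair) != 2:
        raise InvalidPairError("train pair must have exactly two conditions")
    la, lb = ConditionLabel(pair[0]), ConditionLabel(pair[1])
    if relation(la, lb) != train_rel:
        raise InvalidPairError(
            f"train pair {pair} must differ only in {shared_factor} "
            f"(e.g. {default})"
        )
    test = (_partner(la, partner_rel).memory_id,
            _partner(lb, partner_rel).memory_id)
    return (la.memory_id, lb.memory_id), test


def transfer_decode(
    patterns: TrialPatternSet,
    shared_factor: str,
    cost: float = 1.0,
    normalize: str = "none",
    train_pair=None,
) -> TransferResult:
    """Cross-classification of the shared factor across disjoint pairs."""
    if cost <= 0:
        raise InvalidParameterError("cost must be > 0")
    if normalize not in ("zscore", "none"):
        raise InvalidParameterError(f"unknown normalization {normalize!r}")
    train, test = transfer_pairs(shared_factor, train_pair)
    acc, mem = _prepare(patterns, min_per_condition=1)
    y = _codes(mem)
    accuracy = _engine.transfer_acc_one(
        np.ascontiguousarray(acc.patterns),
        y,
        _CODE[train[0]], _CODE[train[1]],
        _CODE[test[0]], _CODE[test[1]],
        float(cost), _DEFAULT_TOL, _DEFAULT_MAX_ITER,
        normalize == "zscore",
    )
    n_test = int(np.sum((mem == test[0]) | (mem == test[1])))
    return TransferResult(
        participant_id=acc.participant_id,
        roi_name=acc.roi_name,
        shared_factor=shared_factor,
        train_pair=train,
        test_pair=test,
        accuracy=float(accuracy),
        n_test=n_test,
    )
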