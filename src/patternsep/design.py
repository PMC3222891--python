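"""Experimental design: the 2x2 event-by-context condition structure and
balanced pseudo-random trial sequences.

Four overlapping memory conditions A-D arise from crossing two action events
with two spatial contexts:

========  =======  =========
memory    event    context
========  =======  =========
A         1        1
B         1        2
C         2        1
D         2        2
========  =======  =========

Every memory therefore shares its spatial context with exactly one other
memory (A-C, B-D), its event content with exactly one (A-B, C-D), and
neither factor with exactly one (A-D, B-C).  :func:`relation` encodes this
factorization; it drives both the cross-classification transfer scoring and
the misclassification decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .util import derive_rng

MEMORY_IDS = ("A", "B", "C", "D")

#: memory_id -> (event_id, context_id)
FACTORS = {"A": (1, 1), "B": (1, 2), "C": (2, 1), "D": (2, 2)}

RELATION_NAMES = ("correct", "spatial", "content", "orthogonal")


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """One of the four memory conditions with its event/context factors."""

    memory_id: str

    def __post_init__(self):
        if self.memory_id not in FACTORS:
            raise InvalidParameterError(
                f"memory_id must be one of {MEMORY_IDS}, got {self.memory_id!r}"
            )

    @property
    def event_id(self) -> int:
        return FACTORS[self.memory_id][0]

    @property
    def context_id(self) -> int:
        return FACTORS[self.memory_id][1]

    @classmethod
    def from_factors(cls, event_id: int, context_id: int) -> "ConditionLabel":
        for mem, (ev, cx) in FACTORS.items():
            if (ev, cx) == (event_id, context_id):
                return cls(mem)
        raise InvalidParameterError(
            f"no condition with event_id={event_id}, context_id={context_id}"
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.memory_id


CONDITIONS = tuple(ConditionLabel(m) for m in MEMORY_IDS)


def relation(true, predicted) -> str:
    """Classify a (true, predicted) condition pair.

    Returns ``"correct"`` for identical labels, ``"spatial"`` when only the
    spatial context is shared, ``"content"`` when only the event content is
    shared, and ``"orthogonal"`` when neither factor is shared.
    """
    true = _as_label(true)
    predicted = _as_label(predicted)
    if true == predicted:
        return "correct"
    same_context = true.context_id == predicted.context_id
    same_event = true.event_id == predicted.event_id
    if same_context and not same_event:
        return "spatial"
    if same_event and not same_context:
        return "content"
    return "orthogonal"


def _as_label(x) -> ConditionLabel:
    if isinstance(x, ConditionLabel):
        return x
    return ConditionLabel(str(x))


@dataclass
class ExperimentDesign:
    """Balanced pseudo-random trial schedule for a group of participants.

    ``trial_orders`` is an ``(n_participants, n_trials)`` array of memory-id
    strings; all participants share the same onset grid (``onsets``, seconds,
    strictly increasing) while their condition orders are independent.
    """

    n_participants: int
    n_trials_per_condition: int
    trial_orders: np.ndarray
    onsets: np.ndarray
    recall_duration: float
    inter_trial_interval: float
    tr: float
    seed: int | None = field(default=None)

    @property
    def n_trials(self) -> int:
        return 4 * self.n_trials_per_condition

    def labels(self, participant: int) -> list[ConditionLabel]:
        """Condition labels for one participant, in trial order."""
        return [ConditionLabel(m) for m in self.trial_orders[participant]]

    def validate(self) -> None:
        orders = np.asarray(self.trial_orders)
        if orders.shape != (self.n_participants, self.n_trials):
            raise InvalidParameterError("trial_orders shape mismatch")
        for p in range(self.n_participants):
            row = orders[p]
            for mem in MEMORY_IDS:
                if int(np.sum(row == mem)) != self.n_trials_per_condition:
                    raise InvalidParameterError(
                        f"participant {p}: unbalanced count for memory {mem}"
                    )
            if np.any(row[1:] == row[:-1]):
                raise InvalidParameterError(
                    f"participant {p}: adjacent repeat in trial order"
                )
        if np.any(np.diff(self.onsets) <= 0):
            raise InvalidParameterError("onsets must be strictly increasing")
        if self.recall_duration <= 0 or self.tr <= 0:
            raise InvalidParameterError("timings must be positive")


def _sample_order(rng: np.random.Generator, n_per_condition: int,
                  max_restarts: int = 10_000) -> np.ndarray:
    """One balanced order with no adjacent repeats.

    Builds the sequence left to right, drawing each label with probability
    proportional to its remaining count among labels different from the
    previous one; restarts on a dead end (all remaining trials belong to the
    previous label).  Dead ends are rare for balanced designs, and the
    construction is exchangeable over condition labels, so every condition
    is equally likely at every serial position.
    """
    n_classes = 4
    for _ in range(max_restarts):
        counts = np.full(n_classes, n_per_condition, dtype=np.int64)
        order = np.empty(n_classes * n_per_condition, dtype=np.int64)
        prev = -1
        ok = True
        for t in range(order.size):
            weights = counts.astype(np.float64)
            if prev >= 0:
                weights[prev] = 0.0
            total = weights.sum()
            if total <= 0:
                ok = False
                break
            choice = rng.choice(n_classes, p=weights / total)
            order[t] = choice
            counts[choice] -= 1
            prev = choice
        if ok:
            return order
    raise InvalidParameterError(
        f"could not build a valid trial order in {max_restarts} restarts"
    )


def make_design(
    n_participants: int = 15,
    n_trials_per_condition: int = 20,
    *,
    recall_duration: float = 12.0,
    inter_trial_interval: float = 4.0,
    tr: float = 2.0,
    seed: int = 0,
) -> ExperimentDesign:
    """Generate a balanced pseudo-random design.

    Each participant receives an independent order in which every memory
    occurs exactly ``n_trials_per_condition`` times and the same memory never
    appears twice in a row.  Deterministic given ``seed``.
    """
    if n_participants < 1 or n_trials_per_condition < 1:
        raise InvalidParameterError("counts must be >= 1")
    if recall_duration <= 0 or inter_trial_interval <= 0 or tr <= 0:
        raise InvalidParameterError("timing parameters must be positive")

    mem_arr = np.array(MEMORY_IDS)
    orders = np.empty((n_participants, 4 * n_trials_per_condition), dtype="U1")
    for p in range(n_participants):
        rng = derive_rng(seed, "design", p)
        orders[p] = mem_arr[_sample_order(rng, n_trials_per_condition)]

    n_trials = 4 * n_trials_per_condition
    spacing = recall_duration + inter_trial_interval
    onsets = np.arange(n_trials, dtype=np.float64) * spacing

    design = ExperimentDesign(
        n_participants=n_participants,
        n_trials_per_condition=n_trials_per_condition,
        trial_orders=orders,
        onsets=onsets,
        recall_duration=recall_duration,
        inter_trial_interval=inter_trial_interval,
        tr=tr,
        seed=seed,
    )
    design.validate()
    return design


def events_frame(design: ExperimentDesign, participant: int,
                 accurate=None) -> pd.DataFrame:
    """BIDS-events-style table for one participant.

    Columns: onset, duration, memory_id, event_id, context_id, accurate.
    """
    labels = design.labels(participant)
    if accurate is None:
        accurate = np.ones(len(labels), dtype=bool)
    accurate = np.asarray(accurate, dtype=bool)
    if accurate.shape != (len(labels),):
        raise InvalidParameterError("accurate flags must match trial count")
    return pd.DataFrame(
        {
            "onset": design.onsets,
            "duration": np.full(len(labels), design.recall_duration),
            "memory_id": [l.memory_id for l in labels],
            "event_id": [l.event_id for l in labels],
            "context_id": [l.context_id for l in labels],
            "accurate": accurate.astype(int),
        }
    )


def write_events(design: ExperimentDesign, path, participant: int,
                 accurate=None) -> None:
    """Write one participant's events as a tab-separated table."""
    events_frame(design, participant, accurate).to_csv(
        path, sep="\t", index=False
    )


def read_events(path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "memory_id", "accurate"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"events table missing columns {sorted(missing)}")
    df["accurate"] = df["accurate"].astype(bool)
    return df
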