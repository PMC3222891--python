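"""Misclassification decomposition and group-level inference.

Group tests follow the study's reporting convention: one-sample (or paired)
Student t with df = n_participants - 1 and a one-tailed upper-tail p-value.
The nonparametric alternative permutes the condition-label vector over
trials independently within each participant, reruns the full decoding
analysis, and compares the observed group mean against the null group means
with the add-one rule

    perm_p = (1 + #{null >= observed}) / (1 + n_permutations),

which can never return zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import _engine
from .decode import _CODE, _DEFAULT_MAX_ITER, _DEFAULT_TOL, _prepare, transfer_pairs
from .design import MEMORY_IDS, relation
from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    ZeroVarianceError,
)
from .util import derive_rng

ANALYSES = ("fourway", "context_transfer", "content_transfer")

_REL_KEYS = ("spatial", "content", "orthogonal")


@dataclass
class MisclassProfile:
    """Decomposition of one participant's four-way decoding errors."""

    counts: dict
    proportions: dict | None
    total_errors: int

    @property
    def defined(self) -> bool:
        return self.proportions is not None


def misclass_profile(result) -> MisclassProfile:
    """Assign every off-diagonal confusion cell to its error type.

    An error is *spatial* when the predicted memory shares the true trial's
    spatial context, *content* when it shares its event content, and
    *orthogonal* when it shares neither.  With zero errors the proportions
    are undefined (flagged ``None``).
    """
    confusion = np.asarray(result.confusion)
    counts = {k: 0 for k in _REL_KEYS}
    for i, true_mem in enumerate(MEMORY_IDS):
        for j, pred_mem in enumerate(MEMORY_IDS):
            if i == j:
                continue
            counts[relation(true_mem, pred_mem)] += int(confusion[i, j])
    total = sum(counts.values())
    props = (
        {k: counts[k] / total for k in _REL_KEYS} if total > 0 else None
    )
    return MisclassProfile(counts=counts, proportions=props, total_errors=total)


@dataclass
class PairedComparison:
    """Paired one-tailed t comparison between two error proportions."""

    contrast: str
    t: float
    df: int
    p: float
    n_used: int
    mean_difference: float


def compare_misclass(profiles, contrast: str) -> PairedComparison:
    """Paired t-test of spatial against content or orthogonal proportions.

    One-tailed in the direction "spatial greater".  Participants with zero
    misclassifications have undefined proportions and are excluded with a
    warning.
    """
    if contrast == "spatial_vs_content":
        other = "content"
    elif contrast == "spatial_vs_orthogonal":
        other = "orthogonal"
    else:
        raise InvalidParameterError(
            "contrast must be 'spatial_vs_content' or 'spatial_vs_orthogonal'"
        )
    usable = [p for p in profiles if p.defined]
    n_dropped = len(list(profiles)) - len(usable)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} participant(s) with zero misclassifications "
            "excluded from the paired comparison",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise InsufficientDataError(
            "paired comparison needs >= 2 participants with errors"
        )
    diffs = np.array(
        [p.proportions["spatial"] - p.proportions[other] for p in usable]
    )
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        if diffs.mean() == 0:
            t = 0.0  # exact null: no difference anywhere
        else:
            raise ZeroVarianceError(
                "difference scores have zero variance but nonzero mean"
            )
    else:
        t = diffs.mean() / (sd / np.sqrt(n))
    return PairedComparison(
        contrast=contrast,
        t=float(t),
        df=n - 1,
        p=t_tail_p(t, n - 1),
        n_used=n,
        mean_difference=float(diffs.mean()),
    )


@dataclass
class GroupResult:
    """Group-level summary of per-participant accuracies against chance."""

    analysis: str
    per_participant: np.ndarray
    chance: float
    mean: float
    sem: float
    t: float
    df: int
    p: float
    perm_p: float | None = None
    n_permutations: int = 0

    @property
    def pct_above_chance(self) -> float:
        return 100.0 * (self.mean - self.chance)


def t_vs_chance(per_participant, chance: float,
                analysis: str = "fourway") -> GroupResult:
    """One-sample t of participant accuracies against the chance level.

    One-tailed (upper tail), df = n - 1.
    """
    acc = np.asarray(per_participant, dtype=np.float64)
    if acc.size < 2:
        raise InsufficientDataError("group test needs >= 2 participants")
    if not np.all(np.isfinite(acc)):
        raise InvalidParameterError("accuracies must be finite")
    d = acc - chance
    sd = d.std(ddof=1)
    n = acc.size
    if sd == 0:
        if d.mean() == 0:
            t = 0.0  # every participant exactly at chance
        else:
            raise ZeroVarianceError(
                "accuracies have zero variance across participants"
            )
    else:
        t = d.mean() / (sd / np.sqrt(n))
    return GroupResult(
        analysis=analysis,
        per_participant=acc,
        chance=float(chance),
        mean=float(acc.mean()),
        sem=float(acc.std(ddof=1) / np.sqrt(n)),
        t=float(t),
        df=n - 1,
        p=t_tail_p(t, n - 1),
    )


def t_tail_p(t: float, df: int) -> float:
    """Upper-tail probability of Student's t at ``t`` with ``df`` degrees of
    freedom (the study's one-tailed reporting convention)."""
    if df < 1:
        raise InvalidParameterError("df must be >= 1")
    return float(sps.t.sf(t, df))


def _participant_accuracy_machinery(pset, analysis, cost, normalize):
    """(observed accuracy, null-accuracy function) for one participant."""
    min_per = 2 if analysis == "fourway" else 1
    acc, mem = _prepare(pset, min_per_condition=min_per)
    y = np.array([_CODE[m] for m in mem], dtype=np.int64)
    P = np.ascontiguousarray(acc.patterns)
    cost = float(cost)
    if analysis == "fourway":
        if normalize == "none":
            G = P @ P.T

            def run(perms):
                return _engine.perm_fourway_acc_raw(
                    G, perms, cost, _DEFAULT_TOL, _DEFAULT_MAX_ITER
                )
        else:
            G3 = _engine.fold_grams(P, normalize)

            def run(perms):
                return _engine.perm_fourway_acc(
                    G3, perms, cost, _DEFAULT_TOL, _DEFAULT_MAX_ITER
                )
    else:
        factor = "context" if analysis == "context_transfer" else "event"
        train, test = transfer_pairs(factor)
        t0, t1 = _CODE[train[0]], _CODE[train[1]]
        s0, s1 = _CODE[test[0]], _CODE[test[1]]

        def run(perms):
            return _engine.perm_transfer_acc(
                P, perms, t0, t1, s0, s1,
                cost, _DEFAULT_TOL, _DEFAULT_MAX_ITER,
                normalize == "zscore",
            )

    observed = float(run(y[None, :])[0])
    return observed, y, run


def permutation_test(
    pattern_sets,
    analysis: str = "fourway",
    n_perm: int = 500,
    seed: int = 0,
    cost: float = 1.0,
    normalize: str = "none",
) -> GroupResult:
    """Group-level label-permutation test of a decoding analysis.

    For each of ``n_perm`` iterations the condition labels are permuted over
    trials independently within every participant, the full analysis is
    rerun, and the group mean accuracy recorded; ``perm_p`` uses the add-one
    rule.  The parametric one-tailed t against chance is reported alongside
    (NaN if the accuracies have no variance).  Deterministic given ``seed``.
    """
    if analysis not in ANALYSES:
        raise InvalidParameterError(
            f"analysis must be one of {ANALYSES}, got {analysis!r}"
        )
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    if normalize not in ("none", "zscore"):
        raise InvalidParameterError(f"unknown normalization {normalize!r}")
    chance = 0.25 if analysis == "fourway" else 0.5
    observed = []
    null = np.zeros((len(pattern_sets), n_perm))
    for k, pset in enumerate(pattern_sets):
        obs, y, run = _participant_accuracy_machinery(
            pset, analysis, cost, normalize
        )
        observed.append(obs)
        rng = derive_rng(seed, "perm", analysis, pset.participant_id)
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
        null[k] = run(perms)
    observed = np.asarray(observed)
    null_means = null.mean(axis=0)
    obs_mean = observed.mean()
    n_ge = int(np.sum(null_means >= obs_mean - 1e-12))
    perm_p = (1 + n_ge) / (1 + n_perm)
    try:
        base = t_vs_chance(observed, chance, analysis)
        t, df, p, sem = base.t, base.df, base.p, base.sem
    except (ZeroVarianceError, InsufficientDataError):
        n = observed.size
        t, df, p, sem = np.nan, n - 1, np.nan, 0.0
    return GroupResult(
        analysis=analysis,
        per_participant=observed,
        chance=chance,
        mean=float(obs_mean),
        sem=float(sem),
        t=float(t),
        df=int(df),
        p=float(p) if np.isfinite(t) else np.nan,
        perm_p=float(perm_p),
        n_permutations=int(n_perm),
    )
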