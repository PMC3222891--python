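"""Group-level decoding model with a statsmodels-style fit/results surface.

:class:`MemoryDecodingModel` wraps the per-participant pattern sets of one
ROI; ``fit()`` runs the requested analyses (four-way leave-one-trial-out
decoding, spatial-context and event-content cross-classification, and the
misclassification decomposition) and returns a
:class:`MemoryDecodingResults` carrying per-participant estimates, group
means with standard errors, one-tailed t statistics against chance,
optional permutation p-values, and a ``summary()`` table.

Example
-------
>>> from patternsep import make_design, generate_patterns, MemoryDecodingModel
>>> design = make_design(n_participants=15, n_trials_per_condition=20, seed=7)
>>> model = MemoryDecodingModel(generate_patterns(design, seed=7))
>>> res = model.fit(n_perm=500, seed=7)
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decode import DecodingResult, TransferResult, loto_cv, transfer_decode
from .design import ExperimentDesign
from .exceptions import InvalidParameterError
from .inference import (
    ANALYSES,
    GroupResult,
    MisclassProfile,
    PairedComparison,
    compare_misclass,
    misclass_profile,
    permutation_test,
    t_vs_chance,
)
from .simulate import SignalSpec, TrialPatternSet, generate_patterns


def _group_result(accuracies, chance, name) -> GroupResult:
    """t_vs_chance, degrading to NaN statistics when the accuracies are
    constant but off chance (the test is undefined, the mean still reported)."""
    from .exceptions import ZeroVarianceError

    try:
        return t_vs_chance(accuracies, chance, name)
    except ZeroVarianceError:
        acc = np.asarray(accuracies, dtype=np.float64)
        return GroupResult(
            analysis=name,
            per_participant=acc,
            chance=float(chance),
            mean=float(acc.mean()),
            sem=0.0,
            t=np.nan,
            df=acc.size - 1,
            p=np.nan,
        )


class MemoryDecodingModel:
    """MVPA decoding analyses for one ROI across participants.

    Parameters
    ----------
    pattern_sets
        One :class:`TrialPatternSet` per participant (same ROI).
    """

    def __init__(self, pattern_sets):
        pattern_sets = list(pattern_sets)
        if not pattern_sets:
            raise InvalidParameterError("at least one pattern set is required")
        rois = {p.roi_name for p in pattern_sets}
        if len(rois) > 1:
            raise InvalidParameterError(
                f"pattern sets span multiple ROIs: {sorted(rois)}"
            )
        self.pattern_sets = pattern_sets
        self.roi_name = pattern_sets[0].roi_name

    @classmethod
    def from_simulation(
        cls,
        design: ExperimentDesign | None = None,
        signal: SignalSpec | None = None,
        seed: int = 0,
        roi_name: str = "HC",
        **design_kwargs,
    ) -> "MemoryDecodingModel":
        """Build the model directly from the synthetic generator."""
        from .design import make_design

        if design is None:
            design = make_design(seed=seed, **design_kwargs)
        return cls(
            generate_patterns(design, signal, seed=seed, roi_name=roi_name)
        )

    @property
    def n_participants(self) -> int:
        return len(self.pattern_sets)

    def fit(
        self,
        analyses=ANALYSES,
        cost: float = 1.0,
        normalize: str = "none",
        n_perm: int = 0,
        seed: int = 0,
    ) -> "MemoryDecodingResults":
        """Run the decoding analyses and group inference.

        ``n_perm > 0`` adds the label-permutation test (>= 100 iterations)
        to every analysis.
        """
        analyses = tuple(analyses)
        unknown = set(analyses) - set(ANALYSES)
        if unknown:
            raise InvalidParameterError(f"unknown analyses: {sorted(unknown)}")
        decodings: list[DecodingResult] = []
        transfers: dict[str, list[TransferResult]] = {
            "context_transfer": [],
            "content_transfer": [],
        }
        misclass: list[MisclassProfile] = []
        for pset in self.pattern_sets:
            if "fourway" in analyses:
                d = loto_cv(pset, cost=cost, normalize=normalize)
                decodings.append(d)
                misclass.append(misclass_profile(d))
            for name, factor in (
                ("context_transfer", "context"),
                ("content_transfer", "event"),
            ):
                if name in analyses:
                    transfers[name].append(
                        transfer_decode(
                            pset, factor, cost=cost, normalize=normalize
                        )
                    )

        group: dict[str, GroupResult] = {}
        if "fourway" in analyses:
            group["fourway"] = _group_result(
                [d.accuracy for d in decodings], 0.25, "fourway"
            )
        for name in ("context_transfer", "content_transfer"):
            if name in analyses:
                group[name] = _group_result(
                    [t.accuracy for t in transfers[name]], 0.5, name
                )
        if n_perm:
            for name in analyses:
                perm = permutation_test(
                    self.pattern_sets,
                    analysis=name,
                    n_perm=n_perm,
                    seed=seed,
                    cost=cost,
                    normalize=normalize,
                )
                group[name].perm_p = perm.perm_p
                group[name].n_permutations = perm.n_permutations

        misclass_tests: dict[str, PairedComparison] = {}
        if "fourway" in analyses and self.n_participants >= 2:
            for contrast in ("spatial_vs_content", "spatial_vs_orthogonal"):
                try:
                    misclass_tests[contrast] = compare_misclass(
                        misclass, contrast
                    )
                except Exception:  # degenerate groups stay unreported
                    pass
        return MemoryDecodingResults(
            model=self,
            decodings=decodings,
            transfers={k: v for k, v in transfers.items() if v},
            misclass=misclass,
            misclass_tests=misclass_tests,
            group=group,
            cost=cost,
            normalize=normalize,
            seed=seed,
        )


@dataclass
class MemoryDecodingResults:
    """Fitted decoding analyses for one ROI."""

    model: MemoryDecodingModel
    decodings: list
    transfers: dict
    misclass: list
    misclass_tests: dict
    group: dict
    cost: float
    normalize: str
    seed: int

    @property
    def roi_name(self) -> str:
        return self.model.roi_name

    def to_frame(self) -> pd.DataFrame:
        """Group-level table: one row per analysis."""
        rows = []
        for name, g in self.group.items():
            rows.append(
                {
                    "roi": self.roi_name,
                    "analysis": name,
                    "n_participants": g.per_participant.size,
                    "mean_accuracy": g.mean,
                    "chance": g.chance,
                    "pct_above_chance": g.pct_above_chance,
                    "sem": g.sem,
                    "t": g.t,
                    "df": g.df,
                    "p_one_tailed": g.p,
                    "perm_p": g.perm_p if g.perm_p is not None else np.nan,
                    "n_permutations": g.n_permutations,
                }
            )
        return pd.DataFrame(rows)

    def misclass_frame(self) -> pd.DataFrame:
        """Per-participant misclassification proportions."""
        rows = []
        for pset, prof in zip(self.model.pattern_sets, self.misclass):
            row = {"roi": self.roi_name,
                   "participant": pset.participant_id,
                   "total_errors": prof.total_errors}
            for k in ("spatial", "content", "orthogonal"):
                row[f"count_{k}"] = prof.counts[k]
                row[f"prop_{k}"] = (
                    prof.proportions[k] if prof.defined else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable results table."""
        lines = [
            f"Memory decoding results — ROI {self.roi_name}",
            "=" * 58,
            f"participants: {self.model.n_participants}   "
            f"cost: {self.cost}   normalize: {self.normalize}",
            "",
            f"{'analysis':<18}{'acc':>7}{'chance':>8}{'%>ch':>7}"
            f"{'t':>8}{'p(1t)':>8}{'perm p':>9}",
            "-" * 65,
        ]
        for name, g in self.group.items():
            perm = f"{g.perm_p:.4f}" if g.perm_p is not None else "     --"
            lines.append(
                f"{name:<18}{g.mean:>7.3f}{g.chance:>8.2f}"
                f"{g.pct_above_chance:>7.1f}{g.t:>8.2f}{g.p:>8.4f}{perm:>9}"
            )
        if self.misclass_tests:
            lines += ["", "misclassification contrasts (paired, one-tailed):"]
            for name, c in self.misclass_tests.items():
                lines.append(
                    f"  {name:<24} t = {c.t:7.3f}  df = {c.df:2d}  "
                    f"P = {c.p:.3f}  (n = {c.n_used})"
                )
        return "\n".join(lines)

    def plot_accuracy(self, ax=None):
        """Bar chart of percentage-above-chance accuracy with SEM bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        names = list(self.group)
        vals = [self.group[n].pct_above_chance for n in names]
        errs = [100 * self.group[n].sem for n in names]
        ax.bar(range(len(names)), vals, yerr=errs, capsize=4,
               color="#4878a8")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=20, ha="right")
        ax.set_ylabel("% accuracy above chance")
        ax.set_title(f"ROI {self.roi_name}")
        return ax
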