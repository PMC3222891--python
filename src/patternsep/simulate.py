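"""Synthetic voxel-pattern and BOLD time-series generator.

The generative model mirrors the signal structure whose detectability the
analyses test.  For each participant, eight unit-norm voxel templates are
drawn: one per memory (the "bound" trace u_A..u_D), one per spatial context
(v_1, v_2) and one per event (w_1, w_2).  A trial of memory m in context c
with event e produces the pattern

    amp_bound * u_m + amp_context * v_c + amp_event * w_e + noise,

with isotropic Gaussian noise of standard deviation ``noise_sd``.  Recall
accuracy flags are Bernoulli(1 - p_inaccurate).  Templates are drawn
independently per participant (no shared group topography), matching the
within-participant decoding design.

Default amplitudes (bound 1.5, context 1.5, event 0 at unit noise and 300
voxels) reflect the study's empirical ordering — unique bound traces and a
shared spatial-context code are detectable with clear margin, a shared
event-content code is not — and were fixed once by an amplitude sweep
against the decoding stage (see the methods note).

:func:`generate_timeseries` optionally pushes the same per-trial amplitudes
through an HRF-convolved design matrix so the single-trial GLM stage can be
exercised and checked for exact recovery in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import MEMORY_IDS, ConditionLabel, ExperimentDesign
from .exceptions import InvalidParameterError, ShapeError
from .util import derive_rng


@dataclass(frozen=True)
class SignalSpec:
    """Amplitudes and noise level of the synthetic pattern generator.

    All amplitudes are in the same arbitrary units as the noise standard
    deviation; only their ratios matter for decodability.
    """

    n_voxels: int = 300
    amp_bound: float = 1.5
    amp_context: float = 1.5
    amp_event: float = 0.0
    noise_sd: float = 1.0
    p_inaccurate: float = 0.05

    def __post_init__(self):
        if self.n_voxels < 1:
            raise InvalidParameterError("n_voxels must be >= 1")
        for name in ("amp_bound", "amp_context", "amp_event"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0")
        if not (np.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise InvalidParameterError("noise_sd must be > 0")
        if not (0 <= self.p_inaccurate < 1):
            raise InvalidParameterError("p_inaccurate must be in [0, 1)")

    def with_(self, **kwargs) -> "SignalSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Temporal noise model for synthetic BOLD series (white or AR(1))."""

    kind: str = "white"
    sd: float = 1.0
    rho: float = 0.0

    def __post_init__(self):
        if self.kind not in ("white", "ar1"):
            raise InvalidParameterError("noise kind must be 'white' or 'ar1'")
        if self.sd < 0:
            raise InvalidParameterError("noise sd must be >= 0")
        if not (-1 < self.rho < 1):
            raise InvalidParameterError("AR(1) rho must be in (-1, 1)")


@dataclass
class TrialPatternSet:
    """Trials x voxels activation patterns for one participant and ROI."""

    participant_id: int
    roi_name: str
    patterns: np.ndarray
    labels: list
    accurate: np.ndarray

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=np.float64)
        self.accurate = np.asarray(self.accurate, dtype=bool)
        self.labels = [
            l if isinstance(l, ConditionLabel) else ConditionLabel(str(l))
            for l in self.labels
        ]
        n = self.patterns.shape[0]
        if len(self.labels) != n or self.accurate.shape != (n,):
            raise ShapeError("patterns, labels and accurate flags must agree")
        if not np.all(np.isfinite(self.patterns)):
            raise InvalidParameterError("patterns must be finite")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    @property
    def memory_ids(self) -> np.ndarray:
        return np.array([l.memory_id for l in self.labels])

    def accurate_subset(self) -> "TrialPatternSet":
        """Restrict to accurately recalled trials."""
        keep = self.accurate
        return TrialPatternSet(
            participant_id=self.participant_id,
            roi_name=self.roi_name,
            patterns=self.patterns[keep],
            labels=[l for l, k in zip(self.labels, keep) if k],
            accurate=np.ones(int(keep.sum()), dtype=bool),
        )

    def to_frame(self) -> pd.DataFrame:
        """Patterns as a DataFrame with label/accuracy columns prepended."""
        df = pd.DataFrame(
            self.patterns,
            columns=[f"v{i:04d}" for i in range(self.n_voxels)],
        )
        df.insert(0, "accurate", self.accurate.astype(int))
        df.insert(0, "memory_id", self.memory_ids)
        return df


@dataclass
class ParticipantTemplates:
    """The eight unit-norm voxel templates of one participant."""

    bound: dict      # memory_id -> (n_voxels,)
    context: dict    # context_id -> (n_voxels,)
    event: dict      # event_id -> (n_voxels,)


@dataclass
class SyntheticTimeseries:
    """Voxels x timepoints synthetic BOLD series with its generating truth."""

    participant_id: int
    series: np.ndarray
    tr: float
    design_ref: ExperimentDesign
    amplitudes: np.ndarray  # trials x voxels ground-truth betas
    accurate: np.ndarray


def _unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def draw_templates(rng: np.random.Generator, n_voxels: int,
                   orthogonalize: bool = False) -> ParticipantTemplates:
    """Draw the eight per-participant templates.

    Independent normalized Gaussian vectors (near-orthogonal at realistic
    voxel counts); with ``orthogonalize=True`` they are Gram-Schmidt
    orthonormalized for exact analyses.
    """
    if orthogonalize and n_voxels < 8:
        raise InvalidParameterError("orthogonalization needs n_voxels >= 8")
    vecs = [_unit(rng, n_voxels) for _ in range(8)]
    if orthogonalize:
        basis = []
        for v in vecs:
            for b in basis:
                v = v - (v @ b) * b
            v = v / np.linalg.norm(v)
            basis.append(v)
        vecs = basis
    return ParticipantTemplates(
        bound=dict(zip(MEMORY_IDS, vecs[:4])),
        context={1: vecs[4], 2: vecs[5]},
        event={1: vecs[6], 2: vecs[7]},
    )


def _signal_matrix(labels, spec: SignalSpec,
                   templates: ParticipantTemplates) -> np.ndarray:
    """Noise-free trials x voxels amplitude matrix for a label sequence."""
    out = np.zeros((len(labels), spec.n_voxels))
    for i, lab in enumerate(labels):
        out[i] = (
            spec.amp_bound * templates.bound[lab.memory_id]
            + spec.amp_context * templates.context[lab.context_id]
            + spec.amp_event * templates.event[lab.event_id]
        )
    return out


def generate_patterns(
    design: ExperimentDesign,
    spec: SignalSpec | None = None,
    seed: int = 0,
    *,
    orthogonalize: bool = False,
    roi_name: str = "HC",
) -> list[TrialPatternSet]:
    """Generate one :class:`TrialPatternSet` per participant.

    Deterministic given ``seed``; per-participant streams are derived by
    stable hashing so participants are independent and insertion-order free.
    """
    spec = spec or SignalSpec()
    out = []
    for p in range(design.n_participants):
        rng = derive_rng(seed, "patterns", roi_name, p)
        templates = draw_templates(rng, spec.n_voxels, orthogonalize)
        labels = design.labels(p)
        signal = _signal_matrix(labels, spec, templates)
        noise = rng.normal(0.0, spec.noise_sd, size=signal.shape)
        accurate = rng.random(len(labels)) >= spec.p_inaccurate
        out.append(
            TrialPatternSet(
                participant_id=p,
                roi_name=roi_name,
                patterns=signal + noise,
                labels=labels,
                accurate=accurate,
            )
        )
    return out


def generate_timeseries(
    design: ExperimentDesign,
    spec: SignalSpec | None = None,
    hrf=None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    orthogonalize: bool = False,
    drift_order: int = 1,
) -> list[SyntheticTimeseries]:
    """Generate synthetic BOLD series whose GLM betas are the pattern model.

    ``series = B_trial @ X_trial.T + E`` where X is the HRF-convolved design
    matrix (trial columns only; drift amplitudes are zero) and B holds the
    noise-free per-trial voxel amplitudes of the generative model.  With
    ``noise.sd == 0`` the single-trial GLM recovers B exactly.
    """
    from .glm import HRFParams, build_design_matrix  # deferred: avoid cycle

    spec = spec or SignalSpec()
    hrf = hrf or HRFParams()
    noise = noise or NoiseModel()
    X = build_design_matrix(design, hrf, drift_order=drift_order)
    n_trials = design.n_trials
    X_trial = X.values[:, :n_trials]  # trial regressors lead the matrix
    out = []
    for p in range(design.n_participants):
        rng = derive_rng(seed, "timeseries", p)
        templates = draw_templates(rng, spec.n_voxels, orthogonalize)
        labels = design.labels(p)
        B = _signal_matrix(labels, spec, templates)  # trials x voxels
        clean = B.T @ X_trial.T  # voxels x timepoints
        if noise.sd > 0:
            eps = rng.normal(0.0, noise.sd, size=clean.shape)
            if noise.kind == "ar1" and noise.rho != 0.0:
                # recursively colour the innovations along time
                eps[:, 0] = eps[:, 0] / np.sqrt(1 - noise.rho**2)
                for t in range(1, eps.shape[1]):
                    eps[:, t] += noise.rho * eps[:, t - 1]
            series = clean + eps
        else:
            series = clean
        accurate = rng.random(len(labels)) >= spec.p_inaccurate
        out.append(
            SyntheticTimeseries(
                participant_id=p,
                series=series,
                tr=design.tr,
                design_ref=design,
                amplitudes=B,
                accurate=accurate,
            )
        )
    return out
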