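"""Single-trial general linear model.

Each recall period is modeled as its own boxcar regressor convolved with a
canonical double-gamma HRF, all trials in one simultaneous model together
with polynomial drift terms and a constant.  Ordinary least squares yields a
beta estimate per trial per voxel; betas are converted to t values with the
per-regressor standard error from the full-model residuals,

    t_i = beta_i / sqrt(sigma2 * [(X'X)^-1]_ii),

producing one t-value pattern per accurately recalled trial — the feature
vectors used by the decoding stage.

No prewhitening is applied: exact-recovery guarantees hold for white-noise
generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .design import ExperimentDesign
from .exceptions import (
    DegenerateInputError,
    InsufficientTrialsError,
    InvalidParameterError,
    ShapeError,
    SingularDesignError,
)
from .simulate import SyntheticTimeseries, TrialPatternSet


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds / unitless).

    Defaults follow the standard convention: response peak around 5-6 s,
    undershoot peaking around 15-16 s at one sixth the amplitude, 32 s
    kernel.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0

    def __post_init__(self):
        vals = (
            self.peak_delay,
            self.undershoot_delay,
            self.peak_dispersion,
            self.undershoot_dispersion,
            self.undershoot_ratio,
            self.kernel_length,
        )
        if any((not np.isfinite(v)) or v <= 0 for v in vals):
            raise InvalidParameterError("all HRF parameters must be positive")
        if self.kernel_length <= self.undershoot_delay:
            raise InvalidParameterError(
                "kernel_length must exceed undershoot_delay"
            )


def canonical_hrf(tr: float, params: HRFParams | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at resolution ``tr``.

    Difference of two gamma densities (peak minus ``undershoot_ratio`` times
    undershoot), peak-normalized to a maximum of exactly 1.
    """
    if tr <= 0:
        raise InvalidParameterError("tr must be > 0")
    params = params or HRFParams()
    t = np.arange(0.0, params.kernel_length, tr)
    peak = sps.gamma.pdf(
        t, a=params.peak_delay / params.peak_dispersion,
        scale=params.peak_dispersion,
    )
    under = sps.gamma.pdf(
        t, a=params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = peak - params.undershoot_ratio * under
    return h / h.max()


@dataclass
class DesignMatrix:
    """Timepoints x regressors matrix with per-regressor names.

    Trial regressors lead the matrix, followed by polynomial drift columns
    and the constant.
    """

    values: np.ndarray
    names: list[str]
    tr: float

    @property
    def n_trial_regressors(self) -> int:
        return sum(1 for n in self.names if n.startswith("trial_"))


def build_design_matrix(
    design: ExperimentDesign,
    hrf: HRFParams | None = None,
    drift_order: int = 1,
    *,
    kernel: np.ndarray | None = None,
    n_scans: int | None = None,
) -> DesignMatrix:
    """HRF-convolved single-trial design matrix.

    Each trial contributes one boxcar (onset, recall_duration) sampled at
    ``tr`` and convolved with the HRF kernel; ``drift_order`` Legendre drift
    columns and a constant follow, giving ``n_trials + drift_order + 1``
    columns in total.  A custom ``kernel`` (already sampled at ``tr``)
    overrides the canonical HRF.
    """
    if drift_order < 0:
        raise InvalidParameterError("drift_order must be >= 0")
    hrf = hrf or HRFParams()
    tr = design.tr
    if kernel is None:
        kernel = canonical_hrf(tr, hrf)
    kernel = np.asarray(kernel, dtype=np.float64)
    last_end = design.onsets[-1] + design.recall_duration + hrf.kernel_length
    if n_scans is None:
        n_scans = int(np.ceil(last_end / tr))

    times = np.arange(n_scans) * tr
    n_trials = design.n_trials
    cols = np.zeros((n_scans, n_trials + drift_order + 1))
    names = []
    for i, onset in enumerate(design.onsets):
        box = (
            (times >= onset) & (times < onset + design.recall_duration)
        ).astype(np.float64)
        cols[:, i] = np.convolve(box, kernel)[:n_scans]
        names.append(f"trial_{i:03d}")
    # Legendre drift terms over scaled time: stable, mutually near-orthogonal
    x = np.linspace(-1.0, 1.0, n_scans)
    for k in range(1, drift_order + 1):
        cols[:, n_trials + k - 1] = np.polynomial.legendre.Legendre.basis(k)(x)
        names.append(f"drift_{k}")
    cols[:, -1] = 1.0
    names.append("constant")
    return DesignMatrix(values=cols, names=names, tr=tr)


@dataclass
class SingleTrialGLMResults:
    """OLS estimates of the single-trial model.

    ``beta`` and ``t`` cover the trial regressors only (trials x voxels);
    ``sigma2`` is the per-voxel residual variance on ``dof`` degrees of
    freedom and ``xtx_inv_diag`` the per-trial-regressor leverage term.
    """

    beta: np.ndarray
    sigma2: np.ndarray
    dof: int
    xtx_inv_diag: np.ndarray
    t: np.ndarray
    names: list[str]
    beta_all: np.ndarray

    def summary(self) -> str:
        n_tr, n_vox = self.beta.shape
        lines = [
            "Single-trial GLM results",
            "========================",
            f"trial regressors: {n_tr}   voxels: {n_vox}",
            f"residual dof:     {self.dof}",
            f"median sigma2:    {np.median(self.sigma2):.6g}",
            f"|beta| range:     [{np.abs(self.beta).min():.4g}, "
            f"{np.abs(self.beta).max():.4g}]",
        ]
        return "\n".join(lines)


class SingleTrialGLM:
    """Statsmodels-style model object for the single-trial GLM.

    Parameters
    ----------
    series
        ``voxels x timepoints`` array or a :class:`SyntheticTimeseries`.
    design_matrix
        A :class:`DesignMatrix` whose row count matches the series length.
    """

    def __init__(self, series, design_matrix: DesignMatrix):
        if isinstance(series, SyntheticTimeseries):
            series = series.series
        self.series = np.asarray(series, dtype=np.float64)
        self.design_matrix = design_matrix
        X = design_matrix.values
        if self.series.ndim != 2:
            raise ShapeError("series must be 2-D (voxels x timepoints)")
        if self.series.shape[1] != X.shape[0]:
            raise ShapeError(
                f"series has {self.series.shape[1]} timepoints but the design "
                f"matrix has {X.shape[0]} rows"
            )

    def fit(self) -> SingleTrialGLMResults:
        X = self.design_matrix.values
        names = self.design_matrix.names
        n_scans, n_reg = X.shape
        # rank check with column identification via pivoted QR
        from scipy.linalg import qr as sqr

        _, r, piv = sqr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
        rank = int(np.sum(diag > tol))
        if rank < n_reg:
            bad = sorted(names[j] for j in piv[rank:])
            raise SingularDesignError(
                f"design matrix is rank deficient; collinear columns: {bad}",
                columns=bad,
            )
        Y = self.series.T  # timepoints x voxels
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        beta_all = xtx_inv @ (X.T @ Y)  # regressors x voxels
        resid = Y - X @ beta_all
        dof = n_scans - n_reg
        if dof < 1:
            raise InvalidParameterError("residual dof must be >= 1")
        sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
        n_trial = self.design_matrix.n_trial_regressors
        lev = np.diag(xtx_inv)[:n_trial]
        beta = beta_all[:n_trial]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / np.sqrt(sigma2[None, :] * lev[:, None])
        t[:, sigma2 <= 0] = np.nan
        return SingleTrialGLMResults(
            beta=beta,
            sigma2=sigma2,
            dof=dof,
            xtx_inv_diag=lev,
            t=t,
            names=names,
            beta_all=beta_all,
        )


def fit_glm(series, X: DesignMatrix) -> SingleTrialGLMResults:
    """Functional wrapper: fit the single-trial GLM and return its results."""
    return SingleTrialGLM(series, X).fit()


def trial_tmaps(
    result: SingleTrialGLMResults,
    labels,
    accurate,
    *,
    participant_id: int = 0,
    roi_name: str = "ALL",
    min_per_condition: int = 2,
) -> TrialPatternSet:
    """One t-value pattern per accurately recalled trial.

    Filters to accurate trials and packages the t statistics as a
    :class:`TrialPatternSet` for decoding.
    """
    n_trials = result.t.shape[0]
    accurate = np.asarray(accurate, dtype=bool)
    if len(labels) != n_trials or accurate.shape != (n_trials,):
        raise ShapeError("labels/accurate length must match trial count")
    # residual variance at rounding-error scale relative to the fit means the
    # model interpolated the data exactly; t values are then meaningless
    scale = float(np.mean(result.beta_all**2)) or 1.0
    if np.any(result.sigma2 <= 1e-20 * scale):
        raise DegenerateInputError(
            "zero residual variance at some voxels; t values undefined "
            "(add noise or remove constant voxels)"
        )
    kept_labels = [l for l, k in zip(labels, accurate) if k]
    mem = np.array([getattr(l, "memory_id", str(l)) for l in kept_labels])
    for m in "ABCD":
        if int(np.sum(mem == m)) < min_per_condition:
            raise InsufficientTrialsError(
                f"condition {m} has fewer than {min_per_condition} accurate trials"
            )
    return TrialPatternSet(
        participant_id=participant_id,
        roi_name=roi_name,
        patterns=result.t[accurate],
        labels=kept_labels,
        accurate=np.ones(int(accurate.sum()), dtype=bool),
    )
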