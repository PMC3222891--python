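"""Single-trial GLM: HRF sampling, design matrix, OLS fit, t conversion."""

import numpy as np
import pytest
from scipy import stats as sps

from patternsep.design import make_design
from patternsep.exceptions import (
    DegenerateInputError,
    InsufficientTrialsError,
    InvalidParameterError,
    ShapeError,
    SingularDesignError,
)
from patternsep.glm import (
    DesignMatrix,
    HRFParams,
    SingleTrialGLM,
    build_design_matrix,
    canonical_hrf,
    fit_glm,
    trial_tmaps,
)
from patternsep.simulate import NoiseModel, SignalSpec, generate_timeseries


class TestCanonicalHRF:
    def test_peak_normalized_to_one(self):
        for tr in (0.5, 1.0, 2.0, 3.0):
            h = canonical_hrf(tr)
            assert h.max() == pytest.approx(1.0)

    def test_peak_latency_in_physiological_range(self):
        """Dense sampling puts the response peak at 5-6 s."""
        h = canonical_hrf(0.1)
        t_peak = 0.1 * np.argmax(h)
        assert 5.0 <= t_peak <= 6.0

    def test_sample_count_scales_with_tr(self):
        n2 = canonical_hrf(2.0).size
        n1 = canonical_hrf(1.0).size
        assert abs(n1 - 2 * n2) <= 1

    def test_undershoot_present(self):
        h = canonical_hrf(0.5)
        assert h.min() < 0

    @pytest.mark.parametrize(
        "kwargs",
        [{"peak_delay": 0.0}, {"undershoot_ratio": -1.0},
         {"kernel_length": 10.0}],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            HRFParams(**kwargs)

    def test_tr_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            canonical_hrf(0.0)


class TestBuildDesignMatrix:
    def test_column_count(self, full_design):
        X = build_design_matrix(full_design, drift_order=1)
        assert X.values.shape[1] == 80 + 1 + 1
        assert X.names[-1] == "constant"
        assert X.n_trial_regressors == 80

    def test_identity_kernel_gives_boxcar(self, small_design):
        X = build_design_matrix(
            small_design, kernel=np.array([1.0]), drift_order=0
        )
        tr = small_design.tr
        times = np.arange(X.values.shape[0]) * tr
        for i, onset in enumerate(small_design.onsets[:5]):
            box = (
                (times >= onset)
                & (times < onset + small_design.recall_duration)
            ).astype(float)
            np.testing.assert_array_equal(X.values[:, i], box)

    def test_convolution_matches_shifted_sum_oracle(self):
        """Boxcar * kernel equals the brute-force shifted sum."""
        box = np.array([0.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        kern = np.array([0.5, 1.0, 0.25])
        # brute force: out[t] = sum_k box[t-k] * kern[k]
        expected = np.zeros(box.size)
        for t in range(box.size):
            for k in range(kern.size):
                if 0 <= t - k < box.size:
                    expected[t] += box[t - k] * kern[k]
        np.testing.assert_allclose(
            np.convolve(box, kern)[: box.size], expected
        )

    def test_negative_drift_order_rejected(self, small_design):
        with pytest.raises(InvalidParameterError):
            build_design_matrix(small_design, drift_order=-1)


class TestFitGLM:
    def test_noiseless_exact_interpolation(self, small_design, rng):
        X = build_design_matrix(small_design, drift_order=1)
        n_reg = X.values.shape[1]
        b = rng.normal(size=(n_reg, 3))
        series = (X.values @ b).T  # voxels x timepoints
        res = fit_glm(series, X)
        np.testing.assert_allclose(res.beta_all, b, rtol=1e-10, atol=1e-10)
        assert np.all(res.sigma2 < 1e-18)

    def test_hand_sized_normal_equations_oracle(self):
        """4 timepoints, 2 regressors: matches the explicit 2x2 solution."""
        X = DesignMatrix(
            values=np.array(
                [[1.0, 1.0], [2.0, 1.0], [3.0, 1.0], [4.0, 1.0]]
            ),
            names=["trial_000", "constant"],
            tr=1.0,
        )
        y = np.array([[1.1, 1.9, 3.2, 3.8]])
        xtx = X.values.T @ X.values
        xty = X.values.T @ y[0]
        expected = np.linalg.solve(xtx, xty)
        res = fit_glm(y, X)
        np.testing.assert_allclose(res.beta_all[:, 0], expected, rtol=1e-12)

    def test_matches_lstsq_oracle_on_random_systems(self, rng):
        for _ in range(10):
            n, p, v = 40, 7, 3
            X = DesignMatrix(
                values=np.column_stack(
                    [rng.normal(size=(n, p - 1)), np.ones(n)]
                ),
                names=[f"trial_{i:03d}" for i in range(p - 1)] + ["constant"],
                tr=1.0,
            )
            Y = rng.normal(size=(v, n))
            res = fit_glm(Y, X)
            expected, *_ = np.linalg.lstsq(X.values, Y.T, rcond=None)
            np.testing.assert_allclose(res.beta_all, expected, atol=1e-10)

    def test_duplicated_column_raises_named_singular_error(self, small_design):
        X = build_design_matrix(small_design, drift_order=0)
        vals = X.values.copy()
        vals[:, 1] = vals[:, 0]
        bad = DesignMatrix(values=vals, names=X.names, tr=X.tr)
        with pytest.raises(SingularDesignError) as err:
            fit_glm(np.zeros((2, vals.shape[0])), bad)
        assert len(err.value.columns) >= 1

    def test_timepoint_mismatch_raises_shape_error(self, small_design):
        X = build_design_matrix(small_design, drift_order=0)
        with pytest.raises(ShapeError):
            fit_glm(np.zeros((2, 10)), X)

    def test_t_and_beta_rank_correlation(self, small_design, rng):
        """Under homoscedastic noise, t is a per-regressor rescaling of beta;
        their across-trial rank correlation per voxel stays high."""
        spec = SignalSpec(n_voxels=20, p_inaccurate=0.0)
        ts = generate_timeseries(
            small_design, spec, noise=NoiseModel(sd=0.5), seed=8
        )[0]
        X = build_design_matrix(small_design, drift_order=1)
        res = SingleTrialGLM(ts, X).fit()
        rhos = [
            sps.spearmanr(res.beta[:, v], res.t[:, v]).statistic
            for v in range(res.beta.shape[1])
        ]
        assert np.mean(rhos) > 0.9

    def test_beta_recovery_improves_with_less_noise(self):
        """Mean absolute beta error shrinks monotonically with noise sd."""
        design = make_design(1, 6, seed=9)
        X = build_design_matrix(design, drift_order=1)
        errors = []
        for sd in (1.0, 0.5, 0.1):
            errs = []
            for seed in range(10):
                spec = SignalSpec(n_voxels=12, p_inaccurate=0.0)
                ts = generate_timeseries(
                    design, spec, noise=NoiseModel(sd=sd), seed=seed
                )[0]
                res = SingleTrialGLM(ts, X).fit()
                errs.append(np.abs(res.beta - ts.amplitudes).mean())
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_summary_mentions_dimensions(self, small_design):
        spec = SignalSpec(n_voxels=4, p_inaccurate=0.0)
        ts = generate_timeseries(small_design, spec, seed=1)[0]
        X = build_design_matrix(small_design, drift_order=1)
        s = SingleTrialGLM(ts, X).fit().summary()
        assert "trial regressors: 32" in s


@pytest.fixture(scope="module")
def fitted():
    design = make_design(1, 8, seed=10)
    spec = SignalSpec(n_voxels=6, p_inaccurate=0.0)
    ts = generate_timeseries(
        design, spec, noise=NoiseModel(sd=0.5), seed=11
    )[0]
    X = build_design_matrix(design, drift_order=1)
    return design, SingleTrialGLM(ts, X).fit()


class TestTrialTmaps:

    def test_all_accurate_keeps_every_trial(self, fitted):
        design, res = fitted
        labels = design.labels(0)
        pset = trial_tmaps(res, labels, np.ones(len(labels), dtype=bool))
        assert pset.n_trials == len(labels)

    def test_inaccurate_trials_filtered(self, fitted):
        design, res = fitted
        labels = design.labels(0)
        accurate = np.ones(len(labels), dtype=bool)
        accurate[[0, 5, 9]] = False
        pset = trial_tmaps(res, labels, accurate)
        assert pset.n_trials == len(labels) - 3

    def test_noiseless_fit_raises_degenerate_error(self, small_design):
        spec = SignalSpec(n_voxels=4, p_inaccurate=0.0)
        ts = generate_timeseries(
            small_design, spec, noise=NoiseModel(sd=0.0), seed=1
        )[0]
        X = build_design_matrix(small_design, drift_order=1)
        res = SingleTrialGLM(ts, X).fit()
        labels = small_design.labels(0)
        with pytest.raises(DegenerateInputError):
            trial_tmaps(res, labels, np.ones(len(labels), dtype=bool))

    def test_too_few_accurate_trials_raises(self, fitted):
        design, res = fitted
        labels = design.labels(0)
        accurate = np.array([l.memory_id != "A" for l in labels])
        accurate[np.argmax([l.memory_id == "A" for l in labels])] = True
        with pytest.raises(InsufficientTrialsError):
            trial_tmaps(res, labels, accurate)


class TestRoundTrip:
    def test_noiseless_timeseries_recovers_amplitudes(self, small_design):
        """End-to-end: GLM betas on noise-free series equal the generating
        amplitudes to high relative precision."""
        spec = SignalSpec(n_voxels=8, p_inaccurate=0.0)
        ts = generate_timeseries(
            small_design, spec, noise=NoiseModel(sd=0.0), seed=12
        )[0]
        X = build_design_matrix(small_design, drift_order=1)
        res = SingleTrialGLM(ts, X).fit()
        rel = np.linalg.norm(res.beta - ts.amplitudes) / np.linalg.norm(
            ts.amplitudes
        )
        assert rel < 1e-8
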