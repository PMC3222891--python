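"""Misclassification decomposition and group-level inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patternsep.decode import DecodingResult
from patternsep.design import MEMORY_IDS, relation
from patternsep.exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    ZeroVarianceError,
)
from patternsep.inference import (
    MisclassProfile,
    compare_misclass,
    misclass_profile,
    permutation_test,
    t_tail_p,
    t_vs_chance,
)
from patternsep.simulate import SignalSpec, generate_patterns


def _result_from_confusion(confusion):
    confusion = np.asarray(confusion, dtype=np.int64)
    n = int(confusion.sum())
    true, pred = [], []
    for i, a in enumerate(MEMORY_IDS):
        for j, b in enumerate(MEMORY_IDS):
            true += [a] * confusion[i, j]
            pred += [b] * confusion[i, j]
    return DecodingResult(
        participant_id=0, roi_name="HC",
        true=np.array(true), predicted=np.array(pred),
        fold_index=np.arange(n),
        accuracy=float(np.trace(confusion)) / n,
        confusion=confusion,
    )


class TestMisclassProfile:
    def test_uniform_errors_give_equal_thirds(self):
        confusion = np.full((4, 4), 2, dtype=int)
        prof = misclass_profile(_result_from_confusion(confusion))
        assert prof.total_errors == 24
        for k in ("spatial", "content", "orthogonal"):
            assert prof.proportions[k] == pytest.approx(1 / 3)

    def test_context_partner_errors_are_all_spatial(self):
        confusion = np.zeros((4, 4), dtype=int)
        # A->C, C->A, B->D, D->B: every error shares the spatial context
        confusion[0, 2] = confusion[2, 0] = 3
        confusion[1, 3] = confusion[3, 1] = 2
        prof = misclass_profile(_result_from_confusion(confusion))
        assert prof.proportions["spatial"] == 1.0

    def test_explicit_confusion_matches_cellwise_relation_oracle(self):
        confusion = np.array(
            [[18, 1, 1, 0], [0, 19, 0, 1], [2, 0, 18, 0], [0, 0, 1, 19]]
        )
        # independent oracle: accumulate off-diagonal cells by relation()
        expected = {"spatial": 0, "content": 0, "orthogonal": 0}
        for i, a in enumerate(MEMORY_IDS):
            for j, b in enumerate(MEMORY_IDS):
                if i != j:
                    expected[relation(a, b)] += int(confusion[i, j])
        prof = misclass_profile(_result_from_confusion(confusion))
        assert prof.counts == expected
        assert prof.total_errors == sum(expected.values())

    def test_invariant_to_diagonal(self):
        base = np.array(
            [[0, 1, 2, 0], [1, 0, 0, 3], [0, 2, 0, 1], [1, 0, 2, 0]]
        )
        inflated = base + np.diag([10, 20, 30, 40])
        a = misclass_profile(_result_from_confusion(base))
        b = misclass_profile(_result_from_confusion(inflated))
        assert a.counts == b.counts

    def test_zero_errors_flagged_undefined(self):
        prof = misclass_profile(_result_from_confusion(np.diag([5, 5, 5, 5])))
        assert prof.total_errors == 0
        assert prof.proportions is None
        assert not prof.defined


def _profile(spatial, content, orthogonal):
    total = spatial + content + orthogonal
    counts = {"spatial": spatial, "content": content, "orthogonal": orthogonal}
    props = {k: v / total for k, v in counts.items()} if total else None
    return MisclassProfile(counts=counts, proportions=props,
                           total_errors=total)


class TestCompareMisclass:
    def test_identical_proportions_give_null_t(self):
        profiles = [_profile(2, 2, 2) for _ in range(5)]
        res = compare_misclass(profiles, "spatial_vs_content")
        assert res.t == 0.0
        assert res.p == pytest.approx(0.5)

    def test_constant_nonzero_differences_raise_zero_variance(self):
        profiles = [_profile(3, 1, 2) for _ in range(4)]
        with pytest.raises(ZeroVarianceError):
            compare_misclass(profiles, "spatial_vs_content")

    def test_matches_hand_formula(self):
        # spatial - content differences: 0.2, -0.1, 0.05, 0.15, 0.0
        diffs = np.array([0.2, -0.1, 0.05, 0.15, 0.0])
        profiles = []
        for d in diffs:
            s = (1 + d) / 3
            c = (1 - d) / 3  # spatial - content == d, proportions sum to 1
            profiles.append(
                MisclassProfile(
                    counts={"spatial": 0, "content": 0, "orthogonal": 0},
                    proportions={"spatial": s, "content": c,
                                 "orthogonal": 1 / 3},
                    total_errors=1,
                )
            )
        res = compare_misclass(profiles, "spatial_vs_content")
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert res.t == pytest.approx(expected_t)
        assert res.df == 4

    def test_zero_error_participants_excluded_with_warning(self):
        profiles = [_profile(0, 0, 0), _profile(3, 1, 1), _profile(1, 2, 1)]
        with pytest.warns(UserWarning):
            res = compare_misclass(profiles, "spatial_vs_orthogonal")
        assert res.n_used == 2

    def test_too_few_usable_participants_rejected(self):
        with pytest.raises(InsufficientDataError), pytest.warns(UserWarning):
            compare_misclass([_profile(0, 0, 0), _profile(1, 1, 1)],
                             "spatial_vs_content")

    def test_unknown_contrast_rejected(self):
        with pytest.raises(InvalidParameterError):
            compare_misclass([_profile(1, 1, 1)] * 3, "spatial_vs_everything")


class TestTVsChance:
    def test_all_at_chance_gives_null_t(self):
        res = t_vs_chance([0.25, 0.25, 0.25, 0.25], 0.25)
        assert res.t == 0.0
        assert res.p == pytest.approx(0.5)

    def test_mean_at_chance_gives_zero_t(self):
        res = t_vs_chance([0.30, 0.20, 0.30, 0.20], 0.25)
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula(self):
        acc = np.array([0.35, 0.30, 0.25, 0.40, 0.30])
        res = t_vs_chance(acc, 0.25)
        d = acc - 0.25
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.t == pytest.approx(expected)
        assert res.df == 4
        assert res.sem == pytest.approx(acc.std(ddof=1) / np.sqrt(5))

    def test_constant_off_chance_raises_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            t_vs_chance([0.4, 0.4, 0.4], 0.25)

    def test_single_participant_rejected(self):
        with pytest.raises(InsufficientDataError):
            t_vs_chance([0.4], 0.25)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(delta=st.floats(-0.2, 0.2, allow_nan=False))
    def test_translation_covariance(self, delta):
        acc = np.array([0.31, 0.27, 0.22, 0.35])
        base = t_vs_chance(acc, 0.25)
        shifted = t_vs_chance(acc + delta, 0.25 + delta)
        assert shifted.t == pytest.approx(base.t, abs=1e-9)


class TestTailProbability:
    @pytest.mark.parametrize(
        "t,expected",
        [(1.90, 0.04), (2.39, 0.02), (1.55, 0.07),
         (-1.09, 0.85), (-1.462, 0.92), (-2.754, 0.99)],
    )
    def test_upper_tail_convention_df14(self, t, expected):
        assert round(t_tail_p(t, 14), 2) == expected

    def test_zero_statistic_is_half(self):
        for df in (1, 5, 14, 100):
            assert t_tail_p(0.0, df) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        t=st.floats(-5, 5, allow_nan=False),
        df=st.integers(min_value=1, max_value=60),
    )
    def test_symmetry_and_monotonicity(self, t, df):
        assert t_tail_p(t, df) + t_tail_p(-t, df) == pytest.approx(1.0)
        assert t_tail_p(t + 0.1, df) < t_tail_p(t, df)

    def test_invalid_df_rejected(self):
        with pytest.raises(InvalidParameterError):
            t_tail_p(1.0, 0)


class TestPermutationTest:
    def test_strong_signal_reaches_floor_p(self, separable_patterns):
        res = permutation_test(
            separable_patterns, "fourway", n_perm=100, seed=1
        )
        assert res.perm_p == pytest.approx(1 / 101)
        assert res.mean == 1.0

    def test_perm_p_floor_and_monotonicity_of_formula(self):
        null = np.linspace(0.1, 0.9, 999)
        n_perm = null.size

        def perm_p(obs):
            return (1 + np.sum(null >= obs - 1e-12)) / (1 + n_perm)

        # observed above every null value: the add-one floor
        assert perm_p(1.0) == 1 / (n_perm + 1)
        # observed at the null median: close to one half
        assert perm_p(np.median(null)) == pytest.approx(0.5, abs=0.05)
        # monotone non-increasing in the observed statistic
        ps = [perm_p(o) for o in np.linspace(0, 1, 50)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_deterministic_given_seed(self, bound_only_patterns):
        a = permutation_test(bound_only_patterns[:2], "fourway",
                             n_perm=100, seed=5)
        b = permutation_test(bound_only_patterns[:2], "fourway",
                             n_perm=100, seed=5)
        assert a.perm_p == b.perm_p
        np.testing.assert_array_equal(a.per_participant, b.per_participant)

    def test_transfer_analysis_supported(self, small_design):
        spec = SignalSpec(n_voxels=40, amp_bound=0.0, amp_context=4.0,
                          amp_event=0.0, noise_sd=0.5, p_inaccurate=0.0)
        psets = generate_patterns(small_design, spec, seed=6)
        res = permutation_test(psets, "context_transfer", n_perm=100, seed=2)
        assert res.chance == 0.5
        assert res.perm_p == pytest.approx(1 / 101)

    def test_invalid_analysis_rejected(self, bound_only_patterns):
        with pytest.raises(InvalidParameterError):
            permutation_test(bound_only_patterns, "fiveway", n_perm=100)

    def test_too_few_permutations_rejected(self, bound_only_patterns):
        with pytest.raises(InvalidParameterError):
            permutation_test(bound_only_patterns, "fourway", n_perm=10)
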