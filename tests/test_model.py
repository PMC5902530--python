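"""Unit and property tests for the capacity-model evaluation layer."""

import functools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings

from causalform import (
    AssignmentError,
    CapacityModel,
    Cause,
    CauseAssignment,
    EffectRange,
    ModelError,
    blocking_passthrough,
    expected_effect,
    linear_expected_effect,
    linearize_cause,
    noisy_addition,
    noisy_max,
    noisy_or,
    noisy_or_and,
    pairwise_combine,
    parameter_count,
)
from conftest import binary_models_with_assignments, finite_models_with_assignments

INF = math.inf


class TestNoisyOr:
    @pytest.mark.parametrize(
        "strengths, indicators, expected",
        [
            ([0.2, 0.5, 0.9], [0, 0, 0], 0.0),  # all causes absent
            ([0.7], [1], 0.7),  # single cause: P(E) = w
            ([0.0], [1], 0.0),
            ([1.0], [1], 1.0),
            # two half-strength causes: 1 - 0.5*0.5 = 0.75, i.e. P(at least
            # one of two independent activations), enumerated by hand
            ([0.5, 0.5], [1, 1], 0.75),
            ([0.2, 0.5, 0.9], [1, 1, 1], 1 - 0.8 * 0.5 * 0.1),
        ],
    )
    def test_values(self, strengths, indicators, expected):
        assert noisy_or(strengths, indicators) == pytest.approx(expected, abs=1e-15)

    def test_rejects_length_mismatch_and_bad_strength(self):
        with pytest.raises(ValueError, match="length mismatch"):
            noisy_or([0.5], [1, 0])
        with pytest.raises(ValueError, match="outside"):
            noisy_or([1.5], [1])
        with pytest.raises(ValueError, match="binary"):
            noisy_or([0.5], [0.3])

    def test_matches_exhaustive_enumeration(self):
        # brute-force oracle: enumerate all activation patterns of each
        # present cause firing independently with probability w
        rng = random.Random(0)
        for _ in range(20):
            k = rng.randint(1, 5)
            w = [rng.random() for _ in range(k)]
            d = [rng.randint(0, 1) for _ in range(k)]
            p_effect = 0.0
            for pattern in range(2**k):
                bits = [(pattern >> i) & 1 for i in range(k)]
                p = 1.0
                for wi, di, bi in zip(w, d, bits):
                    q = wi * di
                    p *= q if bi else (1 - q)
                if any(bits):
                    p_effect += p
            assert noisy_or(w, d) == pytest.approx(p_effect, abs=1e-12)


class TestNoisyOrAnd:
    def test_reduces_to_noisy_or_without_preventers(self):
        assert noisy_or_and([0.5, 0.5], [1, 1], [], []) == 0.75

    def test_sure_preventer_annihilates(self):
        assert noisy_or_and([0.8], [1], [1.0], [1]) == 0.0

    def test_baseline_probability_is_one_when_generators_absent(self):
        # with every generative cause absent the effect stays at baseline
        # with probability exactly 1, whatever the preventers do
        for prev_inds in ([0, 0], [0, 1], [1, 0], [1, 1]):
            p = noisy_or_and([0.2, 0.5, 0.9], [0, 0, 0], [0.3, 0.7], prev_inds)
            assert p == 0.0


class TestPairwiseCombine:
    @pytest.mark.parametrize(
        "x, y, U, expected",
        [
            (0.0, 0.6, 1.0, 0.6),  # identity element: lone cause passes through
            (1.0, 0.6, 1.0, 1.0),  # saturation at the bound
            (0.5, 0.5, 1.0, 0.75),  # matches noisy-OR on two binary causes
            (1.0, 1.0, 2.0, 1.5),
        ],
    )
    def test_values(self, x, y, U, expected):
        assert pairwise_combine(x, y, U) == pytest.approx(expected, abs=1e-15)

    def test_symmetric_and_range_checked(self):
        assert pairwise_combine(0.3, 0.8, 1.0) == pairwise_combine(0.8, 0.3, 1.0)
        with pytest.raises(ValueError, match="outside"):
            pairwise_combine(1.2, 0.5, 1.0)
        with pytest.raises(ValueError, match="outside"):
            pairwise_combine(0.5, -0.1, 1.0)


class TestComparisonFunctions:
    def test_max_and_addition(self):
        assert noisy_max([0.3, 0.8], [1, 1]) == 0.8
        assert noisy_addition([0.3, 0.8], [1, 1]) == pytest.approx(1.1)
        assert noisy_max([0.3, 0.8], [0, 0]) == 0.0
        assert noisy_addition([0.3, 0.8], [0, 0]) == 0.0
        assert noisy_max([0.7], [1]) == noisy_addition([0.7], [1]) == 0.7

    def test_blocking_passthrough(self):
        assert blocking_passthrough([], []) == 1.0
        assert blocking_passthrough([1.0], [1.0]) == 0.0
        assert blocking_passthrough([0.5, 0.5], [1, 1]) == 0.25
        with pytest.raises(ValueError, match="outside"):
            blocking_passthrough([1.5], [1.0])


class TestModelValidation:
    def test_effect_range_needs_a_positive_bound(self):
        with pytest.raises(ModelError, match="at least one"):
            EffectRange(0.0, 0.0)
        with pytest.raises(ModelError, match="magnitude"):
            EffectRange(-1.0, 1.0)

    def test_unknown_role_lists_valid_ones(self):
        with pytest.raises(ModelError, match="generator, reducer, blocker"):
            Cause("x", "preventer", 0.5)

    def test_strength_bound_constraints(self):
        with pytest.raises(ModelError, match="exceeds upper bound"):
            CapacityModel(EffectRange(0, 1), [Cause("g", "generator", 0.6, 2.0)])
        with pytest.raises(ModelError, match="requires lower bound"):
            CapacityModel(EffectRange(0, 1), [Cause("r", "reducer", 0.5)])
        with pytest.raises(ModelError, match="exceeds 1"):
            CapacityModel(EffectRange(0, 1), [Cause("b", "blocker", 0.6, 2.0)])

    def test_assignment_mismatch_and_range(self, two_generator_binary):
        with pytest.raises(AssignmentError, match="missing"):
            expected_effect(two_generator_binary, {"a": 1.0})
        with pytest.raises(AssignmentError, match="unknown"):
            expected_effect(two_generator_binary, {"a": 1.0, "b": 0.0, "z": 1.0})
        with pytest.raises(AssignmentError, match="exceeds max_value"):
            expected_effect(two_generator_binary, {"a": 2.0, "b": 0.0})
        with pytest.raises(AssignmentError, match="below"):
            expected_effect(two_generator_binary, {"a": -0.5, "b": 0.0})


class TestExpectedEffect:
    def test_no_uncaused_effects_is_exact(self, mixed_model):
        zeros = {c.label: 0.0 for c in mixed_model.causes}
        assert expected_effect(mixed_model, zeros) == 0.0

    def test_single_generator_gives_strength_times_value(self):
        m = CapacityModel(EffectRange(0, 5), [Cause("g", "generator", 1.3, 2.0)])
        assert expected_effect(m, {"g": 1.7}) == pytest.approx(1.3 * 1.7, abs=1e-12)

    def test_two_binary_generators(self, two_generator_binary):
        assert expected_effect(two_generator_binary, {"a": 1, "b": 1}) == 0.75

    def test_sure_blocker_annihilates(self, mixed_model):
        m = CapacityModel(
            mixed_model.effect_range,
            list(mixed_model.causes) + [Cause("kill", "blocker", 1.0, 1.0)],
        )
        assign = {c.label: c.max_value for c in m.causes}
        assert expected_effect(m, assign) == 0.0

    def test_reducer_pulls_below_baseline(self):
        m = CapacityModel(EffectRange(2, 1), [Cause("r", "reducer", 1.0, 1.5)])
        assert expected_effect(m, {"r": 1.0}) == pytest.approx(-1.0, abs=1e-12)

    def test_infinite_bounds_rejected(self):
        m = CapacityModel(
            EffectRange(INF, INF), [Cause("g", "generator", 1.0, max_value=INF)]
        )
        with pytest.raises(ModelError, match="linear_expected_effect"):
            expected_effect(m, {"g": 1.0})

    def test_accepts_cause_assignment_object(self, two_generator_binary):
        a = CauseAssignment({"a": 1.0, "b": 0.0})
        assert expected_effect(two_generator_binary, a) == 0.5

    @settings(max_examples=150, derandomize=True)
    @given(finite_models_with_assignments())
    def test_bounded_in_effect_range(self, model_and_values):
        model, values = model_and_values
        e = expected_effect(model, values)
        er = model.effect_range
        assert -er.lower - 1e-12 <= e <= er.upper + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(finite_models_with_assignments())
    def test_permutation_invariance_is_exact(self, model_and_values):
        model, values = model_and_values
        e = expected_effect(model, values)
        causes = list(model.causes)
        rng = random.Random(str(values))
        rng.shuffle(causes)
        shuffled = CapacityModel(model.effect_range, causes)
        assert expected_effect(shuffled, values) == e

    @settings(max_examples=100, derandomize=True)
    @given(finite_models_with_assignments())
    def test_monotone_in_generator_and_reducer_values(self, model_and_values):
        model, values = model_and_values
        e = expected_effect(model, values)
        for c in model.causes:
            if values[c.label] >= c.max_value:
                continue
            bumped = dict(values)
            bumped[c.label] = min(c.max_value, values[c.label] + 0.1 * c.max_value)
            eb = expected_effect(model, bumped)
            if c.role == "generator":
                assert eb >= e - 1e-12
            elif c.role == "reducer":
                assert eb <= e + 1e-12
            else:  # blocker moves the result weakly toward baseline
                assert abs(eb) <= abs(e) + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(binary_models_with_assignments())
    def test_binary_model_equals_noisy_or_and_exactly(self, model_and_values):
        model, values = model_and_values
        e3 = expected_effect(model, values)
        e2 = noisy_or_and(
            [c.strength for c in model.generators],
            [values[c.label] for c in model.generators],
            [c.strength for c in model.blockers],
            [values[c.label] for c in model.blockers],
        )
        assert e3 == e2

    def test_generator_accumulation_matches_pairwise_combine_any_order(self):
        # generators-only models accumulate exactly by repeated pairwise
        # combination of the w*g contributions, in any association order
        rng = random.Random(5)
        for _ in range(30):
            U = rng.uniform(0.5, 5.0)
            k = rng.randint(1, 6)
            causes, values = [], {}
            for i in range(k):
                M = rng.uniform(0.25, 2.0)
                causes.append(Cause(f"c{i}", "generator", rng.uniform(0, U / M), M))
                values[f"c{i}"] = rng.uniform(0, M)
            m = CapacityModel(EffectRange(0.0, U), causes)
            contribs = [c.strength * values[c.label] for c in causes]
            rng.shuffle(contribs)
            paired = functools.reduce(lambda x, y: pairwise_combine(x, y, U), contribs)
            assert expected_effect(m, values) == pytest.approx(paired, abs=1e-9)


class TestLinearExpectedEffect:
    def test_requires_infinite_bounds(self, two_generator_binary):
        with pytest.raises(ModelError, match="infinite"):
            linear_expected_effect(two_generator_binary, {"a": 1, "b": 1})

    def test_linear_form(self):
        m = CapacityModel(
            EffectRange(INF, INF),
            [
                Cause("g", "generator", 2.0, max_value=INF),
                Cause("r", "reducer", 0.5, max_value=INF),
            ],
        )
        assert linear_expected_effect(m, {"g": 0.0, "r": 0.0}) == 0.0
        assert linear_expected_effect(m, {"g": 1.0, "r": 1.0}) == 1.5
        # signed cause values are allowed in the linear limit
        assert linear_expected_effect(m, {"g": -1.0, "r": 0.0}) == -2.0

    def test_blocker_scales_bracket(self):
        m = CapacityModel(
            EffectRange(INF, INF),
            [
                Cause("g", "generator", 2.0, max_value=INF),
                Cause("r", "reducer", 0.5, max_value=INF),
                Cause("b", "blocker", 0.5, 1.0),
            ],
        )
        assert linear_expected_effect(m, {"g": 1.0, "r": 1.0, "b": 1.0}) == 0.75


class TestLinearizeCause:
    def test_identity_is_noop(self):
        vals = [0.0, 0.5, 2.0]
        assert linearize_cause(vals, lambda v: v) == vals

    def test_sqrt_undoes_square(self):
        raw = [0.0, 1.0, 4.0, 9.0]
        assert linearize_cause(raw, math.sqrt) == pytest.approx([0, 1, 2, 3])

    def test_round_trip_recovers_inputs(self):
        rng = random.Random(3)
        vals = [rng.uniform(0, 5) for _ in range(20)]
        fwd = linearize_cause(vals, lambda v: v**3)
        back = linearize_cause(fwd, lambda v: math.copysign(abs(v) ** (1 / 3), v))
        assert back == pytest.approx(vals, abs=1e-9)

    def test_rejects_bad_transforms(self):
        with pytest.raises(ValueError, match="transform\\(0\\)"):
            linearize_cause([1.0], lambda v: v + 0.5)
        with pytest.raises(ValueError, match="monotone"):
            linearize_cause([0.5, 1.0, 2.0], lambda v: v * (2 - v))


class TestParameterCount:
    @pytest.mark.parametrize(
        "n, representation, expected",
        [(3, "capacity", 3), (3, "unrestricted", 8), (0, "unrestricted", 1), (0, "capacity", 0)],
    )
    def test_counts(self, n, representation, expected):
        m = CapacityModel(
            EffectRange(0, 1),
            [Cause(f"c{i}", "generator", 0.5) for i in range(n)],
        )
        assert parameter_count(m, representation) == expected

    def test_unrestricted_requires_binary(self):
        m = CapacityModel(EffectRange(0, 5), [Cause("g", "generator", 1.0, 2.0)])
        with pytest.raises(ModelError, match="binary"):
            parameter_count(m, "unrestricted")
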