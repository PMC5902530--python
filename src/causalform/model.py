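"""Causal capacity models over bounded effect ranges.

A capacity model describes a single effect variable whose value lives in an
interval ``[-L, U]`` around a baseline of 0, together with a set of causes,
each acting as an independent causal capacity.  Three roles are supported:

* **generator** — pushes the expected effect up from baseline toward ``U``;
* **reducer** — pushes the expected effect down toward ``-L``;
* **blocker** — a probabilistic switch that, when active, prevents every
  other capacity from influencing the effect.

The expected effect under a joint cause assignment is

.. math::

    E(E) = \\prod_k (1 - w_k b_k)\\,
           \\Bigl[ U\\bigl(1 - \\prod_i \\tfrac{U - w_i g_i}{U}\\bigr)
                 - L\\bigl(1 - \\prod_j \\tfrac{L - w_j r_j}{L}\\bigr) \\Bigr],

which normalizes each group of contributions to ``[0, 1]``, combines them by
noisy-OR, and maps back to the effect scale.  Causal strength ``w`` is read
as the expected change in the effect per unit increase of the cause from its
inactive state with everything else inactive; for blockers it is the per-unit
increase in complete-blocking probability.  With ``L = 0``, ``U = 1`` and
binary causes this reduces exactly to the classic noisy-OR/AND model, and as
both bounds grow it converges to the linear (additive) model — see
:mod:`causalform.special_cases`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelError",
    "AssignmentError",
    "EffectRange",
    "Cause",
    "CapacityModel",
    "CauseAssignment",
    "noisy_or",
    "noisy_or_and",
    "pairwise_combine",
    "blocking_passthrough",
    "noisy_max",
    "noisy_addition",
    "expected_effect",
    "linear_expected_effect",
    "linearize_cause",
    "parameter_count",
]

ROLES = ("generator", "reducer", "blocker")

#: slack for strength-times-value bound checks; products of validated factors
#: can sit a few ulp past the analytic bound.
_BOUND_SLACK = 1e-12


class ModelError(ValueError):
    """A model definition violates a structural invariant."""


class AssignmentError(ValueError):
    """A cause-value assignment is incompatible with its model."""


def _sorted_prod(factors: Iterable[float]) -> float:
    """Product of factors in ascending order.

    Floating-point multiplication is commutative but not associative, so a
    fixed evaluation order makes every product here invariant under
    permutation of the cause list (bit-for-bit, not just to tolerance).
    """
    arr = np.sort(np.asarray(list(factors), dtype=float))
    if arr.size == 0:
        return 1.0
    out = 1.0
    for v in arr:
        out *= float(v)
    return out


@dataclass(frozen=True)
class EffectRange:
    """The effect's value interval ``[-L, U]`` with baseline 0.

    ``lower`` and ``upper`` are the *magnitudes* L and U (both nonnegative,
    possibly ``math.inf``).  At least one must be strictly positive,
    otherwise the effect could never leave baseline.
    """

    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("lower", self.lower), ("upper", self.upper)):
            if not (isinstance(v, (int, float)) and not math.isnan(v)):
                raise ModelError(f"effect_range.{name} must be a number, got {v!r}")
            if v < 0:
                raise ModelError(
                    f"effect_range.{name} is a magnitude and must be >= 0, got {v}"
                )
        if self.lower == 0 and self.upper == 0:
            raise ModelError(
                "effect_range: at least one of lower, upper must be > 0 "
                "(a [0, 0] range pins the effect at baseline forever)"
            )

    @property
    def finite(self) -> bool:
        return math.isfinite(self.lower) and math.isfinite(self.upper)

    @property
    def baseline(self) -> float:
        return 0.0


@dataclass(frozen=True)
class Cause:
    """One causal capacity: a role, a strength ``w`` and a value range ``[0, M]``.

    The inactive value is always 0.  ``strength`` is on the expected-change
    scale (for blockers: blocking probability per unit of the blocker).
    """

    label: str
    role: str
    strength: float
    max_value: float = 1.0

    def __post_init__(self) -> None:
        if not self.label:
            raise ModelError("cause label must be a non-empty string")
        if self.role not in ROLES:
            raise ModelError(
                f"cause {self.label!r}: unknown role {self.role!r}; "
                f"valid roles are {', '.join(ROLES)}"
            )
        if not (self.strength >= 0):
            raise ModelError(
                f"cause {self.label!r}: strength must be >= 0, got {self.strength}"
            )
        if not (self.max_value > 0):
            raise ModelError(
                f"cause {self.label!r}: max_value must be > 0, got {self.max_value}"
            )

    @property
    def max_contribution(self) -> float:
        """w * M, the largest possible contribution of this cause."""
        if math.isinf(self.max_value):
            return math.inf if self.strength > 0 else 0.0
        return self.strength * self.max_value


@dataclass(frozen=True)
class CapacityModel:
    """An effect range plus an ordered list of causes."""

    effect_range: EffectRange
    causes: tuple[Cause, ...]

    def __init__(self, effect_range: EffectRange, causes: Sequence[Cause]):
        object.__setattr__(self, "effect_range", effect_range)
        object.__setattr__(self, "causes", tuple(causes))
        self._validate()

    def _validate(self) -> None:
        labels = [c.label for c in self.causes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ModelError(f"duplicate cause labels: {dupes}")
        L, U = self.effect_range.lower, self.effect_range.upper
        for c in self.causes:
            if c.role == "generator":
                if U == 0:
                    raise ModelError(
                        f"generator {c.label!r} requires upper bound U > 0"
                    )
                if math.isfinite(U) and c.max_contribution > U + _BOUND_SLACK:
                    raise ModelError(
                        f"generator {c.label!r}: strength*max_value = "
                        f"{c.max_contribution} exceeds upper bound U = {U}"
                    )
            elif c.role == "reducer":
                if L == 0:
                    raise ModelError(
                        f"reducer {c.label!r} requires lower bound L > 0 "
                        "(the normalizing division by L is undefined at L = 0)"
                    )
                if math.isfinite(L) and c.max_contribution > L + _BOUND_SLACK:
                    raise ModelError(
                        f"reducer {c.label!r}: strength*max_value = "
                        f"{c.max_contribution} exceeds lower bound L = {L}"
                    )
            else:  # blocker
                if c.max_contribution > 1 + _BOUND_SLACK:
                    raise ModelError(
                        f"blocker {c.label!r}: strength*max_value = "
                        f"{c.max_contribution} exceeds 1 (it is a probability)"
                    )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.causes)

    @property
    def generators(self) -> tuple[Cause, ...]:
        return tuple(c for c in self.causes if c.role == "generator")

    @property
    def reducers(self) -> tuple[Cause, ...]:
        return tuple(c for c in self.causes if c.role == "reducer")

    @property
    def blockers(self) -> tuple[Cause, ...]:
        return tuple(c for c in self.causes if c.role == "blocker")

    @property
    def all_binary(self) -> bool:
        return all(c.max_value == 1 for c in self.causes)

    def cause(self, label: str) -> Cause:
        for c in self.causes:
            if c.label == label:
                return c
        raise KeyError(label)

    def with_bounds(self, lower: float, upper: float) -> "CapacityModel":
        """Same causes, different effect range (used by limit verifications)."""
        return CapacityModel(EffectRange(lower=lower, upper=upper), self.causes)

    def with_strengths(self, strengths: Mapping[str, float]) -> "CapacityModel":
        new = tuple(
            Cause(c.label, c.role, float(strengths.get(c.label, c.strength)), c.max_value)
            for c in self.causes
        )
        return CapacityModel(self.effect_range, new)


@dataclass(frozen=True)
class CauseAssignment:
    """Values for every cause of a model, keyed by label."""

    values: Mapping[str, float]

    def __getitem__(self, label: str) -> float:
        return self.values[label]


def _as_values(assignment) -> Mapping[str, float]:
    if isinstance(assignment, CauseAssignment):
        return assignment.values
    if isinstance(assignment, Mapping):
        return assignment
    raise AssignmentError(
        f"assignment must be a mapping or CauseAssignment, got {type(assignment).__name__}"
    )


def _validated_values(
    model: CapacityModel, assignment, allow_signed: bool = False
) -> dict[str, float]:
    vals = _as_values(assignment)
    missing = set(model.labels) - set(vals)
    extra = set(vals) - set(model.labels)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing values for {sorted(missing)}")
        if extra:
            parts.append(f"unknown labels {sorted(extra)}")
        raise AssignmentError("; ".join(parts))
    out: dict[str, float] = {}
    for c in model.causes:
        v = float(vals[c.label])
        if math.isnan(v):
            raise AssignmentError(f"cause {c.label!r}: value is NaN")
        signed_ok = allow_signed and c.role in ("generator", "reducer")
        if v < 0 and not signed_ok:
            raise AssignmentError(
                f"cause {c.label!r}: value {v} below the inactive value 0"
            )
        if abs(v) > c.max_value:
            raise AssignmentError(
                f"cause {c.label!r}: value {v} exceeds max_value {c.max_value}"
            )
        out[c.label] = v
    return out


# ---------------------------------------------------------------------------
# Binary-variable kernels: noisy-OR, noisy-OR/AND, comparison functions
# ---------------------------------------------------------------------------

def _check_pairs(strengths, indicators, unit_strengths=True):
    s = list(strengths)
    d = list(indicators)
    if len(s) != len(d):
        raise ValueError(
            f"length mismatch: {len(s)} strengths vs {len(d)} indicators"
        )
    for w in s:
        if unit_strengths and not (0.0 <= w <= 1.0):
            raise ValueError(f"strength {w} outside [0, 1]")
        if not unit_strengths and not (w >= 0):
            raise ValueError(f"strength {w} must be >= 0")
    for x in d:
        if x not in (0, 1, 0.0, 1.0, False, True):
            raise ValueError(f"indicator {x!r} is not binary")
    return s, [float(x) for x in d]


def noisy_or(strengths: Sequence[float], indicators: Sequence[float]) -> float:
    """P(E) = 1 - prod(1 - w_i * delta_i): at least one present cause fires."""
    s, d = _check_pairs(strengths, indicators)
    return 1.0 - _sorted_prod(1.0 - w * x for w, x in zip(s, d))


def blocking_passthrough(
    blocker_strengths: Sequence[float], blocker_values: Sequence[float]
) -> float:
    """prod(1 - w_k * b_k): the probability that no blocker fires."""
    s = list(blocker_strengths)
    b = list(blocker_values)
    if len(s) != len(b):
        raise ValueError(
            f"length mismatch: {len(s)} strengths vs {len(b)} values"
        )
    factors = []
    for w, v in zip(s, b):
        p = w * v
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"blocking probability w*b = {p} outside [0, 1]")
        factors.append(1.0 - p)
    return _sorted_prod(factors)


def noisy_or_and(
    gen_strengths: Sequence[float],
    gen_indicators: Sequence[float],
    prev_strengths: Sequence[float],
    prev_indicators: Sequence[float],
) -> float:
    """The noisy-OR/AND model.

    The effect occurs iff at least one generative capacity is active AND no
    preventive capacity is active:
    ``prod_j(1 - w_j delta(P_j)) * [1 - prod_i(1 - w_i delta(C_i))]``.
    """
    ps, pd_ = _check_pairs(prev_strengths, prev_indicators)
    passthrough = blocking_passthrough(ps, pd_)
    return passthrough * noisy_or(gen_strengths, gen_indicators)


def noisy_max(strengths: Sequence[float], indicators: Sequence[float]) -> float:
    """E(E) = max_i(w_i * delta_i); 0 when no cause is active."""
    s, d = _check_pairs(strengths, indicators, unit_strengths=False)
    contribs = [w * x for w, x in zip(s, d)]
    return max(contribs, default=0.0)


def noisy_addition(strengths: Sequence[float], indicators: Sequence[float]) -> float:
    """E(E) = sum_i(w_i * delta_i)."""
    s, d = _check_pairs(strengths, indicators, unit_strengths=False)
    return float(sum(w * x for w, x in zip(s, d)))


def pairwise_combine(x: float, y: float, U: float) -> float:
    """The privileged two-argument accumulation function ``x + y - xy/U``.

    The unique finite-polynomial function on ``[0, U]`` that is symmetric,
    associative, has 0 as identity (single causes pass through unchanged) and
    saturates at ``U``; see :mod:`causalform.axioms` for the numerical
    verification of that uniqueness.
    """
    if not (U > 0):
        raise ValueError(f"U must be > 0, got {U}")
    for name, v in (("x", x), ("y", y)):
        if not (0.0 <= v <= U):
            raise ValueError(f"{name} = {v} outside [0, {U}]")
    return x + y - x * y / U


# ---------------------------------------------------------------------------
# Expected effect under a capacity model
# ---------------------------------------------------------------------------

def expected_effect(model: CapacityModel, assignment) -> float:
    """Expected effect value under the full bounded-range capacity model.

    Requires both bounds finite; infinite-bound models are served by
    :func:`linear_expected_effect`.  The result always lies in ``[-L, U]``
    and is exactly 0 when every cause is at its inactive value.
    """
    er = model.effect_range
    if not er.finite:
        raise ModelError(
            "expected_effect requires finite bounds; "
            "use linear_expected_effect for infinite-bound models"
        )
    vals = _validated_values(model, assignment)
    L, U = er.lower, er.upper

    gens = model.generators
    if gens:
        gen_term = U * (
            1.0 - _sorted_prod((U - c.strength * vals[c.label]) / U for c in gens)
        )
    else:
        gen_term = 0.0

    reds = model.reducers
    if reds:
        red_term = L * (
            1.0 - _sorted_prod((L - c.strength * vals[c.label]) / L for c in reds)
        )
    else:
        red_term = 0.0

    passthrough = blocking_passthrough(
        [c.strength for c in model.blockers],
        [vals[c.label] for c in model.blockers],
    )
    return passthrough * (gen_term - red_term)


def linear_expected_effect(model: CapacityModel, assignment) -> float:
    """Expected effect in the infinite-bound (linear) limit.

    ``prod_k(1 - w_k b_k) * [sum_i w_i g_i - sum_j w_j r_j]``.  This is the
    form the bounded model converges to as both bounds grow; generator and
    reducer values may be signed here (the bounded form cannot normalize
    signed contributions).
    """
    er = model.effect_range
    if math.isfinite(er.lower) or math.isfinite(er.upper):
        raise ModelError(
            "linear_expected_effect requires both bounds infinite "
            f"(got L = {er.lower}, U = {er.upper})"
        )
    vals = _validated_values(model, assignment, allow_signed=True)
    passthrough = blocking_passthrough(
        [c.strength for c in model.blockers],
        [vals[c.label] for c in model.blockers],
    )
    gen = sum(c.strength * vals[c.label] for c in model.generators)
    red = sum(c.strength * vals[c.label] for c in model.reducers)
    return passthrough * (gen - red)


def linearize_cause(
    values: Sequence[float], transform: Callable[[float], float], tol: float = 1e-9
) -> list[float]:
    """Rescale a non-linear cause so that it acts linearly.

    Modularity of causes licenses an independent (possibly non-linear)
    rescaling of each cause variable; ``transform`` maps the raw scale to the
    linear scale and must be strictly monotone with ``transform(0) = 0`` so
    the inactive state stays at 0.
    """
    t0 = transform(0.0)
    if abs(t0) > tol:
        raise ValueError(f"transform(0) must be 0, got {t0}")
    pts = sorted(set(float(v) for v in values) | {0.0})
    if len(pts) >= 2:
        ts = [transform(p) for p in pts]
        diffs = [b - a for a, b in zip(ts, ts[1:])]
        if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError(
                "transform is not strictly monotone over the provided values"
            )
    return [float(transform(float(v))) for v in values]


def parameter_count(model: CapacityModel, representation: str) -> int:
    """Number of free parameters needed to represent the conditional model.

    With n binary causes the unrestricted conditional distribution needs one
    probability per parent configuration (2^n); the capacity representation
    needs only the n strengths.
    """
    n = len(model.causes)
    if representation == "capacity":
        return n
    if representation == "unrestricted":
        if not model.all_binary:
            raise ModelError(
                "unrestricted parameter count is defined for all-binary models only"
            )
        return 2**n
    raise ValueError(
        f"unknown representation {representation!r}; "
        "expected 'unrestricted' or 'capacity'"
    )
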