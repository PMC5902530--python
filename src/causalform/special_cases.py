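"""Numerical verification that the bounded capacity model reduces to the
classic functional forms in the appropriate regimes.

Four named reductions are checked:

* **noisy-or-and** — with L = 0, U = 1 and binary causes the bounded model
  *is* the noisy-OR/AND model, exactly (the check is over exhaustive binary
  assignments and the agreement is at machine precision);
* **linear** — with no blockers and fixed contributions, the bounded model
  converges to ``sum w_i g_i - sum w_j r_j`` as both bound magnitudes grow,
  at rate O(1/min(U, L)); for two generators the finite-U gap equals xy/U in
  closed form;
* **noisy-addition** — binary generators only: the large-U limit is the
  additive model ``sum w_i delta_i``;
* **blocked-linear** — with blockers present, the limit is the blocking
  passthrough times the linear bracket.

Infinite-bound statements are verified as limits over finite bound sequences
(default 10, 100, 1000, 10000) rather than symbolically; the two-cause closed
form anchors the convergence rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    CapacityModel,
    Cause,
    EffectRange,
    ModelError,
    blocking_passthrough,
    expected_effect,
    noisy_addition,
    noisy_or_and,
)

__all__ = [
    "ReductionReport",
    "DEFAULT_BOUND_SEQUENCE",
    "verify_noisy_or_and_reduction",
    "verify_linear_limit",
    "verify_noisy_addition_case",
    "verify_blocked_linear_limit",
    "verify_all",
    "example_models",
]

DEFAULT_BOUND_SEQUENCE = (10.0, 100.0, 1000.0, 10000.0)

#: exhaustive binary enumeration is used up to this many causes (2^10 rows),
#: seeded sampling beyond
EXHAUSTIVE_LIMIT = 10


@dataclass
class ReductionReport:
    """Outcome of one reduction check: pass iff max discrepancy <= tolerance."""

    case: str
    model_summary: str
    max_discrepancy: float
    n_assignments: int
    tolerance: float
    details: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        ok = self.max_discrepancy <= self.tolerance
        if "monotone" in self.details:
            ok = ok and bool(self.details["monotone"])
        return ok

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "model": self.model_summary,
            "max_discrepancy": self.max_discrepancy,
            "n_assignments": self.n_assignments,
            "tolerance": self.tolerance,
            "passed": self.passed,
            "details": self.details,
        }


def _summary(model: CapacityModel) -> str:
    return (
        f"{len(model.generators)} generators, {len(model.reducers)} reducers, "
        f"{len(model.blockers)} blockers; L={model.effect_range.lower}, "
        f"U={model.effect_range.upper}"
    )


def _binary_assignments(model: CapacityModel, n_assignments: int | None, seed: int):
    labels = model.labels
    k = len(labels)
    if k <= EXHAUSTIVE_LIMIT:
        for combo in itertools.product((0.0, 1.0), repeat=k):
            yield dict(zip(labels, combo))
    else:
        rng = np.random.default_rng(seed)
        n = n_assignments or 1024
        for row in rng.integers(0, 2, size=(n, k)):
            yield dict(zip(labels, row.astype(float)))


def verify_noisy_or_and_reduction(
    model: CapacityModel,
    n_assignments: int | None = None,
    seed: int = 0,
    tolerance: float = 1e-12,
) -> ReductionReport:
    """Binary regime: the bounded model equals noisy-OR/AND assignmentwise.

    Requires L = 0, U = 1, no reducers, and binary causes; enumerates all
    binary assignments (sampling past 2^10) and compares the two evaluations.
    """
    er = model.effect_range
    if not (er.lower == 0.0 and er.upper == 1.0):
        raise ModelError(
            f"binary reduction needs L=0, U=1; got L={er.lower}, U={er.upper}"
        )
    if model.reducers:
        raise ModelError("binary reduction regime has no reducers")
    if not model.all_binary:
        raise ModelError("binary reduction needs max_value = 1 for every cause")

    gen_w = [c.strength for c in model.generators]
    blk_w = [c.strength for c in model.blockers]
    max_disc = 0.0
    count = 0
    for assign in _binary_assignments(model, n_assignments, seed):
        e3 = expected_effect(model, assign)
        e2 = noisy_or_and(
            gen_w,
            [assign[c.label] for c in model.generators],
            blk_w,
            [assign[c.label] for c in model.blockers],
        )
        max_disc = max(max_disc, abs(e3 - e2))
        count += 1
    return ReductionReport(
        case="noisy-or-and",
        model_summary=_summary(model),
        max_discrepancy=max_disc,
        n_assignments=count,
        tolerance=tolerance,
    )


def _limit_report(
    case: str,
    model: CapacityModel,
    assignment: dict[str, float],
    target: float,
    U_values,
    L_values,
    tolerance: float,
) -> ReductionReport:
    discs = []
    mins = []
    for U, L in zip(U_values, L_values):
        L_eff = float(L) if model.reducers else 0.0
        m = CapacityModel(EffectRange(lower=L_eff, upper=float(U)), model.causes)
        discs.append(abs(expected_effect(m, assignment) - target))
        mins.append(min(float(U), float(L)) if model.reducers else float(U))
    monotone = all(b <= a + 1e-15 for a, b in zip(discs, discs[1:]))
    # fitted constant for the O(1/min(U, L)) rate
    C = max((d * m for d, m in zip(discs, mins)), default=0.0)
    return ReductionReport(
        case=case,
        model_summary=_summary(model),
        max_discrepancy=discs[-1],
        n_assignments=1,
        tolerance=tolerance,
        details={
            "bounds": [(float(U), float(L)) for U, L in zip(U_values, L_values)],
            "discrepancies": discs,
            "monotone": monotone,
            "rate_constant": C,
            "target": target,
        },
    )


def verify_linear_limit(
    model: CapacityModel,
    assignment: dict[str, float],
    U_values=DEFAULT_BOUND_SEQUENCE,
    L_values=DEFAULT_BOUND_SEQUENCE,
    tolerance: float = 1e-3,
) -> ReductionReport:
    """No blockers: the bounded model converges to the linear bracket.

    The discrepancy from ``sum w_i g_i - sum w_j r_j`` must decrease
    monotonically along the bound sequence and vanish at rate
    O(1/min(U, L)); the fitted rate constant is reported.
    """
    if model.blockers:
        raise ModelError("linear limit regime has no blockers")
    target = sum(
        c.strength * assignment[c.label] for c in model.generators
    ) - sum(c.strength * assignment[c.label] for c in model.reducers)
    return _limit_report(
        "linear", model, assignment, target, U_values, L_values, tolerance
    )


def verify_noisy_addition_case(
    model: CapacityModel,
    U_values=DEFAULT_BOUND_SEQUENCE,
    tolerance: float = 1e-3,
) -> ReductionReport:
    """Binary generators only: the large-U limit is the additive model.

    Checked over exhaustive binary assignments; the reported discrepancy is
    the assignmentwise maximum at the largest bound.
    """
    if model.reducers or model.blockers:
        raise ModelError("noisy-addition regime allows generators only")
    if not model.all_binary:
        raise ModelError("noisy-addition regime needs binary causes")
    strengths = [c.strength for c in model.generators]
    per_bound = []
    count = 0
    for U in U_values:
        m = CapacityModel(EffectRange(lower=0.0, upper=float(U)), model.causes)
        worst = 0.0
        count = 0
        for assign in _binary_assignments(model, None, 0):
            inds = [assign[c.label] for c in model.generators]
            worst = max(
                worst, abs(expected_effect(m, assign) - noisy_addition(strengths, inds))
            )
            count += 1
        per_bound.append(worst)
    monotone = all(b <= a + 1e-15 for a, b in zip(per_bound, per_bound[1:]))
    return ReductionReport(
        case="noisy-addition",
        model_summary=_summary(model),
        max_discrepancy=per_bound[-1],
        n_assignments=count,
        tolerance=tolerance,
        details={
            "bounds": [float(U) for U in U_values],
            "discrepancies": per_bound,
            "monotone": monotone,
        },
    )


def verify_blocked_linear_limit(
    model: CapacityModel,
    U_values=DEFAULT_BOUND_SEQUENCE,
    L_values=DEFAULT_BOUND_SEQUENCE,
    assignment: dict[str, float] | None = None,
    tolerance: float = 1e-3,
) -> ReductionReport:
    """Full model: the limit is blocking passthrough times the linear bracket."""
    if assignment is None:
        assignment = {
            c.label: c.max_value if math.isfinite(c.max_value) else 1.0
            for c in model.causes
        }
    passthrough = blocking_passthrough(
        [c.strength for c in model.blockers],
        [assignment[c.label] for c in model.blockers],
    )
    bracket = sum(
        c.strength * assignment[c.label] for c in model.generators
    ) - sum(c.strength * assignment[c.label] for c in model.reducers)
    return _limit_report(
        "blocked-linear",
        model,
        assignment,
        passthrough * bracket,
        U_values,
        L_values,
        tolerance,
    )


def example_models() -> dict[str, CapacityModel]:
    """Canonical example models exercising each reduction regime."""
    return {
        "noisy-or-and": CapacityModel(
            EffectRange(0.0, 1.0),
            [
                Cause("g1", "generator", 0.2),
                Cause("g2", "generator", 0.5),
                Cause("g3", "generator", 0.9),
                Cause("b1", "blocker", 0.3),
                Cause("b2", "blocker", 0.7),
            ],
        ),
        "linear": CapacityModel(
            EffectRange(10.0, 10.0),
            [
                Cause("g1", "generator", 0.5),
                Cause("g2", "generator", 0.6),
                Cause("r1", "reducer", 0.25),
            ],
        ),
        "noisy-addition": CapacityModel(
            EffectRange(0.0, 10.0),
            [
                Cause("g1", "generator", 0.3),
                Cause("g2", "generator", 0.8),
            ],
        ),
        "blocked-linear": CapacityModel(
            EffectRange(10.0, 10.0),
            [
                Cause("g1", "generator", 0.3),
                Cause("g2", "generator", 0.8),
                Cause("b1", "blocker", 0.5),
                Cause("b2", "blocker", 0.5),
            ],
        ),
    }


def verify_all(seed: int = 0) -> dict[str, ReductionReport]:
    """Run every reduction check on its canonical example model."""
    models = example_models()
    all_on = {
        name: {c.label: 1.0 for c in m.causes} for name, m in models.items()
    }
    return {
        "noisy-or-and": verify_noisy_or_and_reduction(models["noisy-or-and"], seed=seed),
        "linear": verify_linear_limit(models["linear"], all_on["linear"]),
        "noisy-addition": verify_noisy_addition_case(models["noisy-addition"]),
        "blocked-linear": verify_blocked_linear_limit(models["blocked-linear"]),
    }
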