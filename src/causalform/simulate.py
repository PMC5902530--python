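"""Synthetic trial generation, strength estimation, and the classic
single-cause judgment statistics.

The capacity model pins down only the conditional *expectation* of the
effect, so an observation-noise family must be chosen to simulate trials.
Three families are provided, each with support matching the declared effect
range so the model's expectation is the regression function by construction:

* ``bernoulli`` — binary effect, requires L = 0 and U = 1;
* ``scaled-beta`` — continuous effect on a finite ``[-L, U]``, a Beta law
  re-parametrized by mean and precision then affinely mapped onto the range;
* ``gaussian`` — additive Gaussian noise around the linear (infinite-bound)
  expectation.

Strengths are recovered from trial tables by bound-constrained maximum
likelihood (Bernoulli) or least squares (continuous families), with analytic
gradients of the product-form mean and seeded multi-starts.  For binary
designs the classic contingency-table judgments are available: delta-P
(the linear model's single-cause statistic) and causal power (the noisy-OR
strength estimate), which coincide exactly when the background rate is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import (
    AssignmentError,
    CapacityModel,
    ModelError,
    blocking_passthrough,
)

__all__ = [
    "NoiseSpec",
    "TrialTable",
    "ContingencyTable",
    "EstimationResult",
    "NOISE_FAMILIES",
    "REGIMES",
    "binary_design",
    "uniform_design",
    "fixed_design",
    "simulate_trials",
    "generate_value_sequences",
    "delta_p",
    "causal_power",
    "predicted_judgment",
    "aggregate_contingency",
    "fit_weights",
    "recovery_experiment",
]

NOISE_FAMILIES = ("bernoulli", "scaled-beta", "gaussian")
REGIMES = ("binary", "narrow-continuous", "wide-continuous")

#: interior clamp for Beta means sitting exactly on a support endpoint
_BETA_CLAMP = 1e-9


class EstimationError(ValueError):
    """A judgment statistic or fit is undefined for the given data."""


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise family and dispersion.

    ``dispersion`` is the Beta precision (alpha + beta) for ``scaled-beta``
    and the standard deviation for ``gaussian``; it is ignored for
    ``bernoulli``, whose dispersion is fixed by the mean.
    """

    family: str
    dispersion: float = 20.0

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(
                f"unknown noise family {self.family!r}; "
                f"valid families: {', '.join(NOISE_FAMILIES)}"
            )
        if not (self.dispersion > 0):
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")

    def check_compatible(self, model: CapacityModel) -> None:
        er = model.effect_range
        if self.family == "bernoulli" and not (er.lower == 0.0 and er.upper == 1.0):
            raise ModelError(
                f"bernoulli noise needs L=0, U=1; got L={er.lower}, U={er.upper}"
            )
        if self.family == "scaled-beta" and not er.finite:
            raise ModelError("scaled-beta noise needs both bounds finite")
        if self.family == "gaussian" and er.finite:
            raise ModelError(
                "gaussian noise serves the infinite-bound (linear) model only"
            )


@dataclass
class TrialTable:
    """Simulated or supplied trials: cause-value columns plus an effect column."""

    data: pd.DataFrame
    regime: str | None = None
    seed: int | None = None
    model_label: str | None = None

    EFFECT_COLUMN = "effect"

    def __post_init__(self) -> None:
        if self.EFFECT_COLUMN not in self.data.columns:
            raise ValueError(f"trial table needs an {self.EFFECT_COLUMN!r} column")
        if self.regime is not None and self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cause_labels(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != self.EFFECT_COLUMN)

    @property
    def effects(self) -> np.ndarray:
        return self.data[self.EFFECT_COLUMN].to_numpy(dtype=float)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one binary cause and a binary effect."""

    n_ce: int  # cause present, effect present
    n_cn: int  # cause present, effect absent
    n_ne: int  # cause absent, effect present
    n_nn: int  # cause absent, effect absent

    def __post_init__(self) -> None:
        for name in ("n_ce", "n_cn", "n_ne", "n_nn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_cause_present(self) -> int:
        return self.n_ce + self.n_cn

    @property
    def n_cause_absent(self) -> int:
        return self.n_ne + self.n_nn

    @property
    def p_effect_given_cause(self) -> float:
        if self.n_cause_present == 0:
            raise EstimationError("no cause-present trials: P(e|c) undefined")
        return self.n_ce / self.n_cause_present

    @property
    def p_effect_given_no_cause(self) -> float:
        if self.n_cause_absent == 0:
            raise EstimationError("no cause-absent trials: P(e|~c) undefined")
        return self.n_ne / self.n_cause_absent


def delta_p(ct: ContingencyTable) -> float:
    """Delta-P: P(effect | cause) - P(effect | no cause), in [-1, 1]."""
    return ct.p_effect_given_cause - ct.p_effect_given_no_cause


def causal_power(ct: ContingencyTable) -> float:
    """Generative causal power: delta-P / (1 - P(effect | no cause)).

    This is the single-cause noisy-OR strength: the w solving
    ``P(e|c) = w + P(e|~c) - w * P(e|~c)``.  Undefined when the background
    rate is 1; the preventive case (negative delta-P) is out of scope here.
    """
    p0 = ct.p_effect_given_no_cause
    dp = delta_p(ct)
    if p0 >= 1.0:
        raise EstimationError("P(effect | no cause) = 1: causal power undefined")
    if dp < 0:
        raise EstimationError(
            "negative delta-P: preventive case, outside the generative power estimator"
        )
    return dp / (1.0 - p0)


def predicted_judgment(ct: ContingencyTable, assumed_form: str) -> float:
    """Point prediction of a single-cause strength judgment.

    ``noisy-or-and`` reasoners judge causal power; ``linear`` reasoners judge
    delta-P.  The two coincide exactly when the background rate is 0.
    """
    if assumed_form == "noisy-or-and":
        return causal_power(ct)
    if assumed_form == "linear":
        return delta_p(ct)
    raise ValueError(
        f"unknown assumed_form {assumed_form!r}; expected 'noisy-or-and' or 'linear'"
    )


def aggregate_contingency(table: TrialTable, cause: str) -> ContingencyTable:
    """Collapse a binary trial table to the 2x2 counts for one cause."""
    if cause not in table.cause_labels:
        raise KeyError(cause)
    c = table.data[cause].to_numpy(dtype=float) > 0
    e = table.effects > 0
    return ContingencyTable(
        n_ce=int(np.sum(c & e)),
        n_cn=int(np.sum(c & ~e)),
        n_ne=int(np.sum(~c & e)),
        n_nn=int(np.sum(~c & ~e)),
    )


# ---------------------------------------------------------------------------
# Designs and simulation
# ---------------------------------------------------------------------------

def binary_design(p_active: float = 0.5, always_on: Sequence[str] = ()):
    """Each cause independently at max_value with probability p_active.

    Causes listed in ``always_on`` (e.g. an explicit background generator)
    are at max_value in every trial.
    """
    on = set(always_on)

    def sample(rng: np.random.Generator, model: CapacityModel, n: int) -> pd.DataFrame:
        cols = {}
        for c in model.causes:
            if c.label in on:
                cols[c.label] = np.full(n, c.max_value)
            else:
                cols[c.label] = (rng.random(n) < p_active) * c.max_value
        return pd.DataFrame(cols)

    return sample


def uniform_design(p_active: float = 0.5):
    """Each cause active with probability p_active, value uniform on (0, M]."""

    def sample(rng: np.random.Generator, model: CapacityModel, n: int) -> pd.DataFrame:
        cols = {}
        for c in model.causes:
            if not math.isfinite(c.max_value):
                raise ModelError(
                    f"uniform design needs a finite max_value for {c.label!r}"
                )
            active = rng.random(n) < p_active
            cols[c.label] = active * rng.uniform(0.0, c.max_value, n)
        return pd.DataFrame(cols)

    return sample


def fixed_design(assignment: dict[str, float]):
    """Every trial uses the same cause assignment."""

    def sample(rng: np.random.Generator, model: CapacityModel, n: int) -> pd.DataFrame:
        return pd.DataFrame({c.label: np.full(n, assignment[c.label]) for c in model.causes})

    return sample


def _mean_matrix(model: CapacityModel, values: pd.DataFrame, strengths: np.ndarray | None = None) -> np.ndarray:
    """Vectorized expected effect over a trial-by-cause value matrix."""
    er = model.effect_range
    w = {c.label: (strengths[i] if strengths is not None else c.strength)
         for i, c in enumerate(model.causes)}
    n = len(values)
    if er.finite:
        L, U = er.lower, er.upper
        gen = np.zeros(n)
        if model.generators:
            prod = np.ones(n)
            for c in model.generators:
                prod *= (U - w[c.label] * values[c.label].to_numpy(dtype=float)) / U
            gen = U * (1.0 - prod)
        red = np.zeros(n)
        if model.reducers:
            prod = np.ones(n)
            for c in model.reducers:
                prod *= (L - w[c.label] * values[c.label].to_numpy(dtype=float)) / L
            red = L * (1.0 - prod)
        bracket = gen - red
    else:
        bracket = np.zeros(n)
        for c in model.generators:
            bracket += w[c.label] * values[c.label].to_numpy(dtype=float)
        for c in model.reducers:
            bracket -= w[c.label] * values[c.label].to_numpy(dtype=float)
    block = np.ones(n)
    for c in model.blockers:
        block *= 1.0 - w[c.label] * values[c.label].to_numpy(dtype=float)
    return block * bracket


def simulate_trials(
    model: CapacityModel,
    noise: NoiseSpec,
    design: Callable[[np.random.Generator, CapacityModel, int], pd.DataFrame],
    n: int,
    seed: int,
    regime: str | None = None,
) -> TrialTable:
    """Draw n trials: sample assignments from the design, then observe the
    effect from the noise family centered on the model's expectation.

    Identical seeds reproduce identical tables bit-for-bit.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    noise.check_compatible(model)
    rng = np.random.default_rng(seed)
    values = design(rng, model, n)
    if list(values.columns) != list(model.labels):
        values = values[list(model.labels)]
    mean = _mean_matrix(model, values)

    er = model.effect_range
    if noise.family == "bernoulli":
        effect = (rng.random(n) < mean).astype(float)
    elif noise.family == "scaled-beta":
        L, U = er.lower, er.upper
        span = U + L
        m = np.clip((mean + L) / span, _BETA_CLAMP, 1.0 - _BETA_CLAMP)
        nu = noise.dispersion
        effect = -L + span * rng.beta(m * nu, (1.0 - m) * nu)
    else:  # gaussian
        effect = mean + rng.normal(0.0, noise.dispersion, n)

    data = values.copy()
    data[TrialTable.EFFECT_COLUMN] = effect
    return TrialTable(data=data, regime=regime, seed=seed, model_label=None)


#: functional levels per regime: (low mean, low sd, high mean, high sd)
_REGIME_LEVELS = {
    "binary": (0.0, 0.0, 1.0, 0.0),
    "narrow-continuous": (0.0, 0.02, 1.0, 0.03),
    "wide-continuous": (0.0, 0.04, 17.32, 0.5),
}


def generate_value_sequences(
    regime: str, n: int, seed: int, p_high: float = 0.25
) -> np.ndarray:
    """A value sequence with two functional levels, framed per regime.

    The same seed produces the same low/high pattern in every regime, so the
    three sequences carry essentially the same information while cueing
    different value ranges: binary gives 0/1 exactly; narrow-continuous
    jitters tightly around 0 and 1; wide-continuous spreads the high level
    far from the low one (still only two functionally distinct values).
    Thresholding at half the functional gap recovers the shared pattern.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; valid: {', '.join(REGIMES)}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    pattern = rng.random(n) < p_high  # drawn first: shared across regimes
    lo, lo_sd, hi, hi_sd = _REGIME_LEVELS[regime]
    values = np.where(
        pattern,
        hi + (rng.normal(0.0, hi_sd, n) if hi_sd else 0.0),
        lo + (rng.normal(0.0, lo_sd, n) if lo_sd else 0.0),
    )
    return values


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

@dataclass
class EstimationResult:
    """Bound-constrained strength estimates for one skeleton model."""

    strengths: dict[str, float]
    objective: float
    converged: bool
    n_trials: int
    family: str
    unidentifiable: tuple[str, ...] = ()
    stderr: dict[str, float] | None = None


def _strength_bounds(model: CapacityModel) -> list[tuple[float, float]]:
    er = model.effect_range
    bounds = []
    for c in model.causes:
        if not math.isfinite(c.max_value):
            bounds.append((0.0, np.inf))
            continue
        if c.role == "generator":
            ub = er.upper / c.max_value if math.isfinite(er.upper) else np.inf
        elif c.role == "reducer":
            ub = er.lower / c.max_value if math.isfinite(er.lower) else np.inf
        else:
            ub = 1.0 / c.max_value
        bounds.append((0.0, ub))
    return bounds


def _mean_and_grad(
    model: CapacityModel, w: np.ndarray, cols: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Expected effect and its gradient w.r.t. each strength, per trial.

    Uses the product structure directly: leave-one-out products give exact
    derivatives, which is what lets the ML fit match closed-form estimators
    to optimizer precision.
    """
    er = model.effect_range
    n = cols[0].shape[0]
    k = len(model.causes)
    gen_idx = [i for i, c in enumerate(model.causes) if c.role == "generator"]
    red_idx = [i for i, c in enumerate(model.causes) if c.role == "reducer"]
    blk_idx = [i for i, c in enumerate(model.causes) if c.role == "blocker"]

    grad = np.zeros((k, n))
    if er.finite:
        L, U = er.lower, er.upper

        def group_term(idx, bound):
            if not idx:
                return np.zeros(n), {}
            factors = {i: (bound - w[i] * cols[i]) / bound for i in idx}
            prod = np.ones(n)
            for i in idx:
                prod *= factors[i]
            loo = {}
            for i in idx:
                p = np.ones(n)
                for j in idx:
                    if j != i:
                        p *= factors[j]
                loo[i] = p
            return bound * (1.0 - prod), loo

        gen_term, gen_loo = group_term(gen_idx, U)
        red_term, red_loo = group_term(red_idx, L)
        bracket = gen_term - red_term
    else:
        bracket = np.zeros(n)
        for i in gen_idx:
            bracket += w[i] * cols[i]
        for i in red_idx:
            bracket -= w[i] * cols[i]
        gen_loo = red_loo = None

    block = np.ones(n)
    blk_factors = {i: 1.0 - w[i] * cols[i] for i in blk_idx}
    for i in blk_idx:
        block *= blk_factors[i]

    mean = block * bracket

    for i in gen_idx:
        grad[i] = block * cols[i] * (gen_loo[i] if gen_loo is not None else 1.0)
    for i in red_idx:
        grad[i] = -block * cols[i] * (red_loo[i] if red_loo is not None else 1.0)
    for i in blk_idx:
        loo = np.ones(n)
        for j in blk_idx:
            if j != i:
                loo *= blk_factors[j]
        grad[i] = -cols[i] * loo * bracket
    return mean, grad


def fit_weights(
    table: TrialTable,
    skeleton: CapacityModel,
    noise: NoiseSpec,
    seed: int = 0,
    n_starts: int = 5,
) -> EstimationResult:
    """Estimate causal strengths from a trial table.

    Bernoulli data are fit by maximum likelihood, continuous families by
    least squares, both with the model's expectation as the mean structure,
    analytic gradients, box constraints from the effect range, and seeded
    multi-starts (the objective can be multi-modal with correlated causes).
    A cause whose column is constant across trials is flagged unidentifiable.
    """
    noise.check_compatible(skeleton)
    labels = list(skeleton.labels)
    missing = set(labels) - set(table.cause_labels)
    if missing:
        raise AssignmentError(f"trial table lacks columns for {sorted(missing)}")
    n = len(table)
    k = len(labels)
    if n < 10 * k:
        raise ValueError(
            f"need at least 10 trials per strength ({10 * k}), got {n}"
        )
    cols = [table.data[l].to_numpy(dtype=float) for l in labels]
    y = table.effects
    unident = tuple(
        l for l, c in zip(labels, cols) if np.ptp(c) == 0.0
    )
    bounds = _strength_bounds(skeleton)

    bernoulli = noise.family == "bernoulli"

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        mean, grad = _mean_and_grad(skeleton, w, cols)
        if bernoulli:
            mu = np.clip(mean, 1e-12, 1.0 - 1e-12)
            nll = -np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu))
            dmu = (mu - y) / (mu * (1.0 - mu))
            return float(nll), grad @ dmu
        resid = mean - y
        return float(np.sum(resid**2)), 2.0 * (grad @ resid)

    rng = np.random.default_rng(seed)
    starts = []
    base = np.array([min(0.25 * (ub if np.isfinite(ub) else 1.0), 1.0) or 0.1
                     for _, ub in bounds])
    starts.append(base)
    for _ in range(n_starts - 1):
        starts.append(
            np.array([rng.uniform(0.0, min(ub, 2.0) if np.isfinite(ub) else 2.0)
                      for _, ub in bounds])
        )

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 2000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    strengths = {l: float(v) for l, v in zip(labels, best.x)}
    return EstimationResult(
        strengths=strengths,
        objective=float(best.fun),
        converged=any_converged,
        n_trials=n,
        family=noise.family,
        unidentifiable=unident,
    )


def recovery_experiment(
    true_model: CapacityModel,
    noise: NoiseSpec,
    design,
    n_grid: Sequence[int],
    reps: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate-and-refit at each sample size; report bias and RMSE per strength.

    Fully seeded: per-replicate seeds are spawned deterministically from the
    master seed, so identical calls give identical tables.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(n_grid) * reps) % (2**31)
    skeleton = true_model.with_strengths({c.label: 0.0 for c in true_model.causes})
    rows = []
    idx = 0
    for n in n_grid:
        estimates: dict[str, list[float]] = {c.label: [] for c in true_model.causes}
        for _ in range(reps):
            s = int(child_seeds[idx])
            idx += 1
            table = simulate_trials(true_model, noise, design, n, seed=s)
            fit = fit_weights(table, skeleton, noise, seed=s)
            for l, v in fit.strengths.items():
                estimates[l].append(v)
        for c in true_model.causes:
            est = np.array(estimates[c.label])
            rows.append(
                {
                    "n": int(n),
                    "cause": c.label,
                    "true_strength": c.strength,
                    "bias": float(np.mean(est) - c.strength),
                    "rmse": float(np.sqrt(np.mean((est - c.strength) ** 2))),
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)
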