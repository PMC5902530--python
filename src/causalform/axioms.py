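"""Axiom checks for candidate accumulation functions, and a numerical
uniqueness solver for the privileged form.

A two-argument combination function ``f(x, y)`` on ``[0, U]^2`` describes how
two independent causal contributions accumulate into one expected effect.
The assumption set checked here:

* **symmetry** — f(x, y) = f(y, x);
* **associativity** (with commutativity of incorporation) —
  f(f(x, y), z) = f(x, f(y, z)), so n-cause accumulation is well defined;
* **no uncaused effects** — f(0, 0) = 0;
* **distinct causal effect** — f(x, 0) = x and f(0, y) = y: a lone
  contribution passes through unchanged;
* **generative accumulation** — f(U, U) = U: maximal causes saturate the
  effect at its upper bound;
* **smooth accumulation** — any non-maximal value strictly increases when
  either input increases (this is what MAX-type functions violate);
* **determinism** — f is a many-one mapping; any side-effect-free evaluator
  satisfies this by construction, so it is recorded structurally.

Among functions expressible as finite polynomials, the first five conditions
single out ``f(x, y) = x + y - xy/U`` uniquely.  The checks here are grid
based (the claims are analytic; the artifact verifies numerically), and
:func:`solve_unique_polynomial` recovers the unique coefficient vector by
solving the constraint system at bounded degree.  Whether smooth accumulation
can replace the polynomial restriction is an open question; the suite lets
users probe candidates but claims nothing about it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CombinationFunction",
    "AxiomCheck",
    "AxiomReport",
    "PolynomialSolution",
    "privileged_combination",
    "get_builtin",
    "BUILTIN_NAMES",
    "check_symmetry",
    "check_associativity_commutativity",
    "check_no_uncaused_effects",
    "check_distinct_causal_effect",
    "check_generative_accumulation",
    "check_smooth_accumulation",
    "run_axiom_suite",
    "solve_unique_polynomial",
]

DEFAULT_TOL = 1e-9
DEFAULT_GRID = 21

AXIOM_NAMES = (
    "symmetry",
    "associativity",
    "no_uncaused_effects",
    "distinct_causal_effect",
    "generative_accumulation",
    "smooth_accumulation",
    "determinism",
)


@dataclass(frozen=True)
class CombinationFunction:
    """A candidate two-argument accumulation function on ``[0, U]^2``."""

    name: str
    func: Callable[[float, float], float]
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not (self.upper > 0):
            raise ValueError(f"upper bound must be > 0, got {self.upper}")

    def __call__(self, x: float, y: float) -> float:
        return float(self.func(x, y))


def privileged_combination(U: float = 1.0) -> CombinationFunction:
    """The privileged form ``x + y - xy/U``."""
    return CombinationFunction("privileged", lambda x, y: x + y - x * y / U, U)


def get_builtin(name: str, U: float = 1.0) -> CombinationFunction:
    """Look up a builtin combination function by registry name."""
    builders = {
        "privileged": lambda: privileged_combination(U),
        "noisy-or": lambda: CombinationFunction(
            "noisy-or", lambda x, y: x + y - x * y, U
        ),
        "max": lambda: CombinationFunction("max", lambda x, y: max(x, y), U),
        "addition": lambda: CombinationFunction("addition", lambda x, y: x + y, U),
        "mean": lambda: CombinationFunction("mean", lambda x, y: (x + y) / 2.0, U),
    }
    try:
        return builders[name]()
    except KeyError:
        raise KeyError(
            f"unknown builtin {name!r}; available: {', '.join(sorted(builders))}"
        ) from None


BUILTIN_NAMES = ("privileged", "noisy-or", "max", "addition", "mean")


@dataclass(frozen=True)
class AxiomCheck:
    """Outcome of one axiom check.

    A ``fail`` always carries a counterexample (the offending inputs plus the
    two sides' values); a ``pass`` never does, so reports are self-verifying.
    """

    axiom: str
    status: str  # "pass" | "fail" | "not-applicable"
    counterexample: tuple | None = None  # (inputs, lhs, rhs)
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status == "fail" and self.counterexample is None:
            raise ValueError(f"failed check {self.axiom!r} must carry a counterexample")
        if self.status == "pass" and self.counterexample is not None:
            raise ValueError(f"passing check {self.axiom!r} must not carry one")


@dataclass
class AxiomReport:
    """Aggregated axiom-suite outcome for one candidate function."""

    function_name: str
    upper: float
    grid_n: int
    tolerance: float
    epsilon: float
    checks: dict[str, AxiomCheck] = field(default_factory=dict)

    @property
    def failed_axioms(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in AXIOM_NAMES
            if name in self.checks and self.checks[name].status == "fail"
        )

    @property
    def all_pass(self) -> bool:
        return not self.failed_axioms

    def to_dict(self) -> dict:
        return {
            "function": self.function_name,
            "upper": self.upper,
            "grid_n": self.grid_n,
            "tolerance": self.tolerance,
            "epsilon": self.epsilon,
            "checks": {
                name: {
                    "status": c.status,
                    "counterexample": c.counterexample,
                    "detail": c.detail,
                }
                for name, c in self.checks.items()
            },
            "all_pass": self.all_pass,
        }


def _grid(U: float, n: int) -> np.ndarray:
    if n < 2:
        raise ValueError(f"grid_n must be >= 2, got {n}")
    return np.linspace(0.0, U, n)


def check_symmetry(
    f: CombinationFunction, grid_n: int = DEFAULT_GRID, tol: float = DEFAULT_TOL
) -> AxiomCheck:
    """f(x, y) must equal f(y, x) on every grid pair."""
    g = _grid(f.upper, grid_n)
    for x in g:
        for y in g:
            lhs, rhs = f(x, y), f(y, x)
            if abs(lhs - rhs) > tol:
                return AxiomCheck("symmetry", "fail", ((float(x), float(y)), lhs, rhs))
    return AxiomCheck("symmetry", "pass")


def check_associativity_commutativity(
    f: CombinationFunction, grid_n: int = DEFAULT_GRID, tol: float = DEFAULT_TOL
) -> tuple[AxiomCheck, AxiomCheck]:
    """f(f(x,y),z) must equal f(x,f(y,z)) on every grid triple.

    Closure of the grid image in ``[0, U]`` is checked alongside and reported
    as its own entry; a closure violation does not by itself fail
    associativity (the identity can still hold off-range).
    """
    g = _grid(f.upper, grid_n)
    closure: AxiomCheck | None = None
    assoc: AxiomCheck | None = None
    for x in g:
        for y in g:
            v = f(x, y)
            if closure is None and not (-tol <= v <= f.upper + tol):
                closure = AxiomCheck(
                    "closure",
                    "fail",
                    ((float(x), float(y)), v, None),
                    detail=f"f(x, y) leaves [0, {f.upper}]",
                )
            if assoc is None:
                for z in g:
                    lhs = f(f(x, y), z)
                    rhs = f(x, f(y, z))
                    if abs(lhs - rhs) > tol:
                        assoc = AxiomCheck(
                            "associativity",
                            "fail",
                            ((float(x), float(y), float(z)), lhs, rhs),
                        )
                        break
    if closure is None:
        closure = AxiomCheck("closure", "pass")
    if assoc is None:
        assoc = AxiomCheck("associativity", "pass")
    return assoc, closure


def check_no_uncaused_effects(
    f: CombinationFunction, tol: float = DEFAULT_TOL
) -> AxiomCheck:
    """f(0, 0) must be 0: with nothing active the effect stays at baseline."""
    v = f(0.0, 0.0)
    if abs(v) > tol:
        return AxiomCheck("no_uncaused_effects", "fail", ((0.0, 0.0), v, 0.0))
    return AxiomCheck("no_uncaused_effects", "pass")


def check_distinct_causal_effect(
    f: CombinationFunction, grid_n: int = DEFAULT_GRID, tol: float = DEFAULT_TOL
) -> AxiomCheck:
    """f(x, 0) = x and f(0, y) = y: a lone contribution passes through."""
    g = _grid(f.upper, grid_n)
    for v in g:
        lhs = f(v, 0.0)
        if abs(lhs - v) > tol:
            return AxiomCheck(
                "distinct_causal_effect", "fail", ((float(v), 0.0), lhs, float(v))
            )
        lhs = f(0.0, v)
        if abs(lhs - v) > tol:
            return AxiomCheck(
                "distinct_causal_effect", "fail", ((0.0, float(v)), lhs, float(v))
            )
    return AxiomCheck("distinct_causal_effect", "pass")


def check_generative_accumulation(
    f: CombinationFunction, tol: float = DEFAULT_TOL
) -> AxiomCheck:
    """f(U, U) = U: maximal contributions saturate at the upper bound."""
    U = f.upper
    v = f(U, U)
    if abs(v - U) > tol:
        return AxiomCheck("generative_accumulation", "fail", ((U, U), v, U))
    return AxiomCheck("generative_accumulation", "pass")


def check_smooth_accumulation(
    f: CombinationFunction,
    grid_n: int = DEFAULT_GRID,
    epsilon: float | None = None,
    tol: float = DEFAULT_TOL,
) -> AxiomCheck:
    """Non-maximal values must strictly increase when either input increases.

    Grid points where the perturbed input would leave ``[0, U]`` are skipped,
    not failed.
    """
    U = f.upper
    if epsilon is None:
        epsilon = U / 100.0
    if not (0 < epsilon <= U):
        raise ValueError(f"epsilon must be in (0, U], got {epsilon}")
    g = _grid(U, grid_n)
    for x in g:
        for y in g:
            v = f(x, y)
            if v >= U - tol:
                continue
            if x + epsilon <= U and not f(x + epsilon, y) > v:
                return AxiomCheck(
                    "smooth_accumulation",
                    "fail",
                    ((float(x), float(y)), f(x + epsilon, y), v),
                    detail=f"no strict increase in x by epsilon={epsilon}",
                )
            if y + epsilon <= U and not f(x, y + epsilon) > v:
                return AxiomCheck(
                    "smooth_accumulation",
                    "fail",
                    ((float(x), float(y)), f(x, y + epsilon), v),
                    detail=f"no strict increase in y by epsilon={epsilon}",
                )
    return AxiomCheck("smooth_accumulation", "pass")


def run_axiom_suite(
    f: CombinationFunction,
    grid_n: int = DEFAULT_GRID,
    epsilon: float | None = None,
    tol: float = DEFAULT_TOL,
) -> AxiomReport:
    """Run every axiom check on one candidate and aggregate the outcomes."""
    if epsilon is None:
        epsilon = f.upper / 100.0
    report = AxiomReport(
        function_name=f.name,
        upper=f.upper,
        grid_n=grid_n,
        tolerance=tol,
        epsilon=epsilon,
    )
    report.checks["symmetry"] = check_symmetry(f, grid_n, tol)
    assoc, closure = check_associativity_commutativity(f, grid_n, tol)
    report.checks["associativity"] = assoc
    report.checks["closure"] = closure
    report.checks["no_uncaused_effects"] = check_no_uncaused_effects(f, tol)
    report.checks["distinct_causal_effect"] = check_distinct_causal_effect(
        f, grid_n, tol
    )
    report.checks["generative_accumulation"] = check_generative_accumulation(f, tol)
    report.checks["smooth_accumulation"] = check_smooth_accumulation(
        f, grid_n, epsilon, tol
    )
    report.checks["determinism"] = AxiomCheck(
        "determinism",
        "pass",
        detail="pure evaluator: identical inputs give identical outputs by construction",
    )
    return report


# ---------------------------------------------------------------------------
# Polynomial uniqueness solver
# ---------------------------------------------------------------------------

@dataclass
class PolynomialSolution:
    """A symmetric polynomial satisfying the axiom constraint system.

    ``coefficients`` maps exponent pairs (i, j) to a_ij for i + j <= degree_cap,
    including the entries pinned analytically by the single-cause condition
    (a_00 = 0, a_10 = a_01 = 1, a_i0 = a_0i = 0 for i >= 2).
    """

    degree_cap: int
    upper: float
    coefficients: dict[tuple[int, int], float]
    residual: float
    unique: bool
    n_solutions: int

    def coefficient(self, i: int, j: int) -> float:
        return self.coefficients.get((i, j), 0.0)

    def evaluate(self, x: float, y: float) -> float:
        return float(
            sum(a * x**i * y**j for (i, j), a in self.coefficients.items())
        )


def _free_exponents(degree_cap: int) -> list[tuple[int, int]]:
    # terms with both exponents >= 1 (everything else is pinned by f(x,0)=x),
    # one representative per symmetric pair
    return [
        (i, j)
        for i in range(1, degree_cap)
        for j in range(1, i + 1)
        if i + j <= degree_cap
    ]


def _poly_eval(free: list[tuple[int, int]], a: np.ndarray, x, y):
    out = x + y
    for (i, j), coef in zip(free, a):
        if i == j:
            out = out + coef * x**i * y**j
        else:
            out = out + coef * (x**i * y**j + x**j * y**i)
    return out


def _solve_identity_system(degree_cap: int, U: float) -> list[np.ndarray]:
    """Exact solutions of the associativity + accumulation system.

    Expands f(f(x,y),z) - f(x,f(y,z)) symbolically, sets every monomial
    coefficient to zero, adds f(U,U) = U, and solves in rational arithmetic.
    This resolves the degeneracy that caps double-precision accuracy: at
    degree >= 4 the direction xy(U-x)(U-y) satisfies every constraint to
    first order (it is the tangent of the reparametrization family
    psi^-1(f(psi x, psi y))), so the unique polynomial solution is a double
    root that floating-point least squares can only localize to ~sqrt(eps).
    """
    import sympy as sp

    free = _free_exponents(degree_cap)
    a = sp.symbols(f"a0:{len(free)}")
    x, y, z = sp.symbols("x y z")
    Ur = sp.Rational(U)  # binary floats are exact rationals

    def f(xx, yy):
        out = xx + yy
        for (i, j), coef in zip(free, a):
            if i == j:
                out += coef * xx**i * yy**j
            else:
                out += coef * (xx**i * yy**j + xx**j * yy**i)
        return out

    ident = sp.expand(f(f(x, y), z) - f(x, f(y, z)))
    eqs = sp.Poly(ident, (x, y, z)).coeffs()
    eqs.append(sp.expand(f(Ur, Ur) - Ur))
    raw = sp.solve(list(set(eqs)), list(a), dict=True)
    out = []
    for sol in raw:
        vec = [complex(sp.nsimplify(sol.get(s, 0))) for s in a]
        if all(abs(v.imag) < 1e-12 for v in vec):
            out.append(np.array([v.real for v in vec]))
    return out


def solve_unique_polynomial(
    degree_cap: int,
    U: float,
    seed: int = 0,
    n_triples: int = 50,
    n_starts: int = 16,
    tol: float = 1e-6,
) -> PolynomialSolution:
    """Solve the axiom constraint system over symmetric polynomials.

    The candidate is ``f(x, y) = sum a_ij x^i y^j`` with ``i + j <= degree_cap``
    and ``a_ij = a_ji``.  Symmetry is built into the parametrization; the
    single-cause condition f(x, 0) = x pins a_00 = 0, a_10 = 1 and kills all
    other pure-x terms, leaving only mixed coefficients free.  The remaining
    constraints — f(U, U) = U and associativity — are solved in two stages:
    multi-start least squares on a seeded sample of interior triples plus all
    corner triples (candidate discovery), then an exact symbolic solve of the
    full identity system, which pins the double root the float stage can only
    bracket.  Converged candidates and exact solutions are clustered jointly
    to decide uniqueness.  The known answer is a_11 = -1/U with every other
    mixed coefficient 0, i.e. x + y - xy/U.
    """
    if degree_cap < 2:
        raise ValueError(f"degree_cap must be >= 2, got {degree_cap}")
    if not (U > 0):
        raise ValueError(f"U must be > 0, got {U}")
    free = _free_exponents(degree_cap)
    rng = np.random.default_rng(seed)

    triples = rng.uniform(0.0, U, size=(n_triples, 3))
    corners = np.array(list(itertools.product((0.0, U), repeat=3)))
    triples = np.vstack([triples, corners])
    tx, ty, tz = triples[:, 0], triples[:, 1], triples[:, 2]

    def residuals(a: np.ndarray) -> np.ndarray:
        fa = _poly_eval(free, a, tx, ty)
        fb = _poly_eval(free, a, ty, tz)
        assoc = _poly_eval(free, a, fa, tz) - _poly_eval(free, a, tx, fb)
        accum = _poly_eval(free, a, np.array(U), np.array(U)) - U
        return np.concatenate([assoc, np.atleast_1d(accum)])

    def jacobian(a: np.ndarray) -> np.ndarray:
        # complex-step differentiation: residuals are polynomial in the
        # coefficients, so this gives the Jacobian to machine precision
        # (finite differences stall the solver on this ill-conditioned system)
        h = 1e-200
        cols = []
        for i in range(len(a)):
            ac = a.astype(complex)
            ac[i] += 1j * h
            cols.append(np.imag(residuals(ac)) / h)
        return np.column_stack(cols)

    # coefficient a_ij scales like U^(1-i-j); spread starts accordingly
    scales = np.array([2.0 * U ** (1 - i - j) for (i, j) in free])
    starts = [np.zeros(len(free))]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(-1.0, 1.0, size=len(free)) * scales)

    solutions: list[tuple[np.ndarray, float]] = []
    for x0 in starts:
        res = least_squares(
            residuals, x0, jac=jacobian,
            method="lm" if len(free) <= len(tx) else "trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
        )
        rnorm = float(np.linalg.norm(res.fun))
        if rnorm <= 1e-9 * max(1.0, U):
            solutions.append((res.x, rnorm))

    exact = _solve_identity_system(degree_cap, U)
    if not solutions and not exact:
        raise RuntimeError(
            f"polynomial solver found no solution at degree_cap={degree_cap}, U={U}"
        )

    if exact:
        # exact roots anchor the clusters; numeric candidates that sit within
        # the double-root basin (sqrt(eps)-wide) collapse onto them
        cluster_tol = max(tol, 1e-5)
        clusters = list(exact)
        ref = exact[0]
        best_rnorm = float(np.linalg.norm(residuals(ref)))
    else:
        ref, best_rnorm = min(solutions, key=lambda s: s[1])
        cluster_tol = tol
        clusters = [ref]
    for a, _ in solutions:
        if all(np.max(np.abs(a - c)) > cluster_tol for c in clusters):
            clusters.append(a)
    unique = len(clusters) == 1

    coeffs: dict[tuple[int, int], float] = {(1, 0): 1.0, (0, 1): 1.0}
    for (i, j), v in zip(free, ref):
        coeffs[(i, j)] = float(v)
        coeffs[(j, i)] = float(v)
    for i in range(degree_cap + 1):
        for j in range(degree_cap + 1 - i):
            coeffs.setdefault((i, j), 0.0)

    return PolynomialSolution(
        degree_cap=degree_cap,
        upper=U,
        coefficients=coeffs,
        residual=best_rnorm,
        unique=unique,
        n_solutions=len(clusters),
    )
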