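# Methods

This note records the modeling assumptions, parameter choices, and numerical
decisions behind `causalform`, including the places where the underlying
theory leaves room for interpretation and what this implementation chose.

## 1. The model

An effect variable takes values in `[-L, U]` with baseline 0, where `L ≥ 0`
and `U ≥ 0` are magnitudes (possibly `inf`, not both 0). Each cause is an
independent capacity with a role, a strength `w ≥ 0`, and a value range
`[0, M]` with 0 the inactive value:

* **generator** — raises the expectation toward `U`; requires `w·M ≤ U`;
* **reducer** — lowers it toward `-L`; requires `w·M ≤ L` and `L > 0`
  (the normalizing division by `L` is undefined at `L = 0`);
* **blocker** — vetoes all other influences with probability `w·b`;
  requires `w·M ≤ 1` since `w·b` is a probability.

The expected effect is

```
E(E) = Π_k (1 − w_k b_k) · [ U(1 − Π_i (U − w_i g_i)/U) − L(1 − Π_j (L − w_j r_j)/L) ]
```

Each group's contributions `w·value/bound` are normalized to `[0, 1]`,
combined by noisy-OR (equivalently, iterated `f(x, y) = x + y − xy/bound`),
and mapped back to the effect scale; blocking multiplies the bracket by the
probability that no blocker fires. Strength is interpretable as expected
change per unit of the cause from inactivity, everything else inactive.

Interpretive choices made here, where the theory is open:

* **Generative accumulation at the boundary.** The saturation axiom is
  implemented as `f(U, U) = U` exactly, with `f` monotone nondecreasing in
  each argument on `[0, U]` (closure is checked as a separate axiom so that
  functions like unclipped addition fail for the right reason — escaping the
  range — rather than via an incidental asymmetry).
* **Blockers act linearly in their value.** The blocking probability is
  `w·b`, linear in `b`, mirroring the linear reading of generator/reducer
  values. A nonlinear blocker can be accommodated by rescaling its value
  (see `linearize_cause`), which the modularity of capacities licenses.
* **Blockers are global.** Every blocker gates the entire bracket. The
  theory also admits cause-specific preventers (a preventer wired to one
  generator's noisy gate); that variant is documented here but not
  implemented — it changes the parameterization, not the functional form,
  and nothing downstream depends on it.
* **Infinite bounds.** When both bounds are infinite the products degenerate
  and the model is served by the explicit linear form
  `Π_k (1 − w_k b_k)·[Σ w_i g_i − Σ w_j r_j]` (`linear_expected_effect`);
  mixed finite/infinite bounds are valid model definitions (the finite side
  normalizes, the infinite side would need a limit) but are not evaluable
  and are rejected by both evaluators with an explanatory error.

## 2. Axiom suite and the uniqueness solver

`run_axiom_suite` checks a two-argument combination function on a grid over
`[0, U]²` (default 21×21, plus all triples of a coarser grid for
associativity) against: symmetry; associativity; determinism (structural —
the function is a deterministic map of its arguments by construction);
no uncaused effects `f(0,0) = 0`; distinct causal effect `f(x,0) = x`;
generative accumulation `f(U,U) = U` with monotonicity; smooth accumulation
(increasing either argument by ε strictly increases the output when below
the bound, checked with ε = U/100 by default); and closure into `[0, U]`.
Every failed check carries a machine-verifiable counterexample
`(inputs, lhs, rhs)`; the report refuses a "fail" without one.

Expected fingerprints: the privileged form passes everything at every `U`;
MAX fails exactly smooth accumulation; unclipped addition fails exactly
generative accumulation (closure also fails, reported separately);
averaging fails associativity with the counterexample
`f(f(1,1),0) = 0.5` vs `f(1,f(1,0)) = 0.75`.

`solve_unique_polynomial(degree_cap, U)` searches for all polynomial
solutions `f(x,y) = Σ a_ij x^i y^j` (symmetric coefficients tied, `a00 = 0`,
`a10 = a01 = 1` imposed by the identity axiom) satisfying associativity and
saturation. Two numerical facts shaped the implementation:

* **The solution is a double root.** The exact reparameterization family
  `ψ⁻¹(f(ψ(x), ψ(y)))` satisfies every axiom except polynomiality, and its
  tangent direction at the identity — proportional to `x y (U−x)(U−y)` —
  lies in the kernel of the least-squares Jacobian at the true solution.
  Gauss–Newton therefore stalls at ~1e-6 coefficient accuracy, exactly at
  the acceptance tolerance.
* **Fix: hybrid exact/numeric solving.** The associativity identity
  `f(f(x,y),z) − f(x,f(y,z)) = 0` is expanded symbolically; its monomial
  coefficients plus the saturation constraint form a polynomial system
  solved exactly in rational arithmetic (sympy, ~0.1 s per degree cap).
  The numeric multi-start least-squares pass (complex-step Jacobian —
  exact for polynomial residuals — tolerances 1e-15) is retained to search
  for solutions the symbolic solve might miss and to cluster/count distinct
  solutions; symbolic roots anchor the clusters. Across degree caps 2–4 and
  `U ∈ {0.5, 1, 2}` the solver reports a unique solution with coefficients
  exact to machine precision: `a10 = a01 = 1`, `a11 = −1/U`, all else 0.

## 3. Special-case reductions

* **Noisy-OR/AND (binary, `L=0, U=1`).** Verified *exactly* (tolerance
  1e-12, observed 0.0) over exhaustive binary assignments up to 2^10, by
  evaluating both forms with a shared sorted-factor product (§5).
* **Linear limit.** For fixed strengths the gap to `Σ w_i g_i − Σ w_j r_j`
  is evaluated along the bound sequence (10, 100, 1000, 10000); the report
  requires monotone decrease and fits the rate constant
  `C = max(gap·min(U,L))`, confirming `gap ≤ C/min(U,L)`. For two
  generators the gap is the closed form `xy/U` exactly.
* **Noisy addition.** Binary generators with growing `U`: converges to
  `Σ w_i δ_i`; single causes are exact at any bound (no cross terms).
* **Blocked linear limit.** With blockers held fixed the limit is
  `Π(1 − w_k b_k) · [Σ w_i g_i − Σ w_j r_j]`; a sure blocker gives exactly 0
  at every bound.

## 4. Simulation and estimation

The model pins down only the conditional expectation, so simulation requires
an observation-noise family with support matching the effect range:

* `bernoulli` — requires `L=0, U=1`; the expectation is the event
  probability, no free dispersion;
* `scaled-beta` — finite ranges; a Beta law parameterized by mean and
  precision ν (default 20), affinely mapped onto `[-L, U]`. Means exactly on
  a support endpoint are clamped 1e-9 into the interior, since Beta
  parameters must be positive; this biases endpoint means by < 1e-9.
* `gaussian` — infinite-bound (linear) models; dispersion is the sd.

Defaults: designs activate each cause independently with `p_active = 0.5`
(binary design puts active causes at `M`; uniform design draws values
uniformly on `(0, M]`). All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bit-identical tables,
and `recovery_experiment` spawns per-replicate seeds from a `SeedSequence`
reduced mod 2³¹.

Estimation maximizes the Bernoulli likelihood (binary data) or minimizes
squared error (continuous data) over box-constrained strengths
(`0 ≤ w ≤ bound/M`) with L-BFGS-B, `ftol = 1e-15`, `gtol = 1e-10`, and 5
seeded starts (the objective can be multimodal with correlated causes).
Gradients are analytic leave-one-out products of the mean structure — this,
not optimizer luck, is what makes the ML fit match the closed-form causal
power estimator to ~1e-10 on single-cause data. A cause whose value column
is constant across trials is flagged unidentifiable rather than silently
fit. Fitting requires ≥ 10 trials per strength.

Judgment statistics for 2×2 contingency data: ΔP = P(e|c) − P(e|¬c) (the
linear reasoner's statistic) and causal power = ΔP/(1 − P(e|¬c)) (the
noisy-OR strength); they coincide exactly iff the background rate is 0.
Degenerate tables (no cause-absent trials; background rate 1; negative ΔP
for the generative power) raise `EstimationError` rather than returning NaN.

`generate_value_sequences` produces matched stimuli across three
value-range regimes — binary (exact 0/1), narrow-continuous (tight jitter
around 0 and 1), wide-continuous (high level 17.32, wider jitter) — drawing
the low/high pattern *before* the jitter so the same seed yields the same
functional pattern in every regime; thresholding at half the functional gap
recovers it exactly.

## 5. Numerical decisions

* **Sorted-factor products.** Floating multiplication is commutative but
  not associative, so every product over causes is evaluated in ascending
  factor order. This makes expected effects bit-for-bit invariant under
  permutation of the cause list and makes the binary reduction exact, not
  just within tolerance.
* **Bound slack.** Strength validation (`w·M ≤ bound`) allows 1e-12 slack
  because products of validated factors can land a few ulp past the
  analytic bound.
* **Report precision.** JSON reports round floats to 12 significant digits
  — enough to reproduce every quantitative claim, stable across platforms.
  Trial CSVs are *not* rounded (pandas full-precision repr) so
  write-then-read is lossless; the two formats serve different purposes and
  the asymmetry is deliberate.
* **Infinities in files.** Model files encode infinite bounds as the string
  `"inf"`, keeping the JSON strict and the YAML portable.

## 6. What the simulator does and does not emulate

It emulates: trial-by-trial data generation from the capacity model under
the three noise families, classic elemental-causation designs (single cause
plus background via `always_on`), value-range manipulations, and
simulate-and-refit parameter-recovery studies.

It does not emulate: human judgment noise or response processes (predicted
judgments are point predictions of the relevant statistic), cause-specific
preventers (§1), temporally extended or cyclic causal structures, or
inference over model structure (roles and the cause list are fixed inputs;
only strengths are estimated).
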