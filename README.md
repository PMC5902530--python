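# causalform

Bounded-effect causal capacity models: a single functional form that unifies
the classic noisy-OR/AND model of binary causation and the linear (additive)
model of continuous causation, together with tools to check *why* that form
is special, to verify its special-case reductions numerically, and to
simulate and estimate causal strengths from trial data.

## The scientific problem

People judge the strength of a cause as the expected change it produces in an
effect, and they combine multiple causes as if each were an independent
**capacity**. Two formal models dominate the literature:

* the **noisy-OR/AND** model — binary effects, each generative cause fires
  the effect independently with its own probability, preventers veto it;
* the **linear model** — continuous effects, causes add up.

These look incompatible, but both are special cases of one form. Let the
effect live in an interval `[-L, U]` around a baseline of 0 (`L`, `U` are
nonnegative magnitudes, possibly infinite). Causes come in three roles —
**generators** push the effect up toward `U`, **reducers** push it down
toward `-L`, and **blockers** probabilistically veto all other influences.
The expected effect under a joint assignment is

```
E(E) = Π_k (1 − w_k b_k) · [ U(1 − Π_i (U − w_i g_i)/U) − L(1 − Π_j (L − w_j r_j)/L) ]
```

where `w` are causal strengths and `g, r, b ∈ [0, M]` are cause values. With
`L = 0, U = 1` and binary causes this **is** the noisy-OR/AND model, exactly;
as both bounds grow it converges to the linear model at rate `1/min(U, L)`.

The two-cause accumulation kernel behind the form, `f(x, y) = x + y − xy/U`,
is not an arbitrary choice: it is the *only* polynomial function on `[0, U]`
that is symmetric, associative, leaves single causes unchanged
(`f(x, 0) = x`), produces no uncaused effects (`f(0, 0) = 0`), saturates at
the bound (`f(U, U) = U`), and accumulates smoothly. This package includes an
axiom-checking engine and a numerical uniqueness solver that demonstrate both
halves of that claim: the privileged form passes every axiom, the familiar
alternatives (MAX, unclipped addition, averaging) each fail a specific one,
and within any capped polynomial degree the axioms pin down a single
coefficient vector.

## Worked example

A crop-yield effect bounded in `[-2, 3]` around a baseline of 0, with two
generators, one reducer and one blocker:

```python
from causalform import (CapacityModel, Cause, EffectRange, NoiseSpec,
                        binary_design, expected_effect, fit_weights,
                        simulate_trials, solve_unique_polynomial)

m = CapacityModel(
    EffectRange(lower=2.0, upper=3.0),
    [Cause("fertilizer", "generator", strength=1.2, max_value=2.0),
     Cause("compost",    "generator", strength=0.5, max_value=1.0),
     Cause("drought",    "reducer",   strength=0.8, max_value=1.5),
     Cause("frost",      "blocker",   strength=0.4, max_value=1.0)],
)

a = {"fertilizer": 1.0, "compost": 1.0, "drought": 0.5, "frost": 1.0}
expected_effect(m, a)                      # 0.66
expected_effect(m, {**a, "frost": 0.0})    # 1.1  (frost gates 40% of it away)
expected_effect(m, {k: 0.0 for k in a})    # 0.0  (exact baseline, always)
```

Simulate trials and recover the strengths:

```python
t = simulate_trials(m, NoiseSpec("scaled-beta", 40), binary_design(0.5),
                    n=20_000, seed=7)
fit = fit_weights(t, m.with_strengths({k: 0.0 for k in m.labels}),
                  NoiseSpec("scaled-beta", 40))
fit.strengths
# {'fertilizer': 1.2009, 'compost': 0.5002, 'drought': 0.8020, 'frost': 0.3987}
```

Confirm the uniqueness of the accumulation function at `U = 2` among all
polynomials of degree ≤ 3:

```python
sol = solve_unique_polynomial(degree_cap=3, U=2.0, seed=0)
sol.unique          # True
sol.coefficients    # a10 = a01 = 1.0, a11 = -0.5 (= -1/U); all others 0
```

## Command line

```bash
causalform evaluate --model model.yaml --assignments assignments.csv
causalform simulate --model model.yaml --noise bernoulli --n 20000 --seed 7 --out trials.csv
causalform fit --model-skeleton model.yaml --data trials.csv --noise bernoulli --out fit.json
causalform check-axioms --function "x + y - x*y" -U 1
causalform check-axioms --function max            # fails smooth accumulation
causalform verify-reductions --case all --seed 1 --json-out reductions.json
```

Model files are YAML or JSON:

```yaml
effect_range: {lower: 0, upper: 1}
causes:
  - {label: a, role: generator, strength: 0.5}
  - {label: b, role: blocker,   strength: 0.3}
```

Use the string `"inf"` for infinite bounds or max values. All numeric JSON
report output uses 12 significant digits; trial CSVs are written at full
precision so round trips are lossless.

## Layout

* `src/causalform/model.py` — ranges, causes, models, the expected-effect form
* `src/causalform/axioms.py` — axiom suite and polynomial uniqueness solver
* `src/causalform/special_cases.py` — numerical reduction verifiers
* `src/causalform/simulate.py` — noise families, designs, estimation, ΔP/power
* `src/causalform/io.py`, `cli.py` — file formats and the `causalform` CLI
* `docs/methods.md` — modeling assumptions and numerical methods in detail
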