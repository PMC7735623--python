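# Methods

## The model

A choice among N lotteries is represented as a single Brownian particle with
diffusion coefficient `D` on a star graph with one absorbing branch per
outcome–probability pair across all offered lotteries.  Branch `i` has
length `ℓ_i = 1/p_i` and constant drift `u_i = u(o_i)` directed toward its
absorbing end.  The probability of choosing a lottery is the probability
that the particle is absorbed on one of that lottery's branches.

Solving the stationary splitting problem (a harmonic function of the
generator on each branch, continuous at the junction, with zero net flux)
gives branch absorption odds proportional to the effective utility

    Ũ_p(o) = u / (1 − e^{−2u/(pD)}),      Ũ_p(0) = pD/2,

strictly positive for every real `u`, and the Luce rule
`P(L_j) = U(L_j)/Σ_i U(L_i)` with `U(L) = Σ Ũ`.  Two sign/argument
conventions for the exponential are conceivable (`2u/(pD)` versus
`2up/D`); we fix the former because it alone satisfies, simultaneously:
the `p → 0` limit `Ũ_p(o) → u(o)`, the `D → ∞` limit `π(p) → p` of the
subjective probability, the loss-side suppression `|u| e^{−2|u|/(pD)}`, and
the transformed-utility form with `D_p = pD/2`.  A dedicated unit test pins
this convention by asserting the algebraic identity between the direct
CARA-transformed utility and the log-space route to 1e−10.

Conditioning on a decision before a time budget `T` is implemented by
evaluating the Laplace transform of the absorption current at `s = 1/T`:

    Ũ_p(o|T) = λ e^{u/(pD)} / sinh(λ/p),   λ = √((u/D)² + 2/(DT)).

This is an *approximation* to the exact conditional probability (the
integral of the current to T), not an identity; against the lattice
simulation of the printed low/high-risk pair at `D = 10` the approximation
is accurate to about ±0.012 across the reversal region, and the test suite
enforces a documented 0.03 tolerance.  `T = ∞` is an explicit sentinel that
delegates to the untimed closed form plus the constant `ln(2/D)`; timed and
untimed weights carry different native normalizations and are never mixed
within one distribution (the constant cancels in Luce ratios).

### Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `D` | diffusion coefficient; attention to probabilities vs values | utility²/time | 10 |
| `T` | deliberation-time budget | time | ∞ |
| `r` | CARA coefficient of `u(o) = (1−e^{−ro})/r` | 1/currency | 0 (linear) |
| `outcome_scale` | global outcome rescaling applied before `u` | 1/currency | 1 |

Only ratios are identified: `(outcomes, r, D) → (k·outcomes, r/k, k·D)`
leaves every choice probability unchanged (CARA utilities scale exactly
linearly under this map).  `outcome_scale` is therefore never a free
parameter in fitting, and `T` is only fit when the design varies time
pressure — from static choices alone it is weakly identified.

## Numerical choices

* All weights are computed as logarithms.  Gains use
  `ln u − log1p(−e^{−x})`; losses use `ln|u| − |x| − log1p(−e^{−|x|})`;
  `|x| = |2u/(pD)| < 1e−8` switches to the series
  `(pD/2)(1 + x/2 + x²/12)` around the removable singularity at `u = 0`.
  `ln sinh x` uses the asymptote `x − ln 2` beyond `x = 30`.  Aggregation is
  log-sum-exp throughout; normalization is exact to 1e−12.
* Deeply saturated CARA losses are capped at the largest representable
  exponent so that log-weights stay finite; they are astronomically
  suppressed either way.
* Zero-probability branches are removed at construction (the theory's
  `p = 0` "no branch", distinct from the singular `p → 0` limit of a
  present branch).  Duplicate outcomes are kept as separate branches: the
  representation is branch-based and merging them changes predictions.
* `D·T` underflow (unrepresentable timed weights) raises a
  degenerate-distribution error rather than propagating NaN.
* The inflection point `o*` of the transformed utility is located by a
  curvature scan plus Brent root-finding on a central second difference
  (tolerance 1e−8); `p*` is closed-form.

## The lattice oracle

The simulator realizes the same process on a lattice of spacing `h` with
time step `τ = h²/D` (variance per unit time `D`, drift `u + O(h)`):
branch `i` has `N_i = round(ℓ_i/h)` sites and outward step probability
`q_i = ½(1 + u_i h/D)`; a walker at the hub picks a branch uniformly and
steps out with probability `q_i`, otherwise stays.  A renewal/gambler's-ruin
argument gives *exact* lattice absorption odds
`(u_i h/D)/(1 − r_i^{N_i})`, `r_i = (1−q_i)/q_i`, which converge to
the continuum effective utilities as `h → 0`; the package exposes this
closed form (`discrete_splitting`) so tests can separate Monte Carlo noise
(binomial, 3·SE at 1e5 walkers) from discretization bias (the exact
discrete–continuum gap, evaluated at the *realized* branch lengths
`N_i h`).  The walker loop is a serial numba kernel seeded per run and
bit-reproducible.  The oracle-agreement study uses 20 random star instances
(2–5 branches, drifts in [−20, 20], branch probabilities in [0.05, 0.9],
`D` log-uniform in [1, 100]) with `h ≤ 0.1·D/max|u|` capped at 600 sites
per branch; it runs in roughly two minutes.

## What the synthetic data emulate — and what they do not

`generate_random_lotteries` draws outcomes uniformly and probabilities from
a flat simplex: it emulates the *structure* of laboratory gamble sets
(small finite outcome menus, known probabilities), not their empirical
distribution; there are no framing, order, or learning effects, and every
trial is an independent draw from the model itself.  Passing recovery tests
therefore show that the estimation machinery is consistent and calibrated
under the model, not that the model fits human data.  Fitting to real
datasets (and model comparison against other theories via cross-validation,
Vuong tests, or information criteria) is an explicit hook left open.

The recovery study conditions were chosen for identifiability: truth
`r = 1, D = 10`, 50 two-lottery sets with 2–3 branches and outcomes in
[−3, 6] (stakes of order the CARA scale, mixing mild losses and gains so
that choice probabilities spread over ≈[0.35, 0.65] without saturating),
200 trials per set; 6 replications with 24-resample percentile bootstraps,
plus a single-free-parameter fit of `D` at 400 trials per set.  All-gain
designs with stakes far below `D` are nearly uninformative (all
probabilities ≈ 0.5), and heavy mixed-sign designs saturate at 0/1; both
pathologies are why the optimizer works in log-parameter space from a
Latin-hypercube multi-start.

## Experiment regimes and design choices

* **Fourfold pattern.**  Stakes of 100 currency units are rescaled by
  `outcome_scale = 1/100`; without rescaling the CARA exponential saturates
  and every regime collapses.  The scanned CARA coefficient matters: with
  `D = 10`, `T = 2000`, all four cells of the classic 2×2 table hold for
  `r ≳ 4.8`, and the bundled preset documents `r = 5`.  At lower `r` the
  loss/high-probability cell fails because the sure-loss and risky-loss
  suppressions compete; the same competition makes loss-side risk seeking
  non-monotone in `r` at intermediate values, so the package asserts the
  endpoint trend only.  Risk-attitude labels always derive from the choice
  probability versus 0.5.
* **Weighting shapes.**  Classification uses the sign-change sequence of
  `π(p|T) − p` on a ≥500-point grid with a 1e−9 dead band: inverse-S
  (over→under), S (under→over), double-inverse-S (three crossings).  With
  `u(o_A) = u(o_B) = D = 10` the sequence inverse-S → double-inverse-S → S
  appears as `T` decreases through ≈0.3.
* **Response times.**  The inverse relation between choice probability and
  conditional mean decision time is a prediction for *value-driven*
  preference differences; the default ensemble matches branch probabilities
  within each pair (rank correlation ≈ −0.9 in simulation).  When
  probability differences are geometry-driven (one lottery probable because
  its branches are short) the relation can invert — a genuine boundary of
  the claim.  Neither algebraic reading of the printed mean-time relation
  (`E[T|choose]` as `E[T]·P` or `E[T]/P`) is an identity of the process;
  both are evaluated and reported, and neither sums to `E[T]` under the
  law of total expectation unless `P = 1/2`.

## Known limitations and one red check

* The Laplace-domain timed weights are an approximation (above); exact
  finite-time conditionals would require the full eigenfunction expansion,
  which is out of scope — the lattice simulator covers that ground
  empirically.
* The model is Luce-structured by construction: it cannot produce
  similarity, attraction, or compromise effects, and choices between two
  sure outcomes are excluded from the domain.
* **Strong risk aversion (deliberately red).**  For the printed
  mean-preserving-spread pair `L5 = {0, 0.75; 2, 0.25}` vs
  `L6 = {0, 0.5; 1, 0.5}` with CARA `r = 1`, the claimed inequality
  `P(L6) ≥ P(L5)` for `D ≥ 1` is *structurally impossible* under the
  model's own closed forms: as `D → 0` the lottery worth tends to the raw
  utility sum and `u(2) > u(1)` for any increasing utility, while as
  `D → ∞`, `U(L6) − U(L5) → (u(1) − u(2))/2 < 0`; numerically `P(L6)`
  rises monotonically from 0.430 at `D = 1` toward 0.5 from below.  The
  corresponding test asserts the claimed inequality and is deliberately
  left failing, with `strong_risk_aversion_check` reporting the honest
  verdict at run time.
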