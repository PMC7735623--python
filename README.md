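# srdt — stochastic representation decision theory

`srdt` models human choice between risky lotteries as the first-passage
problem of a drifting Brownian particle on a **star graph**.  Each lottery
outcome–probability pair `(o, p)` becomes one absorbing branch: the branch
*length* is `1/p` (rare outcomes are far away) and the branch *drift* is the
outcome's utility `u(o)` (attractive for gains, repulsive for losses).  The
particle starts at the junction; the probability of being absorbed on one of
a lottery's branches is the probability of choosing that lottery.

Solving the splitting problem gives each branch the **effective utility**

    Ũ_p(o) = u(o) / (1 − exp(−2 u(o) / (p D)))

where `D` is the diffusion coefficient trading off attention to values
(small `D`) against attention to probabilities (large `D`).  Choice follows
Luce's ratio rule,

    P(L_j) = U(L_j) / Σ_i U(L_i),     U(L) = Σ_branches Ũ_p(o),

so probability and value are *entangled*: `Ũ_p(o)` is not a probability
weight times a utility.  Conditioning on deciding within a time budget `T`
(via the Laplace transform of the absorption current at `s = 1/T`) gives the
time-pressured weights

    Ũ_p(o|T) = λ e^{u/(pD)} / sinh(λ/p),   λ = √((u/D)² + 2/(DT)).

This minimal two-parameter model (plus a utility function, e.g. CARA
`u(o) = (1 − e^{−ro})/r`) reproduces a remarkable set of behavioural
regularities: the fourfold pattern of risk attitudes, inverse-S and
double-inverse-S probability weighting, violations of stochastic dominance
for the classic three-outcome trap (and observance when dominance is
evident), and preference reversal under time pressure.

The package is aimed at computational cognitive scientists and decision
theorists who want to evaluate, simulate, or fit this family of models:

* `srdt.lotteries` — lottery/choice-set data model, JSON/CSV I/O, random
  generators for simulation studies;
* `srdt.core` — the closed forms, in overflow-safe log space;
* `srdt.simulate` — a seeded lattice random-walk Monte Carlo oracle
  (numba-compiled) that estimates the same splitting probabilities and
  decision times independently of the closed forms;
* `srdt.experiments` — scripted pipelines for the qualitative predictions;
* `srdt.inference` — maximum-likelihood fitting of `(r, D, T)` from
  trial-level choice data, with bootstrap intervals and recovery tests;
* a `srdt` command-line interface wrapping all of the above.

## Worked example

The printed time-pressure pair — a low-variance gamble against a
higher-mean, higher-variance one — with linear utility and `D = 10`:

```python
from srdt import (ChoiceSet, Lottery, SRDTParams, UtilitySpec,
                  choice_distribution)

pair = ChoiceSet([
    Lottery("safe",  [(180, 0.5), (20, 0.5)]),
    Lottery("risky", [(180, 0.5), (30, 0.25), (15, 0.25)]),
])
for T in (float("inf"), 1.0, 0.03):
    params = SRDTParams(utility=UtilitySpec(family="linear"), D=10.0, T=T)
    dist = choice_distribution(pair, params)
    print(f"T={T:>6}:  P(safe)={dist['safe']:.4f}  P(risky)={dist['risky']:.4f}")
```

```
T=   inf:  P(safe)=0.4706  P(risky)=0.5294
T=   1.0:  P(safe)=0.4757  P(risky)=0.5243
T=  0.03:  P(safe)=0.5033  P(risky)=0.4967
```

With unlimited deliberation the risky gamble is preferred (its expected
value is higher), but as the time budget shrinks the preference reverses:
the long low-probability branches of the risky lottery are the first
casualties of time pressure, and the decision maker turns risk-averse.
The derived probability-weighting function shows the same competition:

```python
from srdt.experiments import weighting_shape
shape, crossings, _ = weighting_shape(
    10.0, 10.0, SRDTParams(utility=UtilitySpec(family="linear"), D=10.0, T=0.3))
print(shape, [round(c, 3) for c in crossings])
```

```
double-inverse-S [0.137, 0.5, 0.863]
```

— extreme small probabilities are neglected, moderate small probabilities
overweighted, symmetric on the other end: the composite weighting shape
that descriptive theories usually have to postulate.

From the shell, the stochastic-dominance suite prints its verdicts directly:

```bash
$ srdt dominance
{
 "birnbaum_violation_small_D": true,
 "birnbaum_P_L2_small_D": 0.61875,
 "evident_A_respected": true,
 "evident_B_respected": true
}
```

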