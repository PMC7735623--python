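"""Closed-form SRDT mathematics in overflow-safe log space.

The model represents a choice among lotteries as a drifting Brownian particle
on a star graph: one absorbing branch per (outcome, probability) pair, branch
length 1/p, constant drift u(o) toward the absorbing end, diffusion
coefficient D.  Solving the splitting problem (harmonic function with flux
conservation at the junction) gives each branch the *effective utility*

    Ũ_p(o) = u(o) / (1 - exp(-2 u(o) / (p D))),

a strictly positive weight for any real u, with the removable singularity
Ũ_p(0) = p D / 2.  A lottery's worth is the sum of its branch weights and
choice probabilities follow the Luce ratio rule

    P(L_j) = U(L_j) / sum_i U(L_i).

Conditioning on deciding before a time budget T is approximated by the
Laplace transform of the absorption current evaluated at s = 1/T, giving

    Ũ_p(o|T) = λ exp(u/(p D)) / sinh(λ/p),   λ = sqrt((u/D)^2 + 2/(D T)),

which recovers (2/D) Ũ_p(o) as T -> infinity and vanishes as p -> 0 for any
finite T (the finite budget removes the singular p -> 0 overweighting of the
infinite-time theory).

All aggregation is done on log weights with log-sum-exp; timed and untimed
weights each keep their native normalization and are never mixed inside one
distribution (the constant factor cancels in Luce ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .lotteries import ChoiceSet, Lottery
from .utility import UtilitySpec, utility

__all__ = [
    "SRDTParams",
    "BranchWeight",
    "ChoiceDistribution",
    "DegenerateDistributionError",
    "log_effective_utility",
    "log_effective_utility_timed",
    "lottery_log_weight",
    "choice_distribution",
    "subjective_probability",
    "limit_choice_probabilities",
    "transformed_utility",
    "inflection_points",
]

#: |2u/(pD)| below this switches to the series around the u = 0 singularity
_SERIES_SWITCH = 1e-8
#: ln sinh(x) uses the asymptotic x - ln 2 beyond this
_LOG_SINH_ASYMPT = 30.0


class DegenerateDistributionError(ValueError):
    """Every branch weight vanished (all branches suppressed by finite T)."""


@dataclass(frozen=True)
class SRDTParams:
    """Full parameterization of the theory: utility spec, D > 0, T > 0.

    ``T = math.inf`` (the default) selects the infinite-deliberation-time
    closed forms; any finite T selects the Laplace-domain weights.
    """

    utility: UtilitySpec = UtilitySpec()
    D: float = 10.0
    T: float = math.inf

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError("diffusion coefficient D must be positive")
        if not self.T > 0:
            raise ValueError("time budget T must be positive (or math.inf)")

    @property
    def timed(self) -> bool:
        return math.isfinite(self.T)


@dataclass(frozen=True)
class BranchWeight:
    """Log-domain effective utility of one lottery branch."""

    outcome: float
    probability: float
    log_weight: float


@dataclass(frozen=True)
class ChoiceDistribution:
    """Per-lottery Luce probabilities plus per-branch conditional weights."""

    ids: tuple[str, ...]
    probabilities: np.ndarray
    branch_weights: tuple[tuple[BranchWeight, ...], ...]
    conditional: tuple[np.ndarray, ...]
    params: SRDTParams

    def __getitem__(self, lottery_id: str) -> float:
        return float(self.probabilities[self.ids.index(lottery_id)])


# ---------------------------------------------------------------------------
# effective utilities
# ---------------------------------------------------------------------------

def log_effective_utility(u_val, p, D: float):
    """ln Ũ_p(o) = ln[ u / (1 - e^{-2u/(pD)}) ] for p in (0, 1], D > 0.

    Computed piecewise so it is finite and accurate for any real u:
    gains use ln u - log1p(-e^{-x}); losses use ln|u| - |x| - log1p(-e^{-|x|});
    |x| < 1e-8 uses the series (pD/2)(1 + x/2 + x^2/12).
    """
    u = np.asarray(u_val, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError(
            "p = 0 has no branch: drop zero-probability branches instead of "
            "evaluating the p -> 0 limit"
        )
    if np.any(p > 1.0 + 1e-12):
        raise ValueError("branch probability must lie in (0, 1]")
    if not D > 0:
        raise ValueError("D must be positive")
    u, p = np.broadcast_arrays(u, p)
    x = 2.0 * u / (p * D)
    out = np.empty_like(x)

    small = np.abs(x) < _SERIES_SWITCH
    pos = (~small) & (x > 0)
    neg = (~small) & (x < 0)
    if np.any(small):
        xs = x[small]
        out[small] = np.log(p[small] * D / 2.0) + np.log1p(
            xs / 2.0 + xs * xs / 12.0
        )
    if np.any(pos):
        out[pos] = np.log(u[pos]) - np.log1p(-np.exp(-x[pos]))
    if np.any(neg):
        ax = -x[neg]
        out[neg] = np.log(-u[neg]) - ax - np.log1p(-np.exp(-ax))
    if out.ndim == 0:
        return float(out)
    return out


def _log_sinh(x: np.ndarray) -> np.ndarray:
    """ln sinh(x) for x > 0, asymptotic x - ln 2 past x = 30."""
    x = np.asarray(x, dtype=float)
    big = x > _LOG_SINH_ASYMPT
    out = np.empty_like(x)
    out[big] = x[big] - math.log(2.0)
    xs = x[~big]
    with np.errstate(divide="ignore"):
        out[~big] = np.log(np.sinh(xs))
    return out


def log_effective_utility_timed(u_val, p, D: float, T: float):
    """ln Ũ_p(o|T) = ln λ + u/(pD) - ln sinh(λ/p), λ = sqrt((u/D)^2 + 2/(DT)).

    ``T = inf`` delegates to the untimed form plus the constant ln(2/D).
    The result may be very negative (effectively -inf) for p -> 0 with finite
    T; that is the physical suppression of never-reached branches.
    """
    if not D > 0:
        raise ValueError("D must be positive")
    if not T > 0:
        raise ValueError("T must be positive")
    if math.isinf(T):
        base = log_effective_utility(u_val, p, D)
        return base + math.log(2.0 / D)
    u = np.asarray(u_val, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError("p = 0 has no branch")
    u, p = np.broadcast_arrays(u, p)
    if D * T == 0.0 or not np.all(np.isfinite(np.abs(u) / D)):
        raise DegenerateDistributionError(
            f"D*T={D * T} underflows; the timed weights are not representable"
        )
    lam = np.sqrt((u / D) ** 2 + 2.0 / (D * T))
    out = np.log(lam) + u / (p * D) - _log_sinh(lam / p)
    if out.ndim == 0:
        return float(out)
    return out


def _branch_log_weight(u: np.ndarray, p: np.ndarray, params: SRDTParams):
    if params.timed:
        return log_effective_utility_timed(u, p, params.D, params.T)
    return log_effective_utility(u, p, params.D)


def lottery_log_weight(L: Lottery, params: SRDTParams):
    """ln U(L): log-sum-exp of branch log weights.

    Returns ``(log_total, branch_logs)`` so callers can form the per-branch
    conditional weights without recomputation.
    """
    u = utility(params.utility, L.outcomes)
    logs = np.atleast_1d(_branch_log_weight(np.atleast_1d(u), L.probabilities, params))
    return float(logsumexp(logs)), logs


# ---------------------------------------------------------------------------
# choice probabilities
# ---------------------------------------------------------------------------

def choice_distribution(cs: ChoiceSet, params: SRDTParams) -> ChoiceDistribution:
    """Luce choice probabilities P(L_j) = U(L_j) / sum_i U(L_i).

    Computed entirely in log space; the returned probabilities sum to one to
    1e-12 and the ratio P(L_i)/P(L_j) does not depend on the other lotteries
    in the set (independence from irrelevant alternatives is structural).
    """
    totals = []
    branch_logs = []
    for L in cs.lotteries:
        tot, logs = lottery_log_weight(L, params)
        totals.append(tot)
        branch_logs.append(logs)
    totals = np.asarray(totals)
    if np.all(np.isneginf(totals)) or np.any(np.isnan(totals)):
        raise DegenerateDistributionError(
            "branch weights vanished or overflowed (probabilities too small "
            f"for the time budget T={params.T}, or D*T underflow)"
        )
    probs = np.exp(totals - logsumexp(totals))
    probs /= probs.sum()
    weights = tuple(
        tuple(
            BranchWeight(b.outcome, b.probability, float(lw))
            for b, lw in zip(L.branches, logs)
        )
        for L, logs in zip(cs.lotteries, branch_logs)
    )
    conditional = tuple(
        np.exp(logs - logsumexp(logs)) if np.isfinite(tot) else np.full(len(logs), np.nan)
        for logs, tot in zip(branch_logs, totals)
    )
    return ChoiceDistribution(
        ids=tuple(cs.ids),
        probabilities=probs,
        branch_weights=weights,
        conditional=conditional,
        params=params,
    )


def subjective_probability(p: float, oA: float, oB: float, params: SRDTParams) -> float:
    """π(p): conditional absorption weight of the p-branch within its lottery.

    For the two-branch lottery {oA, p; oB, 1-p},
    π(p) = Ũ_p(u(oA)) / (Ũ_p(u(oA)) + Ũ_{1-p}(u(oB))), with the timed weights
    substituted when T is finite.  This is the theory's derived analogue of a
    probability weighting function: π -> p as D -> infinity and π -> a pure
    value ratio as D -> 0 (for gains).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    uA = utility(params.utility, oA)
    uB = utility(params.utility, oB)
    la = _branch_log_weight(np.asarray(uA), np.asarray(p), params)
    lb = _branch_log_weight(np.asarray(uB), np.asarray(1.0 - p), params)
    # sigmoid of the log-weight difference, stable in both tails
    d = float(lb) - float(la)
    if math.isnan(d):
        raise DegenerateDistributionError(
            "both branch weights vanished under the finite time budget"
        )
    if d >= 0:
        return 1.0 / (1.0 + math.exp(min(d, 700.0)))
    return 1.0 - 1.0 / (1.0 + math.exp(min(-d, 700.0)))


def limit_choice_probabilities(
    cs: ChoiceSet, params: SRDTParams, which: str
) -> ChoiceDistribution:
    """Closed-form D -> 0 / D -> infinity limits, no extreme exponentials.

    D -> infinity: every branch weight tends to p_i D/2, so each complete
    lottery carries total weight D/2 and the distribution is uniform.

    D -> 0: gain branches contribute u(o); loss branches are exponentially
    suppressed with rate 2|u|/p, so they survive only when no gain branch
    exists anywhere, in which case mass concentrates on the slowest-decaying
    branches (largest -|u|/p exponent), split by their |u| prefactors.
    """
    if which not in ("D_to_0", "D_to_inf"):
        raise ValueError("which must be 'D_to_0' or 'D_to_inf'")
    n = len(cs)
    if which == "D_to_inf":
        probs = np.full(n, 1.0 / n)
    else:
        u_per = [utility(params.utility, L.outcomes) for L in cs.lotteries]
        p_per = [L.probabilities for L in cs.lotteries]
        any_gain = any(np.any(np.atleast_1d(u) > 0) for u in u_per)
        weights = np.zeros(n)
        if any_gain:
            for j, u in enumerate(u_per):
                u = np.atleast_1d(u)
                weights[j] = float(np.sum(u[u > 0]))
        else:
            # all-loss sets: rate of exponential decay per branch is 2|u|/p
            rates = [
                -2.0 * np.abs(np.atleast_1d(u)) / np.atleast_1d(p)
                for u, p in zip(u_per, p_per)
            ]
            best = max(float(np.max(r)) for r in rates)
            for j, (u, r) in enumerate(zip(u_per, rates)):
                u = np.atleast_1d(u)
                sel = np.isclose(r, best, rtol=1e-12, atol=1e-12)
                weights[j] = float(np.sum(np.abs(u[sel])))
        if weights.sum() <= 0:
            raise DegenerateDistributionError("no branch survives the D -> 0 limit")
        probs = weights / weights.sum()
    empty = tuple(() for _ in range(n))
    cond = tuple(np.array([]) for _ in range(n))
    return ChoiceDistribution(
        ids=tuple(cs.ids),
        probabilities=probs,
        branch_weights=empty,
        conditional=cond,
        params=params,
    )


# ---------------------------------------------------------------------------
# probability-distorted utility
# ---------------------------------------------------------------------------

def transformed_utility(o, p: float, r: float, D: float):
    """Effective utility of a CARA decision maker as a function of outcome.

    Direct evaluation of Ũ_p(o) = u / (1 - exp(-u/D_p)) with
    u = (1 - e^{-r o})/r and D_p = p D / 2.  This is an independent algebraic
    route to ``exp(log_effective_utility(u_cara(o), p, D))``; the identity of
    the two paths pins the exponent convention and is enforced by a unit test.
    """
    if not (0.0 < p <= 1.0) or not D > 0 or not r > 0:
        raise ValueError("need p in (0,1], r > 0, D > 0")
    o = np.asarray(o, dtype=float)
    Dp = p * D / 2.0
    u = -np.expm1(np.minimum(-r * o, 700.0)) / r
    z = u / Dp
    out = np.empty_like(u)
    small = np.abs(z) < _SERIES_SWITCH
    pos = (~small) & (z > 0)
    neg = (~small) & (z < 0)
    out[small] = Dp * (1.0 + z[small] / 2.0 + z[small] ** 2 / 12.0)
    out[pos] = u[pos] / (-np.expm1(-z[pos]))
    # losses: u/(1 - e^{|z|}) = |u| e^{-|z|} / (1 - e^{-|z|}), underflow-safe
    az = -z[neg]
    out[neg] = -u[neg] * np.exp(-az) / (-np.expm1(-az))
    if out.ndim == 0:
        return float(out)
    return out


def inflection_points(
    oA: float,
    oB: float,
    r: float,
    D: float,
    p: float = 1.0,
    bracket: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """(p*, o*): where the subjective probability and the transformed utility
    change curvature.

    p* = u(oA) / (u(oA) + u(oB)) is the closed-form crossing of π(p) with the
    diagonal (requires both utilities positive).  o* is the root of the second
    derivative (in o) of the transformed CARA utility with D_p = p D / 2,
    located by bracketed root finding on a central-difference estimate to a
    tolerance of 1e-8.
    """
    spec = UtilitySpec(family="cara", r=r)
    uA = utility(spec, oA)
    uB = utility(spec, oB)
    if uA <= 0 or uB <= 0:
        raise ValueError("p* requires u(oA) > 0 and u(oB) > 0")
    p_star = uA / (uA + uB)

    Dp = p * D / 2.0
    # curvature via central second difference; step tied to the CARA scale
    h = max(1e-4, 1e-4 / r)

    def curv(o: float) -> float:
        f = transformed_utility(np.array([o - h, o, o + h]), p, r, D)
        return float(f[0] - 2.0 * f[1] + f[2]) / h**2

    if bracket is None:
        # transformed utility is convex deep in the loss domain and concave
        # for large gains; scan outward from 0 for the curvature sign change
        lo = -5.0 / r * max(1.0, math.log1p(1.0 / Dp) + 1.0)
        hi = 5.0 / r
        bracket = (lo, hi)
    grid = np.linspace(bracket[0], bracket[1], 400)
    c = np.array([curv(g) for g in grid])
    sign = np.sign(c)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        raise ValueError(
            f"no curvature sign change in bracket {bracket}; "
            f"curvature range [{c.min():.3g}, {c.max():.3g}]"
        )
    i = idx[0]
    o_star = float(brentq(curv, grid[i], grid[i + 1], xtol=1e-8))
    return float(p_star), o_star
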