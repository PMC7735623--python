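"""Lattice random-walk realization of the star-graph diffusion (the oracle).

The continuum process — drifting Brownian motion on a star with one absorbing
branch per lottery outcome — is discretized on a lattice of spacing h with
time step τ = h²/D, so that the per-unit-time variance of the walk equals D
and the per-unit-time mean displacement equals the branch drift u + O(h).
Branch i carries N_i = round(ℓ_i/h) sites with ℓ_i = 1/p_i, an outward step
probability q_i = ½(1 + u_i h/D), and an absorbing wall at its last site.

Junction rule: a walker at the hub picks a branch uniformly at random and
takes the outward step with probability q_i (otherwise it stays at the hub);
interior sites step outward with q_i and inward with 1 - q_i.  A renewal
argument shows the absorption odds of branch i are proportional to
(u_i h/D)/(1 - e^{-2 u_i ℓ_i / D}) + O(h) ∝ Ũ_i uniformly over branches, so
the lattice walk estimates the same Luce weights as the closed forms.  This
is one consistent O(h) realization of the continuum junction flux matching,
not a unique construction.

The walker loop is a serial numba-compiled kernel seeded per run, which makes
results bit-identical for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import SRDTParams
from .lotteries import ChoiceSet
from .utility import utility

logger = logging.getLogger("srdt")

__all__ = [
    "StarGeometry",
    "WalkResult",
    "build_geometry",
    "discrete_splitting",
    "run",
    "splitting_estimates",
    "conditional_before",
    "conditional_mean_times",
]

#: step probabilities are clipped to (EPS, 1-EPS); strict mode rejects clipping
_CLIP_EPS = 1e-6


@dataclass(frozen=True)
class StarGeometry:
    """Discretized star: per-branch site counts, step probabilities, labels."""

    n_sites: np.ndarray        # N_i >= 2 per branch
    q_out: np.ndarray          # outward step probability per branch
    h: float                   # lattice spacing
    tau: float                 # physical time per step, h^2 / D
    drifts: np.ndarray         # continuum drift u_i per branch
    probabilities: np.ndarray  # requested branch probability p_i (l_i = 1/p_i)
    lottery_index: np.ndarray  # which lottery each branch belongs to
    lottery_ids: tuple[str, ...]
    branch_ids: tuple[str, ...]

    @property
    def n_branches(self) -> int:
        return len(self.n_sites)

    @property
    def effective_probabilities(self) -> np.ndarray:
        """Branch probabilities actually realized on the lattice, 1/(N_i h).

        Site counts are integers, so the realized branch lengths N_i h differ
        from 1/p_i by up to h/2; continuum formulas should be compared against
        these when validating the walk at finite h.
        """
        return 1.0 / (self.n_sites * self.h)


@dataclass(frozen=True)
class WalkResult:
    """Absorption outcomes of one simulation run."""

    geometry: StarGeometry
    absorbed_branch: np.ndarray  # -1 for walkers that hit max_steps
    steps: np.ndarray            # steps taken until absorption (or cutoff)
    n_walkers: int
    seed: int

    @property
    def counts(self) -> np.ndarray:
        """Per-branch absorption counts."""
        g = self.geometry
        mask = self.absorbed_branch >= 0
        return np.bincount(
            self.absorbed_branch[mask], minlength=g.n_branches
        ).astype(np.int64)

    @property
    def n_absorbed(self) -> int:
        return int(np.sum(self.absorbed_branch >= 0))


def _star_from_branches(
    u: np.ndarray,
    p: np.ndarray,
    D: float,
    h: float,
    lottery_index: np.ndarray,
    lottery_ids: tuple[str, ...],
    branch_ids: tuple[str, ...],
    strict: bool = False,
) -> StarGeometry:
    u = np.asarray(u, dtype=float)
    p = np.asarray(p, dtype=float)
    peclet = np.abs(u) * h / D
    if np.any(peclet >= 0.5):
        h_max = 0.45 * D / float(np.max(np.abs(u)))
        raise ValueError(
            f"spacing h={h} too coarse: max |u| h / D = {peclet.max():.3f} "
            f">= 0.5; use h <= {h_max:.3g}"
        )
    lengths = 1.0 / p
    n_sites = np.maximum(2, np.rint(lengths / h)).astype(np.int64)
    if np.any(lengths / h < 2):
        raise ValueError(
            f"spacing h={h} too coarse: shortest branch {lengths.min():.3g} "
            f"needs h <= {lengths.min() / 2:.3g} for >= 2 sites"
        )
    q = 0.5 * (1.0 + u * h / D)
    clipped = (q <= _CLIP_EPS) | (q >= 1.0 - _CLIP_EPS)
    if np.any(clipped):
        if strict:
            raise ValueError("geometry requires step-probability clipping")
        q = np.clip(q, _CLIP_EPS, 1.0 - _CLIP_EPS)
    return StarGeometry(
        n_sites=n_sites,
        q_out=q,
        h=float(h),
        tau=float(h * h / D),
        drifts=u,
        probabilities=p,
        lottery_index=np.asarray(lottery_index, dtype=np.int64),
        lottery_ids=lottery_ids,
        branch_ids=branch_ids,
    )


def discrete_splitting(geom: StarGeometry) -> np.ndarray:
    """Exact absorption probabilities of the lattice chain (renewal form).

    From the junction, branch i is entered with the outward step and absorbed
    before returning with the gambler's-ruin probability, giving odds
    q_i (1 - r_i) / (1 - r_i^{N_i}) with r_i = (1 - q_i)/q_i.  Since
    q_i (1 - r_i) = u_i h / D, the odds are the lattice analogue of the
    continuum effective utilities; this closed form pins the walk kernel to
    machine precision and quantifies the O(h) discretization bias when
    compared with the continuum weights.
    """
    q = geom.q_out
    N = geom.n_sites
    a = 2.0 * q - 1.0  # = u h / D after clipping
    odds = np.empty_like(a)
    drift = np.abs(a) >= 1e-12
    odds[~drift] = 0.5 / N[~drift]
    logr = np.log1p(-a[drift]) - np.log1p(a[drift])
    # 1 - r^N, stable for r near 1 (zero drift) via expm1
    odds[drift] = a[drift] / -np.expm1(N[drift] * logr)
    return odds / odds.sum()


def build_geometry(
    cs: ChoiceSet, params: SRDTParams, h: float, strict: bool = False
) -> StarGeometry:
    """Discretize the star representation of a choice set at spacing h.

    One branch per positive-probability outcome across all lotteries; branch
    drift equals the branch's utility (larger outcomes attract more), branch
    length is the reciprocal of its probability.
    """
    u, p, lidx, bids = [], [], [], []
    for j, L in enumerate(cs.lotteries):
        uv = np.atleast_1d(utility(params.utility, L.outcomes))
        for k, b in enumerate(L.branches):
            u.append(float(uv[k]))
            p.append(b.probability)
            lidx.append(j)
            bids.append(f"{L.id}[{k}]")
    return _star_from_branches(
        np.array(u), np.array(p), params.D, h,
        np.array(lidx), tuple(cs.ids), tuple(bids), strict=strict,
    )


@njit(cache=True)
def _walk_kernel(n_walkers, n_branches, n_sites, q_out, max_steps, seed):
    np.random.seed(seed)
    absorbed = np.full(n_walkers, -1, dtype=np.int64)
    steps = np.zeros(n_walkers, dtype=np.int64)
    for w in range(n_walkers):
        branch = -1
        site = 0
        t = 0
        while t < max_steps:
            t += 1
            if site == 0:
                b = np.random.randint(0, n_branches)
                if np.random.random() < q_out[b]:
                    branch = b
                    site = 1
                    if site == n_sites[b]:
                        absorbed[w] = b
                        break
            else:
                if np.random.random() < q_out[branch]:
                    site += 1
                    if site == n_sites[branch]:
                        absorbed[w] = branch
                        break
                else:
                    site -= 1
                    if site == 0:
                        branch = -1
        steps[w] = t
    return absorbed, steps


def run(
    geom: StarGeometry,
    n_walkers: int,
    seed: int,
    max_steps: int | None = None,
) -> WalkResult:
    """Release independent walkers at the junction and record absorptions.

    Walkers still alive after ``max_steps`` lattice steps are reported as
    unabsorbed; an unabsorbed fraction above 1% triggers a logged warning.
    """
    if n_walkers < 1:
        raise ValueError("need at least one walker")
    if max_steps is None:
        # a few hundred diffusive times of the longest branch
        max_steps = int(min(10_000_000, 400 * int(np.max(geom.n_sites)) ** 2))
    absorbed, steps = _walk_kernel(
        int(n_walkers),
        geom.n_branches,
        geom.n_sites,
        geom.q_out,
        int(max_steps),
        int(seed) & 0x7FFFFFFF,
    )
    frac_lost = float(np.mean(absorbed < 0))
    if frac_lost > 0.01:
        logger.warning(
            "star walk: %.1f%% of walkers unabsorbed after %d steps",
            100 * frac_lost, max_steps,
        )
    return WalkResult(
        geometry=geom,
        absorbed_branch=absorbed,
        steps=steps,
        n_walkers=int(n_walkers),
        seed=int(seed),
    )


def splitting_estimates(res: WalkResult):
    """Binomial point estimates ± SE of per-branch and per-lottery splitting.

    Returns ``(branch_p, branch_se, lottery_p, lottery_se)`` where the
    lottery-level estimates sum branch counts within each lottery.
    """
    n = res.n_absorbed
    if n == 0:
        raise ValueError("no walker was absorbed; cannot estimate splitting")
    counts = res.counts
    p_hat = counts / n
    se = np.sqrt(p_hat * (1.0 - p_hat) / n)
    g = res.geometry
    n_lot = len(g.lottery_ids)
    lot_counts = np.bincount(g.lottery_index, weights=counts, minlength=n_lot)
    lp = lot_counts / n
    lse = np.sqrt(lp * (1.0 - lp) / n)
    return p_hat, se, lp, lse


def conditional_before(res: WalkResult, T: float):
    """Per-lottery choice probabilities conditioned on absorption before T.

    T is physical time; a walker contributes when steps · τ <= T.  ``T = inf``
    reduces to the unconditional splitting estimates.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    g = res.geometry
    mask = res.absorbed_branch >= 0
    if math.isfinite(T):
        mask = mask & (res.steps * g.tau <= T)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no absorption occurred before T={T}")
    counts = np.bincount(res.absorbed_branch[mask], minlength=g.n_branches)
    n_lot = len(g.lottery_ids)
    lot_counts = np.bincount(g.lottery_index, weights=counts, minlength=n_lot)
    lp = lot_counts / n
    lse = np.sqrt(lp * (1.0 - lp) / n)
    return lp, lse


def conditional_mean_times(res: WalkResult):
    """Mean absorption time ± SE conditioned on the chosen lottery.

    Returns ``(mean_t, se_t, overall_mean)`` in physical time units (steps·τ).
    Lotteries with no absorptions get NaN entries.
    """
    g = res.geometry
    mask = res.absorbed_branch >= 0
    if not np.any(mask):
        raise ValueError("no walker was absorbed")
    times = res.steps[mask] * g.tau
    lots = g.lottery_index[res.absorbed_branch[mask]]
    n_lot = len(g.lottery_ids)
    mean_t = np.full(n_lot, np.nan)
    se_t = np.full(n_lot, np.nan)
    for j in range(n_lot):
        tj = times[lots == j]
        if len(tj):
            mean_t[j] = tj.mean()
            se_t[j] = tj.std(ddof=1) / math.sqrt(len(tj)) if len(tj) > 1 else np.nan
    return mean_t, se_t, float(times.mean())
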