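"""Likelihood-based estimation of SRDT parameters from trial-level choices.

The forward model is the Luce choice rule over effective utilities, so a
dataset of (choice set, chosen lottery) trials has log-likelihood
sum_t log P(chosen_t | set_t, theta) with theta a subset of {r, D, T}.
Optimization runs in log-parameter space (all three parameters are positive
scale parameters) with bounded L-BFGS-B from a seeded Latin-hypercube of
starting points.

Identifiability notes
---------------------
* outcome_scale is never free: jointly rescaling outcomes by k, r by 1/k and
  D by k leaves every choice probability unchanged (CARA utilities scale
  exactly linearly under this map), so only ratios like u/D are identified.
* T is weakly identified from static choices alone; it is fit only when the
  experimental design varies time pressure, and otherwise fixed at infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .core import SRDTParams, choice_distribution
from .lotteries import ChoiceSet
from .utility import UtilitySpec

__all__ = [
    "ChoiceDataset",
    "FitResult",
    "simulate_choices",
    "negative_log_likelihood",
    "fit",
]

_FREE_ORDER = ("r", "D", "T")


@dataclass(frozen=True)
class ChoiceDataset:
    """Trial-level binary/multinomial choice data.

    ``sets`` holds the distinct choice sets; ``set_index``/``chosen`` give,
    per trial, which set was offered and which lottery (by position) was
    chosen.  ``truth`` records generating parameters for synthetic data.
    """

    sets: tuple[ChoiceSet, ...]
    set_index: np.ndarray
    chosen: np.ndarray
    truth: SRDTParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.set_index) != len(self.chosen):
            raise ValueError("set_index and chosen must have equal length")
        if len(self.set_index) == 0:
            raise ValueError("dataset has no trials")
        for i, c in zip(self.set_index, self.chosen):
            if not (0 <= i < len(self.sets)):
                raise ValueError(f"trial references unknown set {i}")
            if not (0 <= c < len(self.sets[i])):
                raise ValueError(f"chosen index {c} invalid for set {i}")

    @property
    def n_trials(self) -> int:
        return len(self.chosen)

    def counts(self) -> list[np.ndarray]:
        """Per-set choice counts (sufficient statistics for the likelihood)."""
        out = []
        for i, cs in enumerate(self.sets):
            mask = self.set_index == i
            out.append(np.bincount(self.chosen[mask], minlength=len(cs)))
        return out


@dataclass(frozen=True)
class FitResult:
    """Point estimates with likelihood and convergence diagnostics."""

    params: SRDTParams
    free: tuple[str, ...]
    nll: float
    converged: bool
    n_starts: int
    start_nlls: tuple[float, ...]
    message: str
    bootstrap: dict | None = None

    @property
    def estimates(self) -> dict:
        return {
            name: getattr(self.params, name) if name != "r"
            else self.params.utility.r
            for name in self.free
        }


def simulate_choices(
    sets: list[ChoiceSet] | tuple[ChoiceSet, ...],
    params: SRDTParams,
    n_per_set: int,
    seed: int,
) -> ChoiceDataset:
    """Draw independent trials from each set's choice distribution."""
    if n_per_set < 1:
        raise ValueError("need at least one trial per set")
    rng = np.random.default_rng(seed)
    set_index, chosen = [], []
    for i, cs in enumerate(sets):
        probs = choice_distribution(cs, params).probabilities
        draws = rng.choice(len(cs), size=n_per_set, p=probs)
        set_index.extend([i] * n_per_set)
        chosen.extend(draws.tolist())
    return ChoiceDataset(
        sets=tuple(sets),
        set_index=np.asarray(set_index, dtype=np.int64),
        chosen=np.asarray(chosen, dtype=np.int64),
        truth=params,
        seed=seed,
    )


def negative_log_likelihood(data: ChoiceDataset, params: SRDTParams) -> float:
    """-sum_t log P(chosen_t); +inf when a chosen option has zero probability."""
    total = 0.0
    for cs, cnt in zip(data.sets, data.counts()):
        if cnt.sum() == 0:
            continue
        probs = choice_distribution(cs, params).probabilities
        sel = cnt > 0
        if np.any(probs[sel] <= 0.0):
            return math.inf
        total -= float(np.sum(cnt[sel] * np.log(probs[sel])))
    return total


def _apply_theta(base: SRDTParams, free: tuple[str, ...], log_theta) -> SRDTParams:
    vals = dict(zip(free, np.exp(np.asarray(log_theta, dtype=float))))
    params = base
    if "r" in vals:
        fam = "cara"
        params = replace(params, utility=replace(params.utility, family=fam, r=float(vals["r"])))
    if "D" in vals:
        params = replace(params, D=float(vals["D"]))
    if "T" in vals:
        params = replace(params, T=float(vals["T"]))
    return params


def fit(
    data: ChoiceDataset,
    free=("r", "D"),
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    base_params: SRDTParams | None = None,
    n_bootstrap: int = 0,
) -> FitResult:
    """Multi-start bounded maximum-likelihood estimation.

    Parameters
    ----------
    free:
        Subset of {"r", "D", "T"} to estimate; the rest are taken from
        ``base_params`` (default: CARA r=1, D=10, T=inf).
    bounds:
        Per-parameter (low, high) boxes on the natural scale; defaults to
        [1e-3, 1e3] for every free parameter.
    n_starts:
        Latin-hypercube starting points in log space.
    n_bootstrap:
        When positive, nonparametric bootstrap over trials with this many
        resamples; percentile 95% intervals are attached to the result.
    """
    free = tuple(p for p in _FREE_ORDER if p in free)
    if not free:
        raise ValueError("at least one free parameter is required")
    if base_params is None:
        base_params = SRDTParams(utility=UtilitySpec(family="cara", r=1.0), D=10.0)
    bounds = bounds or {}
    lo = np.log([bounds.get(p, (1e-3, 1e3))[0] for p in free])
    hi = np.log([bounds.get(p, (1e-3, 1e3))[1] for p in free])

    def objective(log_theta) -> float:
        try:
            nll = negative_log_likelihood(data, _apply_theta(base_params, free, log_theta))
        except (ValueError, FloatingPointError):
            return 1e15
        # a large finite penalty keeps numerical gradients well defined
        return min(nll, 1e15)

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)

    best = None
    start_nlls = []
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 500},
        )
        start_nlls.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"all {n_starts} starts failed to converge; start NLLs: {start_nlls}"
        )

    boot = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed + 1)
        n = data.n_trials
        samples = {p: [] for p in free}
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            bdata = ChoiceDataset(
                sets=data.sets,
                set_index=data.set_index[idx],
                chosen=data.chosen[idx],
            )

            def bobj(log_theta):
                try:
                    nll = negative_log_likelihood(
                        bdata, _apply_theta(base_params, free, log_theta)
                    )
                except (ValueError, FloatingPointError):
                    return 1e15
                return min(nll, 1e15)

            bres = minimize(
                bobj, best.x, method="L-BFGS-B",
                bounds=list(zip(lo, hi)), options={"maxiter": 200},
            )
            for p, v in zip(free, np.exp(bres.x)):
                samples[p].append(float(v))
        boot = {
            p: {
                "samples": np.asarray(v),
                "ci95": (
                    float(np.percentile(v, 2.5)),
                    float(np.percentile(v, 97.5)),
                ),
            }
            for p, v in samples.items()
        }

    return FitResult(
        params=_apply_theta(base_params, free, best.x),
        free=free,
        nll=float(best.fun),
        converged=bool(best.success),
        n_starts=n_starts,
        start_nlls=tuple(start_nlls),
        message=str(best.message),
        bootstrap=boot,
    )
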