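"""Lottery data model: validation, (de)serialization and synthetic generation.

A lottery is a finite set of (outcome, probability) branches.  The stochastic
representation attaches one absorbing branch of a star graph to every
positive-probability branch, so zero-probability branches have no physical
realization and are removed at construction time (the p -> 0 limit of a branch
and the absence of a branch are *different* objects in this theory; see
:mod:`srdt.core`).

Duplicate outcomes are deliberately kept as separate branches: the model is
branch-based and coalescing {o,p1; o,p2} into {o,p1+p2} changes its
predictions.  Editing-style simplification of prospects is out of scope.
"""

from __future__ import annotations

import io
import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("srdt")

__all__ = [
    "OutcomeBranch",
    "Lottery",
    "ChoiceSet",
    "LotteryError",
    "is_degenerate",
    "load_lotteries",
    "dump_lotteries",
    "generate_random_lotteries",
]

#: branch probabilities must sum to one within this after normalization
_SUM_TOL = 1e-9
#: without renormalization, the raw sum may deviate from one by at most this
_RAW_SUM_TOL = 1e-6


class LotteryError(ValueError):
    """Malformed lottery, choice set, or input file."""


@dataclass(frozen=True)
class OutcomeBranch:
    """One (outcome, probability) pair of a lottery.

    outcome is a monetary amount in arbitrary currency units (any finite real);
    probability lies in [0, 1].
    """

    outcome: float
    probability: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.outcome):
            raise LotteryError(f"outcome must be finite, got {self.outcome!r}")
        if not (0.0 <= self.probability <= 1.0 + _RAW_SUM_TOL):
            raise LotteryError(
                f"probability must lie in [0, 1], got {self.probability!r}"
            )


@dataclass(frozen=True)
class Lottery:
    """An ordered collection of outcome branches with probabilities summing to 1.

    Zero-probability branches are dropped on construction (with a logged
    warning) and the remaining probabilities renormalized, unless
    ``normalize=False`` in which case the raw probabilities must already sum
    to one within 1e-6.
    """

    id: str
    branches: tuple[OutcomeBranch, ...]

    def __init__(self, id: str, branches: Iterable, normalize: bool = True):
        object.__setattr__(self, "id", str(id))
        parsed = []
        for b in branches:
            if not isinstance(b, OutcomeBranch):
                b = OutcomeBranch(float(b[0]), float(b[1]))
            parsed.append(b)
        kept = [b for b in parsed if b.probability > 0.0]
        if len(kept) < len(parsed):
            logger.warning(
                "lottery %r: dropped %d zero-probability branch(es)",
                id, len(parsed) - len(kept),
            )
        if not kept:
            raise LotteryError(f"lottery {id!r} has no positive-probability branch")
        total = float(sum(b.probability for b in kept))
        if normalize:
            if total <= 0.0:
                raise LotteryError(f"lottery {id!r}: probabilities sum to {total}")
            kept = [
                OutcomeBranch(b.outcome, b.probability / total) for b in kept
            ]
        elif abs(total - 1.0) > _RAW_SUM_TOL:
            raise LotteryError(
                f"lottery {id!r}: probabilities sum to {total:.9f}, "
                f"more than {_RAW_SUM_TOL} away from 1"
            )
        object.__setattr__(self, "branches", tuple(kept))
        s = sum(b.probability for b in self.branches)
        if abs(s - 1.0) > _SUM_TOL:
            raise LotteryError(f"lottery {id!r}: normalized sum {s} != 1")

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([b.outcome for b in self.branches], dtype=float)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([b.probability for b in self.branches], dtype=float)

    def __len__(self) -> int:
        return len(self.branches)


def is_degenerate(lottery: Lottery) -> bool:
    """True iff the lottery pays a single outcome with certainty.

    Structural definition: exactly one positive-probability branch.  A lottery
    like {7, 0.5; 7, 0.5} is *not* degenerate — its two branches are distinct
    objects in the star representation even though the payoff is sure.
    """
    return len(lottery.branches) == 1


@dataclass(frozen=True)
class ChoiceSet:
    """Two or more lotteries offered simultaneously.

    Luce's restriction: a choice set consisting only of sure (degenerate)
    lotteries is rejected, because the ratio-scale choice rule would assign a
    non-degenerate probability to a choice between two sure amounts.
    """

    lotteries: tuple[Lottery, ...]

    def __init__(self, lotteries: Iterable[Lottery]):
        lot = tuple(lotteries)
        if len(lot) < 2:
            raise LotteryError("a choice set needs at least two lotteries")
        if all(is_degenerate(L) for L in lot):
            raise LotteryError(
                "all lotteries are degenerate (sure outcomes); the Luce-form "
                "choice rule is not defined for choices between sure amounts"
            )
        object.__setattr__(self, "lotteries", lot)

    def __len__(self) -> int:
        return len(self.lotteries)

    @property
    def ids(self) -> list[str]:
        return [L.id for L in self.lotteries]


# ---------------------------------------------------------------------------
# serialization
#
# JSON schema: {"lotteries": [{"id": str,
#                              "branches": [{"outcome": x, "probability": p}]}]}
# CSV schema:  columns lottery_id, outcome, probability; one row per branch.
# ---------------------------------------------------------------------------

def _infer_format(source, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    name = source if isinstance(source, (str, os.PathLike)) else ""
    name = str(name)
    if name.endswith(".json"):
        return "json"
    if name.endswith(".csv"):
        return "csv"
    text = name.strip()
    if text.startswith("{"):
        return "json"
    raise LotteryError("cannot infer format; pass format='json' or 'csv'")


def load_lotteries(source, format: str | None = None) -> ChoiceSet:
    """Read a ChoiceSet from a JSON/CSV file path or literal text.

    Probabilities are renormalized; zero-probability branches are dropped with
    a logged warning.  Malformed inputs raise :class:`LotteryError` naming the
    offending lottery or field.
    """
    fmt = _infer_format(source, format)
    is_path = isinstance(source, os.PathLike) or (
        isinstance(source, str) and os.path.exists(source)
    )
    if fmt == "json":
        try:
            if is_path:
                with open(source) as fh:
                    doc = json.load(fh)
            else:
                doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise LotteryError(f"malformed JSON at line {exc.lineno}: {exc.msg}") from exc
        if "lotteries" not in doc:
            raise LotteryError("JSON document lacks top-level 'lotteries' field")
        lots = []
        for entry in doc["lotteries"]:
            try:
                branches = [
                    (b["outcome"], b["probability"]) for b in entry["branches"]
                ]
                lots.append(Lottery(entry["id"], branches))
            except KeyError as exc:
                raise LotteryError(
                    f"lottery entry {entry.get('id', '?')!r} missing field {exc}"
                ) from exc
    elif fmt == "csv":
        buf = source if is_path else io.StringIO(str(source))
        df = pd.read_csv(buf)
        required = {"lottery_id", "outcome", "probability"}
        if not required.issubset(df.columns):
            raise LotteryError(
                f"CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        lots = []
        for lid, grp in df.groupby("lottery_id", sort=False):
            lots.append(
                Lottery(str(lid), list(zip(grp["outcome"], grp["probability"])))
            )
    else:
        raise LotteryError(f"unknown format {fmt!r}")
    return ChoiceSet(lots)


def dump_lotteries(cs: ChoiceSet, path=None, format: str = "json"):
    """Serialize a ChoiceSet.  Returns the text if ``path`` is None."""
    if format == "json":
        doc = {
            "lotteries": [
                {
                    "id": L.id,
                    "branches": [
                        {"outcome": b.outcome, "probability": b.probability}
                        for b in L.branches
                    ],
                }
                for L in cs.lotteries
            ]
        }
        text = json.dumps(doc, indent=1)
    elif format == "csv":
        rows = [
            {"lottery_id": L.id, "outcome": b.outcome, "probability": b.probability}
            for L in cs.lotteries
            for b in L.branches
        ]
        text = pd.DataFrame(rows).to_csv(index=False)
    else:
        raise LotteryError(f"unknown format {format!r}")
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


def generate_random_lotteries(
    seed: int,
    n_sets: int,
    branches_per_lottery: tuple[int, int] = (2, 3),
    outcome_range: tuple[float, float] = (-100.0, 100.0),
    lotteries_per_set: int = 2,
) -> list[ChoiceSet]:
    """Reproducible random choice sets for property tests and fixtures.

    Outcomes are uniform on ``outcome_range``; branch probabilities are drawn
    from the flat simplex (symmetric Dirichlet with unit concentration).
    """
    lo_b, hi_b = branches_per_lottery
    if lo_b < 1 or hi_b < lo_b:
        raise ValueError(f"empty branch-count range {branches_per_lottery}")
    lo_o, hi_o = outcome_range
    if not (hi_o > lo_o):
        raise ValueError(f"empty outcome range {outcome_range}")
    if n_sets < 1 or lotteries_per_set < 2:
        raise ValueError("need n_sets >= 1 and lotteries_per_set >= 2")
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        lots = []
        for j in range(lotteries_per_set):
            k = int(rng.integers(lo_b, hi_b + 1))
            outs = rng.uniform(lo_o, hi_o, size=k)
            probs = rng.dirichlet(np.ones(k))
            # guard against numerically-zero simplex coordinates
            probs = np.clip(probs, 1e-12, None)
            probs /= probs.sum()
            lots.append(Lottery(f"set{i}_L{j}", list(zip(outs, probs))))
        sets.append(ChoiceSet(lots))
    return sets
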