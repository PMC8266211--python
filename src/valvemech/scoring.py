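"""Multi-criteria min-max scoring and ranking of valve model cases.

Each criterion is a vector of raw metric values, one per case, with a fixed
direction: for a higher-is-better criterion the score is
``(v - min) / (max - min)`` and for a lower-is-better criterion
``(max - v) / (max - min)``, so the best case scores 1 and the worst 0.
Summing the twelve criterion scores per case and sorting descending ranks
the candidate constitutive-law/fiber-architecture combinations.

In table-reproduction mode scores are rounded half-up to two decimals
*before* totaling, matching how the published comparison table totals its
printed entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOWER_BETTER",
    "HIGHER_BETTER",
    "CRITERIA",
    "CriterionSpec",
    "ScoreTable",
    "variation",
    "normalize_criterion",
    "build_score_table",
    "round_half_up",
]

#: Fixed direction registry for the twelve comparison criteria.
LOWER_BETTER = frozenset(
    {
        "ex_vivo_fitting_error",
        "opening_duration",
        "closing_duration",
        "regurgitation_flow",
        "strain_variation",
        "stress_variation",
        "rf",
        "tpg",
        "energy_loss",
    }
)
HIGHER_BETTER = frozenset({"opening_orifice", "forward_flow", "eoa"})

#: Canonical criterion order for the full comparison table.
CRITERIA = (
    "ex_vivo_fitting_error",
    "opening_orifice",
    "opening_duration",
    "closing_duration",
    "forward_flow",
    "regurgitation_flow",
    "strain_variation",
    "stress_variation",
    "rf",
    "tpg",
    "eoa",
    "energy_loss",
)


def default_direction(name: str) -> str:
    if name in LOWER_BETTER:
        return "lower-better"
    if name in HIGHER_BETTER:
        return "higher-better"
    raise KeyError(f"criterion {name!r} has no registered direction")


@dataclass(frozen=True)
class CriterionSpec:
    """One criterion: raw values per case (or pre-normalized scores)."""

    name: str
    values: np.ndarray
    direction: str = ""
    prenormalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        direction = self.direction or default_direction(self.name)
        if direction not in ("lower-better", "higher-better"):
            raise ValueError(f"unknown direction {direction!r}")
        object.__setattr__(self, "direction", direction)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"criterion {self.name}: values must be finite")
        if self.prenormalized and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError(f"criterion {self.name}: pre-normalized scores must lie in [0, 1]")


@dataclass
class ScoreTable:
    """Normalized criteria x cases scores with totals and rank order."""

    cases: Sequence[str]
    scores: pd.DataFrame  # criteria rows x case columns, entries in [0, 1]
    totals: pd.Series
    rank: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        out = {
            "cases": list(self.cases),
            "scores": {c: self.scores.loc[c].tolist() for c in self.scores.index},
            "totals": self.totals.tolist(),
            "rank": list(self.rank),
        }
        text = json.dumps(out, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def render(self) -> str:
        """Plain-text table: criteria rows, case columns, totals last."""
        df = self.scores.copy()
        df.loc["total"] = self.totals
        return df.to_string(float_format=lambda x: f"{x:.2f}")


def variation(belly: float, top_center: float) -> float:
    """Regional spread |belly - top_center| of a strain or stress metric.

    The absolute value makes the measure a spread regardless of which region
    carries the larger value (the circumferential architecture loads the
    top-center region harder than the belly).
    """
    return abs(float(belly) - float(top_center))


def normalize_criterion(spec: CriterionSpec) -> np.ndarray:
    """Min-max scores in [0, 1]; best case 1, worst 0, ties share values.

    An all-equal criterion carries no information and scores 1 for every
    case (no penalty).  Pre-normalized criteria pass through unchanged.
    """
    v = spec.values
    if spec.prenormalized:
        return v.copy()
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.ones_like(v)
    if spec.direction == "higher-better":
        return (v - lo) / (hi - lo)
    return (hi - v) / (hi - lo)


def round_half_up(x, decimals: int = 2):
    """Decimal half-up rounding (0.625 -> 0.63), elementwise."""
    q = Decimal(1).scaleb(-decimals)

    def _one(val):
        # pre-round far below the target precision so that exact halves
        # perturbed by float arithmetic (0.87499999...) round as 0.875
        d = Decimal(repr(round(float(val), decimals + 7)))
        return float(d.quantize(q, rounding=ROUND_HALF_UP))

    a = np.asarray(x, dtype=float)
    if a.ndim == 0:
        return _one(a)
    return np.vectorize(_one)(a)


def build_score_table(
    criteria: Dict[str, CriterionSpec],
    cases: Sequence[str],
    reproduce_published: bool = False,
    required: Sequence[str] = CRITERIA,
) -> ScoreTable:
    """Normalize every criterion, total per case, and rank.

    ``reproduce_published=True`` rounds each score half-up to 2 decimals
    before totaling (the published table totals its printed entries); full
    precision is kept otherwise.  Raises if any ``required`` criterion is
    missing, listing the gaps.
    """
    missing = [c for c in required if c not in criteria]
    if missing:
        raise ValueError(f"missing criteria: {missing}")
    ncase = len(cases)
    rows = {}
    for name in required:
        spec = criteria[name]
        if spec.values.shape != (ncase,):
            raise ValueError(f"criterion {name}: expected {ncase} case values")
        s = normalize_criterion(spec)
        if reproduce_published:
            s = round_half_up(s, 2)
        rows[name] = s
    scores = pd.DataFrame(rows, index=list(cases)).T
    totals = scores.sum(axis=0)
    if reproduce_published:
        totals = pd.Series(round_half_up(totals.to_numpy(), 2), index=totals.index)
    order = np.argsort(-totals.to_numpy(), kind="stable")
    rank = [cases[i] for i in order]
    return ScoreTable(cases=list(cases), scores=scores, totals=totals, rank=rank)
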