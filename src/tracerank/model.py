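"""The decision problem's data model.

A :class:`DecisionMatrix` holds linguistic or crisp evaluations of
alternatives on criteria, each criterion carrying an optimization
direction, an importance weight (linguistic term or crisp number) and a
preference-function specification.  :func:`crispify` defuzzifies every
cell and weight with the Yager index and normalizes the weights to sum
to one, producing the :class:`CrispMatrix` consumed by the ranking
engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .fuzzy import LinguisticScale, TriangularFuzzyNumber, yager_defuzzify
from .preference import PreferenceFunction

__all__ = ["Criterion", "DecisionMatrix", "CrispMatrix", "crispify", "signed_difference"]

MAXIMIZE = "max"
MINIMIZE = "min"

_DIRECTION_ALIASES = {
    "max": MAXIMIZE,
    "max.": MAXIMIZE,
    "maximize": MAXIMIZE,
    "benefit": MAXIMIZE,
    "min": MINIMIZE,
    "min.": MINIMIZE,
    "minimize": MINIMIZE,
    "cost": MINIMIZE,
}


def _normalize_direction(direction: str) -> str:
    try:
        return _DIRECTION_ALIASES[str(direction).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown criterion direction {direction!r}") from None


@dataclass(frozen=True)
class Criterion:
    """A single evaluation criterion.

    ``weight`` is either a linguistic term resolved against the scale or a
    nonnegative crisp number; ``pref_fn`` defaults to the usual (strict)
    preference function.
    """

    name: str
    direction: str = MAXIMIZE
    weight: str | float = 1.0
    pref_fn: PreferenceFunction = field(
        default_factory=lambda: PreferenceFunction("usual")
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", _normalize_direction(self.direction))

    @property
    def is_cost(self) -> bool:
        return self.direction == MINIMIZE

    def resolve_weight(self, scale: LinguisticScale) -> float:
        if isinstance(self.weight, str):
            w = yager_defuzzify(
                scale.resolve(self.weight, context=f"weight of criterion {self.name!r}")
            )
        else:
            w = float(self.weight)
        if w < 0:
            raise ValueError(f"criterion {self.name!r} has negative weight {w}")
        return w


class DecisionMatrix:
    """Alternatives x criteria table of linguistic or crisp evaluations."""

    def __init__(
        self,
        alternatives: Sequence[str],
        criteria: Sequence[Criterion],
        cells: Sequence[Sequence[str | float]] | pd.DataFrame,
    ):
        alternatives = [str(a) for a in alternatives]
        if len(set(alternatives)) != len(alternatives):
            dupes = sorted({a for a in alternatives if alternatives.count(a) > 1})
            raise ValueError(f"duplicate alternative labels: {dupes}")
        names = [c.name for c in criteria]
        if len(set(names)) != len(names):
            raise ValueError("duplicate criterion names")
        table = pd.DataFrame(cells)
        table.index = pd.Index(alternatives, name="alternative")
        if table.shape[1] != len(criteria):
            raise ValueError(
                f"matrix is not rectangular: {table.shape[1]} cell columns for "
                f"{len(criteria)} criteria"
            )
        table.columns = names
        self.alternatives = alternatives
        self.criteria = list(criteria)
        self.cells = table

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(f"unknown criterion {name!r}")

    def with_weight(self, criterion: str, new_weight: str | float) -> "DecisionMatrix":
        """Copy of the problem with one criterion's weight replaced."""
        self.criterion(criterion)  # raise early on unknown name
        criteria = [
            replace(c, weight=new_weight) if c.name == criterion else c
            for c in self.criteria
        ]
        return DecisionMatrix(self.alternatives, criteria, self.cells.copy())

    def reorder(self, alternatives: Sequence[str]) -> "DecisionMatrix":
        if sorted(alternatives) != sorted(self.alternatives):
            raise ValueError("reorder must permute the existing alternatives")
        return DecisionMatrix(
            list(alternatives), self.criteria, self.cells.loc[list(alternatives)]
        )

    def __repr__(self) -> str:
        return (
            f"DecisionMatrix({self.n_alternatives} alternatives x "
            f"{len(self.criteria)} criteria)"
        )


@dataclass
class CrispMatrix:
    """Defuzzified form of a decision problem.

    ``values`` holds Yager-defuzzified cell values, ``weights`` the
    normalized (sum-to-one) criterion weights; optimization directions are
    retained so the engines can orient pairwise differences.
    """

    values: pd.DataFrame
    weights: pd.Series
    directions: pd.Series
    criteria: list[Criterion]

    def __post_init__(self) -> None:
        total = float(self.weights.sum())
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"normalized weights must sum to 1, got {total}")

    @property
    def alternatives(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_alternatives(self) -> int:
        return len(self.values)

    def signed_differences(self) -> np.ndarray:
        """All pairwise oriented advantages, shape (n, n, k).

        Entry (t, u, j) is positive when alternative t beats u on
        criterion j, regardless of the criterion's direction.
        """
        v = self.values.to_numpy(dtype=float)
        sign = np.where(self.directions.to_numpy() == MINIMIZE, -1.0, 1.0)
        return (v[:, None, :] - v[None, :, :]) * sign


def _cell_value(cell, scale: LinguisticScale, context: str) -> float:
    if isinstance(cell, str):
        return yager_defuzzify(scale.resolve(cell, context=context))
    return yager_defuzzify(TriangularFuzzyNumber.crisp(float(cell)))


def crispify(m: DecisionMatrix, scale: LinguisticScale) -> CrispMatrix:
    """Defuzzify cells and weights (Yager) and normalize weights to sum 1.

    Crisp numeric cells are treated as degenerate triangles, so they pass
    through unchanged.  Raises on an unknown linguistic term (naming the
    offending cell) and on an all-zero weight vector.
    """
    values = pd.DataFrame(
        [
            [
                _cell_value(
                    m.cells.iat[i, j], scale, f"cell ({m.alternatives[i]}, {c.name})"
                )
                for j, c in enumerate(m.criteria)
            ]
            for i in range(m.n_alternatives)
        ],
        index=m.cells.index,
        columns=m.cells.columns,
    )
    raw = np.array([c.resolve_weight(scale) for c in m.criteria], dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("degenerate weights: criterion weights sum to zero")
    weights = pd.Series(raw / total, index=values.columns, name="weight")
    directions = pd.Series(
        [c.direction for c in m.criteria], index=values.columns, name="direction"
    )
    return CrispMatrix(values, weights, directions, list(m.criteria))


def signed_difference(c: CrispMatrix, t: str, u: str, j: str) -> float:
    """Oriented advantage of alternative ``t`` over ``u`` on criterion ``j``.

    Positive means t is better than u on j: for maximize criteria this is
    ``value(t) - value(u)``, for minimize criteria the sign is flipped.
    """
    d = float(c.values.at[t, j] - c.values.at[u, j])
    return -d if c.directions[j] == MINIMIZE else d
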