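"""Random decision-problem generator for property testing and demos.

Cells are drawn uniformly from the linguistic ladder, criterion
directions are maximize with probability 3/4 (mirroring the typical
benefit-heavy composition of evaluation criteria; the case study uses
3 of 4), and weights are drawn uniformly from the ladder.  Identical
seeds yield identical problems.
"""

from __future__ import annotations

import numpy as np

from .fuzzy import LinguisticScale, default_scale
from .model import Criterion, DecisionMatrix
from .preference import PreferenceFunction

__all__ = ["generate_random_problem"]


def generate_random_problem(
    n_alts: int,
    n_crit: int,
    seed: int,
    scale: LinguisticScale | None = None,
    pref_fn: PreferenceFunction | None = None,
) -> DecisionMatrix:
    """Draw a random linguistic decision problem.

    Parameters
    ----------
    n_alts, n_crit:
        Problem size; at least 2 alternatives and 1 criterion.
    seed:
        Seed for the underlying generator; determinism contract.
    scale:
        Linguistic scale to draw terms from (default: the shipped
        five-term ladder).
    pref_fn:
        Preference function attached to every criterion (default: usual).
    """
    if n_alts < 2 or n_crit < 1:
        raise ValueError("need at least 2 alternatives and 1 criterion")
    scale = scale or default_scale()
    pref_fn = pref_fn or PreferenceFunction("usual")
    rng = np.random.default_rng(seed)
    terms = scale.terms
    cells = rng.choice(terms, size=(n_alts, n_crit))
    directions = rng.choice(["max", "min"], size=n_crit, p=[0.75, 0.25])
    weights = rng.choice(terms, size=n_crit)
    criteria = [
        Criterion(
            name=f"criterion_{j + 1}",
            direction=directions[j],
            weight=str(weights[j]),
            pref_fn=pref_fn,
        )
        for j in range(n_crit)
    ]
    alternatives = [f"alt_{i + 1}" for i in range(n_alts)]
    return DecisionMatrix(alternatives, criteria, cells.tolist())
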