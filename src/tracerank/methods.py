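"""Weighted-sum and TOPSIS comparators on the crisp decision matrix.

Both methods consume the same Yager-defuzzified matrix and normalized
weights as the PROMETHEE path, so rankings are directly comparable.
Conventions the method definitions leave open (how cost criteria are
folded in, whether columns are vector-normalized before weighting) are
exposed as named flags so a replication harness can enumerate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import MINIMIZE, CrispMatrix
from .promethee import competition_ranks

__all__ = ["weighted_sum_scores", "topsis_scores"]


def _cost_mask(c: CrispMatrix) -> np.ndarray:
    return (c.directions.to_numpy() == MINIMIZE)


def weighted_sum_scores(c: CrispMatrix, cost_handling: str = "complement") -> pd.DataFrame:
    """Sum-normalized weighted-sum scores.

    Cost criteria are converted to a benefit scale first: ``complement``
    maps v -> 1 - v on the defuzzified [0, 1] scale (default), ``negate``
    uses -v.  Raw scores sum_k w_k * benefit(t, k) are divided by their
    grand total so the reported scores sum to one.  Ranks are competition
    ranks on the rounded scores.
    """
    v = c.values.to_numpy(dtype=float).copy()
    cost = _cost_mask(c)
    if cost_handling == "complement":
        v[:, cost] = 1.0 - v[:, cost]
    elif cost_handling == "negate":
        v[:, cost] = -v[:, cost]
    else:
        raise ValueError(f"unknown cost_handling {cost_handling!r}")
    raw = v @ c.weights.to_numpy()
    total = raw.sum()
    if np.isclose(total, 0.0, atol=1e-15):
        raise ValueError("degenerate scores: weighted-sum total is zero")
    score = raw / total
    out = pd.DataFrame({"score": score}, index=c.values.index)
    out["rank"] = competition_ranks(score)
    out.attrs["method"] = "weighted_sum"
    return out.sort_values(["rank", "score"], ascending=[True, False], kind="stable")


def topsis_scores(
    c: CrispMatrix,
    normalization: str = "vector",
    cost_handling: str = "min_ideal",
) -> pd.DataFrame:
    """TOPSIS closeness coefficients.

    The weighted matrix is compared against the ideal point (per-criterion
    best) and the anti-ideal (per-criterion worst); the closeness
    coefficient C = D- / (D+ + D-) is 1 at the ideal and 0 at the
    anti-ideal.

    ``normalization``: ``vector`` (default) scales each column to unit
    Euclidean norm before weighting; ``none`` uses the defuzzified values
    directly (they already share a [0, 1] scale).
    ``cost_handling``: ``min_ideal`` (default) keeps cost columns raw and
    takes their minimum as ideal; ``complement`` maps them to 1 - v and
    treats them as benefits.

    If an alternative coincides with both reference points (all
    alternatives identical) its closeness is defined as 0.5.
    """
    x = c.values.to_numpy(dtype=float).copy()
    cost = _cost_mask(c)
    if cost_handling == "complement":
        x[:, cost] = 1.0 - x[:, cost]
        cost = np.zeros_like(cost)
    elif cost_handling != "min_ideal":
        raise ValueError(f"unknown cost_handling {cost_handling!r}")
    if normalization == "vector":
        norms = np.sqrt((x**2).sum(axis=0))
        x = np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    u = x * c.weights.to_numpy()
    ideal = np.where(cost, u.min(axis=0), u.max(axis=0))
    anti = np.where(cost, u.max(axis=0), u.min(axis=0))
    d_plus = np.sqrt(((u - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((u - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    score = np.divide(d_minus, denom, out=np.full(len(u), 0.5), where=denom > 0)
    out = pd.DataFrame({"score": score}, index=c.values.index)
    out["rank"] = competition_ranks(score)
    out.attrs["method"] = "topsis"
    return out.sort_values(["rank", "score"], ascending=[True, False], kind="stable")
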