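"""PROMETHEE outranking engine.

Given a crisp decision matrix with normalized weights, the pairwise
preference index is

    pi(a_t, a_u) = sum_k w_k * P_k(d_k(t, u)),

where d_k is the oriented advantage of t over u on criterion k and P_k
that criterion's preference function.  Averaging preference indices over
opponents gives the positive flow Phi+ (strength), negative flow Phi-
(weakness) and net flow Phi = Phi+ - Phi-.  PROMETHEE I derives a partial
order (preference / indifference / incomparability) from the two flows;
PROMETHEE II ranks by net flow alone.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CrispMatrix
from .preference import PreferenceFunction

__all__ = [
    "preference_index",
    "outranking_flows",
    "promethee2_rank",
    "promethee1_relations",
    "unicriterion_net_flows",
    "competition_ranks",
    "promethee2",
]

#: equality tolerance for flow comparisons in PROMETHEE I
FLOW_ATOL = 1e-12

#: net flows are rounded to this many decimals before rank-tie detection,
#: matching the reporting precision of the flow tables
RANK_DECIMALS = 4


def _resolve_specs(
    c: CrispMatrix,
    specs: Mapping[str, PreferenceFunction] | Sequence[PreferenceFunction] | PreferenceFunction | None,
) -> list[PreferenceFunction]:
    names = list(c.values.columns)
    if specs is None:
        return [crit.pref_fn for crit in c.criteria]
    if isinstance(specs, PreferenceFunction):
        return [specs] * len(names)
    if isinstance(specs, Mapping):
        missing = [n for n in names if n not in specs]
        if missing:
            raise KeyError(f"no preference function for criteria {missing}")
        return [specs[n] for n in names]
    specs = list(specs)
    if len(specs) != len(names):
        raise ValueError("one preference function required per criterion")
    return specs


def _preference_cube(c: CrispMatrix, specs) -> np.ndarray:
    """P_k(d_k(t,u)) for all ordered pairs, shape (n, n, k), zero diagonal."""
    d = c.signed_differences()
    fns = _resolve_specs(c, specs)
    cube = np.stack([fns[k](d[:, :, k]) for k in range(d.shape[2])], axis=-1)
    idx = np.arange(c.n_alternatives)
    cube[idx, idx, :] = 0.0
    return cube


def preference_index(c: CrispMatrix, specs=None) -> pd.DataFrame:
    """Aggregated preference indices pi(t, u); diagonal zero.

    With weights summing to one every entry lies in [0, 1].
    """
    if c.n_alternatives < 2:
        raise ValueError("outranking needs at least two alternatives")
    cube = _preference_cube(c, specs)
    pi = cube @ c.weights.to_numpy()
    return pd.DataFrame(pi, index=c.values.index, columns=c.values.index)


def outranking_flows(pi: pd.DataFrame) -> pd.DataFrame:
    """Positive, negative and net outranking flows from a preference index.

    Phi+(t) averages pi(t, .) over the n-1 opponents, Phi-(t) averages
    pi(., t); the net flow is their difference and sums to zero over all
    alternatives.
    """
    n = len(pi)
    if n < 2:
        raise ValueError("outranking needs at least two alternatives")
    m = pi.to_numpy(dtype=float)
    phi_plus = m.sum(axis=1) / (n - 1)
    phi_minus = m.sum(axis=0) / (n - 1)
    return pd.DataFrame(
        {
            "phi_plus": phi_plus,
            "phi_minus": phi_minus,
            "phi_net": phi_plus - phi_minus,
        },
        index=pi.index,
    )


def competition_ranks(values: Sequence[float], decimals: int = RANK_DECIMALS) -> np.ndarray:
    """Descending competition ranking ("1, 2, 2, 4") with rounded ties.

    Values are rounded to ``decimals`` before tie detection, so ties that
    would only show below reporting precision are honored as ties.
    """
    v = np.round(np.asarray(values, dtype=float), decimals)
    order = np.argsort(-v, kind="stable")
    ranks = np.empty(len(v), dtype=int)
    prev = None
    rank = 0
    for pos, i in enumerate(order, start=1):
        if prev is None or v[i] != prev:
            rank = pos
        ranks[i] = rank
        prev = v[i]
    return ranks


def promethee2_rank(flows: pd.DataFrame) -> pd.DataFrame:
    """Complete PROMETHEE II ranking: sort by net flow, competition ranks."""
    out = flows.copy()
    out["rank"] = competition_ranks(out["phi_net"].to_numpy())
    return out.sort_values(["rank", "phi_net"], ascending=[True, False], kind="stable")


def promethee1_relations(flows: pd.DataFrame) -> pd.DataFrame:
    """PROMETHEE I pairwise relations from the two flows.

    Row label ``P`` if the row alternative outranks the column one
    (higher-or-equal Phi+ and strictly lower Phi-, or strictly higher Phi+
    and equal Phi-), ``O`` for the converse direction (row is outranked),
    ``I`` if both flows are equal, ``R`` (incomparable) when one flow
    favors each side; ``self`` on the diagonal.  P/O are mutually
    transposed, I and R are symmetric.  Equality of flows uses an absolute
    tolerance.
    """
    plus = flows["phi_plus"].to_numpy()
    minus = flows["phi_minus"].to_numpy()
    n = len(flows)
    rel = np.full((n, n), "R", dtype=object)
    for t in range(n):
        rel[t][t] = "self"
        for u in range(t + 1, n):
            peq = np.isclose(plus[t], plus[u], rtol=0.0, atol=FLOW_ATOL)
            meq = np.isclose(minus[t], minus[u], rtol=0.0, atol=FLOW_ATOL)
            pgt = not peq and plus[t] > plus[u]
            plt = not peq and plus[t] < plus[u]
            mlt = not meq and minus[t] < minus[u]
            mgt = not meq and minus[t] > minus[u]
            if peq and meq:
                rel[t][u] = rel[u][t] = "I"
            elif ((pgt or peq) and mlt) or (pgt and meq):
                rel[t][u], rel[u][t] = "P", "O"
            elif ((plt or peq) and mgt) or (plt and meq):
                rel[t][u], rel[u][t] = "O", "P"
            # otherwise both flows strictly favor different sides: R/R
    return pd.DataFrame(rel, index=flows.index, columns=flows.index)


def unicriterion_net_flows(c: CrispMatrix, specs=None) -> pd.DataFrame:
    """Per-criterion net flow decomposition phi_k(t).

    phi_k(t) averages P_k(d(t,u)) - P_k(d(u,t)) over opponents; the overall
    net flow is the weight-combination sum_k w_k phi_k(t).  Positive
    entries are strengths of the alternative on that criterion, negative
    entries weaknesses (the stacked-bar decomposition view).
    """
    if c.n_alternatives < 2:
        raise ValueError("outranking needs at least two alternatives")
    cube = _preference_cube(c, specs)
    phi = (cube - cube.transpose(1, 0, 2)).sum(axis=1) / (c.n_alternatives - 1)
    return pd.DataFrame(phi, index=c.values.index, columns=c.values.columns)


def promethee2(c: CrispMatrix, specs=None) -> pd.DataFrame:
    """Convenience: preference index, flows and PROMETHEE II ranking."""
    return promethee2_rank(outranking_flows(preference_index(c, specs)))
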