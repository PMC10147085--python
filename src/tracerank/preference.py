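"""Preference functions mapping pairwise advantages to degrees in [0, 1].

PROMETHEE compares alternatives pairwise on each criterion; a preference
function P(d) turns the advantage d into a preference degree.  The six
standard shapes (usual, U-shape, V-shape, level, linear, Gaussian) are
provided, plus a monotone *staircase* generalization (piecewise-constant
levels at arbitrary thresholds) used by the replication calibration.
Every shape satisfies P(d) = 0 for d <= 0 and is nondecreasing in d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["PreferenceFunction", "preference_value", "PREFERENCE_TYPES"]

PREFERENCE_TYPES = (
    "usual",
    "u_shape",
    "v_shape",
    "level",
    "linear",
    "gaussian",
    "staircase",
)


@dataclass(frozen=True)
class PreferenceFunction:
    """Specification of a preference function.

    Parameters
    ----------
    type:
        One of ``usual``, ``u_shape``, ``v_shape``, ``level``, ``linear``,
        ``gaussian``, ``staircase``.
    q:
        Indifference threshold (u_shape, level, linear); d <= q yields no
        preference.
    p:
        Preference threshold (v_shape, level, linear); d >= p yields full
        (or plateau) preference.  Must exceed q where both apply.
    s:
        Gaussian spread (> 0); P(d) = 1 - exp(-d^2 / (2 s^2)) for d > 0.
    thresholds, levels:
        Staircase only: increasing thresholds t_1 < t_2 < ... and
        nondecreasing levels l_1 <= l_2 <= ... in [0, 1]; P(d) = l_i for
        t_i <= d < t_{i+1}, 0 below t_1, l_last above.
    """

    type: str
    q: float | None = None
    p: float | None = None
    s: float | None = None
    thresholds: tuple[float, ...] = field(default=())
    levels: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        t = self.type
        if t not in PREFERENCE_TYPES:
            raise ValueError(f"unknown preference function type {t!r}")
        if t == "u_shape" and (self.q is None or self.q < 0):
            raise ValueError("u_shape requires indifference threshold q >= 0")
        if t == "v_shape" and (self.p is None or self.p <= 0):
            raise ValueError("v_shape requires preference threshold p > 0")
        if t in ("level", "linear"):
            if self.q is None or self.p is None or not 0 <= self.q < self.p:
                raise ValueError(f"{t} requires thresholds 0 <= q < p")
        if t == "gaussian" and (self.s is None or self.s <= 0):
            raise ValueError("gaussian requires spread s > 0")
        if t == "staircase":
            th, lv = self.thresholds, self.levels
            if len(th) != len(lv) or not th:
                raise ValueError("staircase requires matching thresholds/levels")
            if any(b <= a for a, b in zip(th, th[1:])):
                raise ValueError("staircase thresholds must strictly increase")
            if any(b < a for a, b in zip(lv, lv[1:])):
                raise ValueError("staircase levels must be nondecreasing")
            if min(lv) < 0 or max(lv) > 1 or min(th) <= 0:
                raise ValueError("staircase levels in [0,1], thresholds > 0")

    def __call__(self, d):
        return preference_value(d, self)

    def describe(self) -> str:
        parts = [self.type]
        for name in ("q", "p", "s"):
            v = getattr(self, name)
            if v is not None:
                parts.append(f"{name}={v:g}")
        if self.type == "staircase":
            steps = ", ".join(
                f"{t:.4g}->{l:.4g}" for t, l in zip(self.thresholds, self.levels)
            )
            parts.append(f"[{steps}]")
        return " ".join(parts)


def preference_value(d, spec: PreferenceFunction):
    """Evaluate a preference function at advantage ``d`` (scalar or array).

    Always returns values in [0, 1], zero for non-positive advantages.
    """
    scalar = np.isscalar(d)
    d = np.asarray(d, dtype=float)
    t = spec.type
    if t == "usual":
        out = (d > 0).astype(float)
    elif t == "u_shape":
        out = (d > spec.q).astype(float)
    elif t == "v_shape":
        out = np.where(d > 0, np.clip(d / spec.p, 0.0, 1.0), 0.0)
    elif t == "level":
        out = np.where(d <= spec.q, 0.0, np.where(d <= spec.p, 0.5, 1.0))
    elif t == "linear":
        out = np.clip(
            np.where(d <= spec.q, 0.0, (d - spec.q) / (spec.p - spec.q)), 0.0, 1.0
        )
    elif t == "gaussian":
        out = np.where(d <= 0, 0.0, 1.0 - np.exp(-(d**2) / (2.0 * spec.s**2)))
    elif t == "staircase":
        th = np.asarray(spec.thresholds)
        lv = np.asarray(spec.levels)
        # index of the largest threshold <= d (1e-9 slop absorbs float noise
        # in thresholds derived from rating-scale differences)
        idx = np.searchsorted(th, d + 1e-9, side="left")
        out = np.where(idx > 0, lv[np.maximum(idx - 1, 0)], 0.0)
        out = np.where(d <= 0, 0.0, out)
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(t)
    return float(out) if scalar else out


def usual() -> PreferenceFunction:
    return PreferenceFunction("usual")


def gaussian(s: float) -> PreferenceFunction:
    return PreferenceFunction("gaussian", s=s)


def staircase(
    thresholds: Sequence[float], levels: Sequence[float]
) -> PreferenceFunction:
    return PreferenceFunction(
        "staircase", thresholds=tuple(thresholds), levels=tuple(levels)
    )
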