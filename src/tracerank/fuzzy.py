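"""Triangular fuzzy numbers, linguistic rating scales, and defuzzification.

Qualitative evidence about decision alternatives ("specificity is very
high") is encoded on a five-term linguistic ladder.  Each term maps to a
triangular fuzzy number (TFN) on [0, 1]; the Yager index collapses a TFN
to a single crisp value so that classical multi-criteria machinery can be
applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "TriangularFuzzyNumber",
    "LinguisticScale",
    "yager_defuzzify",
    "default_scale",
]


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A fuzzy quantity with support ``[left, right]`` and peak at ``mode``.

    The left spread ``a = mode - left`` and right spread ``b = right - mode``
    measure the asymmetry of the uncertainty.  A degenerate TFN with
    ``left == mode == right`` represents a crisp number, which lets crisp
    and linguistic evaluations flow through one code path.
    """

    left: float
    mode: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left <= self.mode <= self.right):
            raise ValueError(
                f"malformed fuzzy number: require left <= mode <= right, "
                f"got ({self.left}, {self.mode}, {self.right})"
            )

    @property
    def a(self) -> float:
        """Left spread (distance from the mode to the lower support bound)."""
        return self.mode - self.left

    @property
    def b(self) -> float:
        """Right spread (distance from the mode to the upper support bound)."""
        return self.right - self.mode

    @classmethod
    def crisp(cls, value: float) -> "TriangularFuzzyNumber":
        return cls(value, value, value)

    def defuzzify(self) -> float:
        return yager_defuzzify(self)

    def __iter__(self):
        return iter((self.left, self.mode, self.right))


def yager_defuzzify(x: TriangularFuzzyNumber) -> float:
    """Crisp value of a TFN by the Yager index ``(3N - a + b) / 3``.

    ``N`` is the mode, ``a``/``b`` the left/right spreads.  The index uses
    all three vertices of the triangle: it equals the mode for symmetric
    triangles and shifts toward the heavier tail otherwise.  For a
    degenerate (crisp) triangle it returns the value itself.
    """
    return (3.0 * x.mode - x.a + x.b) / 3.0


class LinguisticScale:
    """Ordered mapping from linguistic terms to triangular fuzzy numbers.

    Terms are declared best-first (e.g. VH, H, M, L, VL); lookups are
    case-insensitive.  The constructor enforces that term labels are unique
    and that the modes strictly decrease along the declared order, so the
    scale is ordinally consistent.
    """

    def __init__(self, term_map: Mapping[str, TriangularFuzzyNumber]):
        terms = list(term_map)
        lowered = [t.lower() for t in terms]
        if len(set(lowered)) != len(lowered):
            raise ValueError("duplicate term labels in linguistic scale")
        modes = [term_map[t].mode for t in terms]
        if any(m2 >= m1 for m1, m2 in zip(modes, modes[1:])):
            raise ValueError(
                "linguistic scale modes must strictly decrease along the "
                f"declared order; got modes {modes} for terms {terms}"
            )
        self._terms = terms
        self._map = {t.lower(): tfn for t, tfn in term_map.items()}

    @property
    def terms(self) -> list[str]:
        """Term labels, best first."""
        return list(self._terms)

    def __contains__(self, label: str) -> bool:
        return isinstance(label, str) and label.lower() in self._map

    def resolve(self, label: str, *, context: str = "") -> TriangularFuzzyNumber:
        """Look up a term; raises ``KeyError`` naming the offending cell."""
        try:
            return self._map[label.lower()]
        except (KeyError, AttributeError):
            where = f" in {context}" if context else ""
            raise KeyError(
                f"unknown linguistic term {label!r}{where}; "
                f"known terms: {', '.join(self._terms)}"
            ) from None

    def value(self, label: str) -> float:
        """Defuzzified (Yager) value of a term."""
        return yager_defuzzify(self.resolve(label))

    def items(self) -> Iterable[tuple[str, TriangularFuzzyNumber]]:
        return ((t, self._map[t.lower()]) for t in self._terms)

    def to_dict(self) -> dict[str, list[float]]:
        return {t: [tfn.left, tfn.mode, tfn.right] for t, tfn in self.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[float]]) -> "LinguisticScale":
        return cls({t: TriangularFuzzyNumber(*v) for t, v in d.items()})

    def __repr__(self) -> str:
        inner = ", ".join(f"{t}={tuple(tfn)}" for t, tfn in self.items())
        return f"LinguisticScale({inner})"


def default_scale() -> LinguisticScale:
    """The shipped five-term scale on [0, 1].

    VH (0.75, 1, 1), H (0.5, 0.75, 1), M (0.25, 0.5, 0.75), L (0, 0.25, 0.5),
    VL (0, 0, 0.25).  Yager values: 0.9167, 0.75, 0.5, 0.25, 0.0833.
    """
    return LinguisticScale(
        {
            "VH": TriangularFuzzyNumber(0.75, 1.0, 1.0),
            "H": TriangularFuzzyNumber(0.50, 0.75, 1.0),
            "M": TriangularFuzzyNumber(0.25, 0.50, 0.75),
            "L": TriangularFuzzyNumber(0.0, 0.25, 0.50),
            "VL": TriangularFuzzyNumber(0.0, 0.0, 0.25),
        }
    )
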