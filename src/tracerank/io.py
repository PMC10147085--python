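"""File formats: decision-matrix CSV, scale and criteria configs, reports.

The matrix CSV mirrors the layout of a typical published evaluation
table: a header row of criterion names, an ``aim`` row (max/min), a
``weight`` row (linguistic term or number), then one row per
alternative.  Scales and criteria configurations round-trip through
JSON or YAML.  Unicode minus signs are normalized to ASCII on ingest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO

import pandas as pd
import yaml

from .fuzzy import LinguisticScale
from .model import Criterion, DecisionMatrix
from .preference import PreferenceFunction

__all__ = [
    "load_matrix_csv",
    "write_matrix_csv",
    "load_scale",
    "write_scale",
    "load_criteria_config",
    "write_criteria_config",
]

_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


def _normalize_minus(text: str) -> str:
    for bad, good in _MINUS_VARIANTS.items():
        text = text.replace(bad, good)
    return text


def _coerce_cell(cell: str) -> str | float:
    cell = _normalize_minus(str(cell).strip())
    try:
        return float(cell)
    except ValueError:
        return cell


def load_matrix_csv(path: str | Path | IO[str]) -> DecisionMatrix:
    """Read a decision matrix with embedded ``aim`` and ``weight`` rows."""
    raw = pd.read_csv(path, dtype=str).fillna("")
    raw.iloc[:, 0] = raw.iloc[:, 0].str.strip()
    first = raw.iloc[:, 0].str.lower()
    meta = {}
    for key in ("aim", "weight"):
        match = raw[first == key]
        if len(match) != 1:
            raise ValueError(f"matrix CSV must contain exactly one {key!r} row")
        meta[key] = [str(v).strip() for v in match.iloc[0, 1:]]
    body = raw[~first.isin(("aim", "weight"))]
    criteria = [
        Criterion(name=str(name).strip(), direction=aim, weight=_coerce_cell(wt))
        for name, aim, wt in zip(raw.columns[1:], meta["aim"], meta["weight"])
    ]
    cells = [[_coerce_cell(v) for v in row] for row in body.iloc[:, 1:].to_numpy()]
    return DecisionMatrix(list(body.iloc[:, 0]), criteria, cells)


def write_matrix_csv(m: DecisionMatrix, path: str | Path | IO[str]) -> None:
    rows = [
        ["aim"] + [c.direction for c in m.criteria],
        ["weight"] + [str(c.weight) for c in m.criteria],
    ]
    for alt in m.alternatives:
        rows.append([alt] + [str(v) for v in m.cells.loc[alt]])
    frame = pd.DataFrame(rows, columns=["alternative"] + [c.name for c in m.criteria])
    frame.to_csv(path, index=False)


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_scale(path: str | Path) -> LinguisticScale:
    """Read a term -> [left, mode, right] mapping from JSON or YAML."""
    return LinguisticScale.from_dict(_load_structured(path))


def write_scale(scale: LinguisticScale, path: str | Path) -> None:
    path = Path(path)
    data = scale.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def _pref_fn_from_dict(d: dict) -> PreferenceFunction:
    kwargs = dict(d)
    if "thresholds" in kwargs:
        kwargs["thresholds"] = tuple(kwargs["thresholds"])
    if "levels" in kwargs:
        kwargs["levels"] = tuple(kwargs["levels"])
    return PreferenceFunction(**kwargs)


def _pref_fn_to_dict(fn: PreferenceFunction) -> dict:
    out: dict = {"type": fn.type}
    for name in ("q", "p", "s"):
        v = getattr(fn, name)
        if v is not None:
            out[name] = v
    if fn.type == "staircase":
        out["thresholds"] = list(fn.thresholds)
        out["levels"] = list(fn.levels)
    return out


def load_criteria_config(path: str | Path) -> list[Criterion]:
    """Criteria (direction, weight, preference function) from JSON/YAML.

    Expected shape: a list of objects with keys ``name``, ``direction``,
    ``weight`` and optional ``pref_fn``.
    """
    entries = _load_structured(path)
    criteria = []
    for e in entries:
        kwargs = {"name": e["name"]}
        if "direction" in e:
            kwargs["direction"] = e["direction"]
        if "weight" in e:
            kwargs["weight"] = e["weight"]
        if "pref_fn" in e:
            kwargs["pref_fn"] = _pref_fn_from_dict(e["pref_fn"])
        criteria.append(Criterion(**kwargs))
    return criteria


def write_criteria_config(criteria: list[Criterion], path: str | Path) -> None:
    path = Path(path)
    data = [
        {
            "name": c.name,
            "direction": c.direction,
            "weight": c.weight,
            "pref_fn": _pref_fn_to_dict(c.pref_fn),
        }
        for c in criteria
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
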