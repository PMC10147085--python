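"""The bundled tau PET radiotracer case study.

Fifteen first- and second-generation tau PET radiotracers evaluated on
four criteria — specificity (weight VH), target binding affinity (H),
brain uptake and penetration (VH), adverse reactions (M, minimized) —
with linguistic ratings on the five-term VH..VL ladder.  The published
result tables (baseline PROMETHEE flows, the specificity-weight
sensitivity run, and the weighted-sum/TOPSIS comparison) are bundled as
reference data for the replication harness and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .fuzzy import LinguisticScale
from .io import load_matrix_csv, load_scale
from .model import DecisionMatrix

__all__ = [
    "PaperFixture",
    "load_fixture",
    "reference_rank_groups",
    "REFERENCE_BASELINE",
    "REFERENCE_SENSITIVITY",
    "REFERENCE_SCORES",
]

# Published baseline PROMETHEE result: net, positive, negative flow per tracer,
# listed best-first.  Values are reported at 4-decimal precision.
REFERENCE_BASELINE = pd.DataFrame(
    [
        ("[18F]RO-948", 0.0051, 0.0051, 0.0000),
        ("[11C]RO-643", 0.0045, 0.0048, 0.0003),
        ("[11C]RO-963", 0.0045, 0.0048, 0.0003),
        ("[18F]MK-6240", 0.0042, 0.0043, 0.0001),
        ("[18F]JNJ-067", 0.0033, 0.0036, 0.0003),
        ("[18F]PI-2620", 0.0027, 0.0032, 0.0006),
        ("[18F]PM-PBB3", 0.0019, 0.0023, 0.0004),
        ("[18F]JNJ-311", 0.0019, 0.0023, 0.0004),
        ("[18F]GTP1", 0.0013, 0.0020, 0.0007),
        ("[18F]AV-1451", -0.0023, 0.0014, 0.0037),
        ("[18F]THK5351", -0.0041, 0.0006, 0.0048),
        ("[11C]PBB3", -0.0047, 0.0003, 0.0050),
        ("[18F]THK5317", -0.0057, 0.0003, 0.0060),
        ("[18F]THK5105", -0.0063, 0.0000, 0.0063),
        ("[18F]THK5117", -0.0063, 0.0000, 0.0063),
    ],
    columns=["alternative", "phi_net", "phi_plus", "phi_minus"],
).set_index("alternative")

# Published sensitivity run (specificity weight VH -> H), same layout.
REFERENCE_SENSITIVITY = pd.DataFrame(
    [
        ("[18F]RO-948", 0.0049, 0.0049, 0.0000),
        ("[11C]RO-643", 0.0043, 0.0046, 0.0003),
        ("[11C]RO-963", 0.0043, 0.0046, 0.0003),
        ("[18F]MK-6240", 0.0041, 0.0043, 0.0001),
        ("[18F]JNJ-067", 0.0032, 0.0035, 0.0003),
        ("[18F]PI-2620", 0.0026, 0.0032, 0.0006),
        ("[18F]PM-PBB3", 0.0018, 0.0023, 0.0004),
        ("[18F]JNJ-311", 0.0018, 0.0023, 0.0004),
        ("[18F]GTP1", 0.0012, 0.0020, 0.0007),
        ("[18F]AV-1451", -0.0025, 0.0012, 0.0037),
        ("[11C]PBB3", -0.0033, 0.0005, 0.0038),
        ("[18F]THK5351", -0.0042, 0.0005, 0.0048),
        ("[18F]THK5317", -0.0057, 0.0003, 0.0060),
        ("[18F]THK5105", -0.0063, 0.0000, 0.0063),
        ("[18F]THK5117", -0.0063, 0.0000, 0.0063),
    ],
    columns=["alternative", "phi_net", "phi_plus", "phi_minus"],
).set_index("alternative")

# Published weighted-sum and TOPSIS comparison columns.
REFERENCE_SCORES = pd.DataFrame(
    [
        ("[18F]RO-948", 0.0884, 1, 1.0000, 1),
        ("[11C]RO-643", 0.0810, 3, 0.7684, 3),
        ("[11C]RO-963", 0.0810, 3, 0.7684, 3),
        ("[18F]MK-6240", 0.0838, 2, 0.8282, 2),
        ("[18F]JNJ-067", 0.0792, 5, 0.7541, 5),
        ("[18F]PI-2620", 0.0718, 8, 0.6646, 8),
        ("[18F]PM-PBB3", 0.0748, 6, 0.6865, 6),
        ("[18F]JNJ-311", 0.0748, 6, 0.6865, 6),
        ("[18F]GTP1", 0.0671, 9, 0.5987, 9),
        ("[18F]AV-1451", 0.0588, 10, 0.4210, 10),
        ("[18F]THK5351", 0.0548, 11, 0.3209, 12),
        ("[11C]PBB3", 0.0543, 12, 0.3388, 11),
        ("[18F]THK5317", 0.0487, 13, 0.2316, 13),
        ("[18F]THK5105", 0.0408, 14, 0.0000, 14),
        ("[18F]THK5117", 0.0408, 14, 0.0000, 14),
    ],
    columns=["alternative", "wsm_score", "wsm_rank", "topsis_score", "topsis_rank"],
).set_index("alternative")


def reference_rank_groups(reference: pd.DataFrame) -> list[list[str]]:
    """Tied groups of alternatives, best-first, from a reference flow table.

    Grouping is by the published 4-decimal net flows, so alternatives with
    identical printed flows (necessarily including identically rated ones)
    form one group.
    """
    groups: list[list[str]] = []
    prev = None
    for alt, row in reference.iterrows():
        if prev is not None and np.isclose(row["phi_net"], prev, atol=1e-12):
            groups[-1].append(alt)
        else:
            groups.append([alt])
        prev = row["phi_net"]
    return groups


@dataclass
class PaperFixture:
    """The bundled dataset plus its published reference outputs."""

    scale: LinguisticScale
    matrix: DecisionMatrix

    #: the weight change exercised by the published sensitivity analysis
    sensitivity_criterion: str = "Specificity"
    sensitivity_weight: str = "H"

    @property
    def baseline_reference(self) -> pd.DataFrame:
        return REFERENCE_BASELINE.copy()

    @property
    def sensitivity_reference(self) -> pd.DataFrame:
        return REFERENCE_SENSITIVITY.copy()

    @property
    def scores_reference(self) -> pd.DataFrame:
        return REFERENCE_SCORES.copy()


def _verify(fixture: PaperFixture) -> None:
    m = fixture.matrix
    if m.n_alternatives != 15 or len(m.criteria) != 4:
        raise ValueError("corrupted fixture: expected 15 alternatives x 4 criteria")
    cells = m.cells
    if not cells.loc["[11C]RO-643"].equals(cells.loc["[11C]RO-963"]):
        raise ValueError("corrupted fixture: RO-643 and RO-963 must rate identically")
    if not cells.loc["[18F]THK5105"].equals(cells.loc["[18F]THK5117"]):
        raise ValueError("corrupted fixture: THK5105 and THK5117 must rate identically")
    values = pd.DataFrame(
        {
            c.name: [fixture.scale.value(v) for v in cells[c.name]]
            for c in m.criteria
        },
        index=cells.index,
    )
    oriented = values.copy()
    for c in m.criteria:
        if c.is_cost:
            oriented[c.name] = -oriented[c.name]
    best = oriented.loc["[18F]RO-948"]
    if (oriented.gt(best, axis=1)).any().any():
        raise ValueError("corrupted fixture: RO-948 must be weakly best everywhere")
    worst = oriented.loc["[18F]THK5105"]
    if (oriented.lt(worst, axis=1)).any().any():
        raise ValueError("corrupted fixture: THK5105/THK5117 must be weakly worst")
    weights = [c.weight for c in m.criteria]
    if weights != ["VH", "H", "VH", "M"]:
        raise ValueError(f"corrupted fixture: unexpected weights {weights}")


def load_fixture() -> PaperFixture:
    """Load and validate the bundled tau tracer dataset."""
    pkg = resources.files("tracerank.data")
    with resources.as_file(pkg / "linguistic_scale.json") as p:
        scale = load_scale(p)
    with resources.as_file(pkg / "tau_tracers.csv") as p:
        matrix = load_matrix_csv(p)
    fixture = PaperFixture(scale=scale, matrix=matrix)
    _verify(fixture)
    return fixture
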