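"""One-at-a-time weight sensitivity analysis for PROMETHEE II rankings.

A perturbation replaces a single criterion's importance weight
(linguistic term or crisp number), re-defuzzifies, re-normalizes the
weights and re-runs the complete ranking pipeline; the report pairs the
baseline and perturbed flow tables and lists every rank move.  Sweeping
the full linguistic ladder for each criterion gives an empirical picture
of how much a weight can move before the ranking changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .fuzzy import LinguisticScale
from .model import DecisionMatrix, crispify
from .promethee import promethee2

__all__ = ["SensitivityReport", "perturb_weight", "sweep_linguistic_weights", "rank_agreement"]


@dataclass
class SensitivityReport:
    """Before/after comparison for a single weight perturbation."""

    criterion: str
    old_weight: str | float
    new_weight: str | float
    baseline: pd.DataFrame
    perturbed: pd.DataFrame
    rank_changes: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def stable(self) -> bool:
        """True iff no alternative changed rank."""
        return not self.rank_changes

    def to_frame(self) -> pd.DataFrame:
        base = self.baseline[["phi_net", "rank"]].rename(
            columns={"phi_net": "phi_net_baseline", "rank": "rank_baseline"}
        )
        pert = self.perturbed[["phi_net", "rank"]].rename(
            columns={"phi_net": "phi_net_perturbed", "rank": "rank_perturbed"}
        )
        return base.join(pert).sort_values("rank_baseline")


def perturb_weight(
    problem: DecisionMatrix,
    criterion: str,
    new_weight: str | float,
    scale: LinguisticScale,
    specs=None,
) -> SensitivityReport:
    """Re-rank with one criterion's weight replaced; report rank moves.

    The full pipeline (defuzzification, weight normalization, flows,
    ranking) is recomputed from scratch for both the baseline and the
    perturbed problem, so perturbing a weight to its current value is
    bit-identical to the baseline run.
    """
    old_weight = problem.criterion(criterion).weight
    baseline = promethee2(crispify(problem, scale), specs)
    perturbed = promethee2(
        crispify(problem.with_weight(criterion, new_weight), scale), specs
    )
    changes = [
        (alt, int(baseline.at[alt, "rank"]), int(perturbed.at[alt, "rank"]))
        for alt in problem.alternatives
        if int(baseline.at[alt, "rank"]) != int(perturbed.at[alt, "rank"])
    ]
    return SensitivityReport(
        criterion=criterion,
        old_weight=old_weight,
        new_weight=new_weight,
        baseline=baseline,
        perturbed=perturbed,
        rank_changes=changes,
    )


def sweep_linguistic_weights(
    problem: DecisionMatrix, scale: LinguisticScale, specs=None
) -> pd.DataFrame:
    """One-at-a-time sweep of every criterion over the linguistic ladder.

    Returns a tidy table with one row per (criterion, candidate term)
    recording whether the complete ranking survives that single change —
    an empirical view of the weight ranges that leave the result intact.
    """
    rows = []
    for crit in problem.criteria:
        for term in scale.terms:
            report = perturb_weight(problem, crit.name, term, scale, specs)
            rows.append(
                {
                    "criterion": crit.name,
                    "baseline_weight": crit.weight,
                    "candidate_weight": term,
                    "stable": report.stable,
                    "n_rank_changes": len(report.rank_changes),
                }
            )
    return pd.DataFrame(rows)


def rank_agreement(a: pd.Series, b: pd.Series) -> float:
    """Kendall tau-b between two rank vectors over the same alternatives.

    1.0 for identical rankings, -1.0 for fully reversed strict rankings;
    ties are handled by the b-variant correction.
    """
    a = pd.Series(a)
    b = pd.Series(b)
    if sorted(a.index) != sorted(b.index):
        raise ValueError("rankings must cover the same alternatives")
    b = b.reindex(a.index)
    # ranks order inversely to scores, tau is orientation-consistent either way
    tau = stats.kendalltau(a.to_numpy(), b.to_numpy(), variant="b").statistic
    return float(tau)
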