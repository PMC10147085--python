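import numpy as np
import pandas as pd
import pytest

from tracerank import (
    default_scale,
    generate_random_problem,
    perturb_weight,
    rank_agreement,
    sweep_linguistic_weights,
)
from tracerank.preference import PreferenceFunction

SCALE = default_scale()


def test_noop_perturbation_is_bit_identical(fixture, calibration):
    report = perturb_weight(
        fixture.matrix, "Specificity", "VH", fixture.scale, calibration.specs
    )
    pd.testing.assert_frame_equal(report.baseline, report.perturbed)
    assert report.stable
    assert report.rank_changes == []


def test_perturbation_recomputes_full_pipeline(fixture, calibration):
    report = perturb_weight(
        fixture.matrix,
        fixture.sensitivity_criterion,
        fixture.sensitivity_weight,
        fixture.scale,
        calibration.specs,
    )
    # flows stay internally consistent after the weight change
    assert report.perturbed["phi_net"].sum() == pytest.approx(0.0, abs=1e-9)
    assert report.old_weight == "VH" and report.new_weight == "H"
    # the dominant tracer cannot lose the top rank through re-weighting
    assert report.perturbed.at["[18F]RO-948", "rank"] == 1


@pytest.mark.parametrize("seed", [13, 14])
def test_dominant_alternative_immune_to_reweighting(seed):
    problem = generate_random_problem(5, 3, seed=seed)
    cells = problem.cells.copy()
    for j, crit in enumerate(problem.criteria):
        cells.iat[0, j] = "VL" if crit.is_cost else "VH"
    from tracerank import DecisionMatrix

    dominant = DecisionMatrix(problem.alternatives, problem.criteria, cells)
    for term in SCALE.terms:
        report = perturb_weight(
            dominant, problem.criteria[0].name, term, SCALE, PreferenceFunction("usual")
        )
        assert report.perturbed.at[problem.alternatives[0], "rank"] == 1


def test_unknown_criterion_rejected(fixture):
    with pytest.raises(KeyError):
        perturb_weight(fixture.matrix, "nope", "H", fixture.scale)


def test_sweep_covers_ladder(fixture, calibration):
    table = sweep_linguistic_weights(fixture.matrix, fixture.scale, calibration.specs)
    assert len(table) == len(fixture.matrix.criteria) * len(fixture.scale.terms)
    # perturbing to the current weight is always stable
    own = table[table["baseline_weight"] == table["candidate_weight"]]
    assert own["stable"].all()
    assert ((table["n_rank_changes"] == 0) == table["stable"]).all()


def brute_force_tau_b(a, b):
    """O(n^2) concordant/discordant pair count with tie corrections."""
    n = len(a)
    concordant = discordant = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(a)) * (n0 - _tie_term(b)))
    return (concordant - discordant) / denom


def _tie_term(x):
    from collections import Counter

    return sum(c * (c - 1) / 2 for c in Counter(x).values())


def test_rank_agreement_extremes():
    idx = list("abcde")
    r1 = pd.Series([1, 2, 3, 4, 5], index=idx)
    assert rank_agreement(r1, r1) == pytest.approx(1.0)
    assert rank_agreement(r1, r1[::-1].set_axis(idx)) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        rank_agreement(r1, pd.Series([1, 2], index=["a", "b"]))


def test_rank_agreement_matches_brute_force_on_published_rankings(fixture):
    """Kendall tau-b between the published baseline and sensitivity rank
    columns equals a direct concordant/discordant pair count."""
    base = fixture.baseline_reference["phi_net"].rank(ascending=False, method="min")
    pert = fixture.sensitivity_reference["phi_net"].rank(ascending=False, method="min")
    pert = pert.reindex(base.index)
    expected = brute_force_tau_b(base.to_numpy(), pert.to_numpy())
    assert rank_agreement(base, pert) == pytest.approx(expected, abs=1e-12)
    assert 0.9 < expected < 1.0  # near-identical rankings, one adjacent swap
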