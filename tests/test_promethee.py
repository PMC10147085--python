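"""Engine tests, including a naive triple-loop oracle for the flows."""

import numpy as np
import pandas as pd
import pytest

from tracerank import (
    Criterion,
    DecisionMatrix,
    crispify,
    default_scale,
    generate_random_problem,
    outranking_flows,
    preference_index,
    promethee1_relations,
    promethee2,
    promethee2_rank,
    signed_difference,
    unicriterion_net_flows,
)
from tracerank.preference import PreferenceFunction

PF = PreferenceFunction
SCALE = default_scale()

ORACLE_SPECS = [
    PF("usual"),
    PF("gaussian", s=0.3),
    PF("linear", q=0.1, p=0.5),
    PF("v_shape", p=0.4),
]


def naive_flows(crisp, spec):
    """Direct transcription of the flow definitions: explicit loops over
    alternative pairs and criteria."""
    alts = crisp.alternatives
    n = len(alts)
    w = crisp.weights
    pi = pd.DataFrame(0.0, index=alts, columns=alts)
    for t in alts:
        for u in alts:
            if t == u:
                continue
            total = 0.0
            for j in crisp.values.columns:
                total += w[j] * spec(signed_difference(crisp, t, u, j))
            pi.at[t, u] = total
    phi_plus = {t: sum(pi.at[t, u] for u in alts if u != t) / (n - 1) for t in alts}
    phi_minus = {t: sum(pi.at[u, t] for u in alts if u != t) / (n - 1) for t in alts}
    return pi, phi_plus, phi_minus


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("spec", ORACLE_SPECS, ids=lambda s: s.type)
def test_vectorized_flows_equal_triple_loop_oracle(seed, spec):
    rng = np.random.default_rng(seed)
    n_alts = int(rng.integers(3, 7))
    n_crit = int(rng.integers(1, 5))
    problem = generate_random_problem(n_alts, n_crit, seed=seed)
    crisp = crispify(problem, SCALE)
    pi_ref, plus_ref, minus_ref = naive_flows(crisp, spec)
    pi = preference_index(crisp, spec)
    flows = outranking_flows(pi)
    assert np.allclose(pi.to_numpy(), pi_ref.to_numpy(), atol=1e-12)
    for t in crisp.alternatives:
        assert flows.at[t, "phi_plus"] == pytest.approx(plus_ref[t], abs=1e-12)
        assert flows.at[t, "phi_minus"] == pytest.approx(minus_ref[t], abs=1e-12)


def test_preference_index_basic_cases():
    # identical rating vectors -> no preference either way
    m = DecisionMatrix(
        ["a", "b"], [Criterion("c1", "max", 1.0)], [["H"], ["H"]]
    )
    pi = preference_index(crispify(m, SCALE), PF("usual"))
    assert pi.at["a", "b"] == 0.0 and pi.at["b", "a"] == 0.0
    # single criterion, full weight, strict advantage -> 1 / 0
    m = DecisionMatrix(["a", "b"], [Criterion("c1", "max", 1.0)], [["H"], ["L"]])
    pi = preference_index(crispify(m, SCALE), PF("usual"))
    assert pi.at["a", "b"] == 1.0 and pi.at["b", "a"] == 0.0
    # two equally weighted criteria, one advantage each -> 0.5 / 0.5
    m = DecisionMatrix(
        ["a", "b"],
        [Criterion("c1", "max", 1.0), Criterion("c2", "max", 1.0)],
        [["H", "L"], ["L", "H"]],
    )
    pi = preference_index(crispify(m, SCALE), PF("usual"))
    assert pi.at["a", "b"] == pytest.approx(0.5)
    assert pi.at["b", "a"] == pytest.approx(0.5)
    assert np.diag(pi.to_numpy()) == pytest.approx([0.0, 0.0])


@pytest.mark.parametrize("seed", [7, 8, 9])
def test_net_flows_sum_to_zero(seed):
    problem = generate_random_problem(8, 3, seed=seed)
    flows = outranking_flows(preference_index(crispify(problem, SCALE), PF("gaussian", s=0.5)))
    assert flows["phi_net"].sum() == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(
        flows["phi_net"], flows["phi_plus"] - flows["phi_minus"], atol=1e-12
    )


def test_dominant_alternative_has_zero_negative_flow(fixture, calibration):
    crisp = crispify(fixture.matrix, fixture.scale)
    for spec in ORACLE_SPECS + [calibration.specs]:
        flows = outranking_flows(preference_index(crisp, spec))
        assert flows.at["[18F]RO-948", "phi_minus"] == 0.0
        assert flows.at["[18F]THK5105", "phi_plus"] == 0.0
        assert flows.at["[18F]THK5117", "phi_plus"] == 0.0
        assert promethee2_rank(flows).at["[18F]RO-948", "rank"] == 1


def test_promethee1_relations():
    flows = pd.DataFrame(
        {
            "phi_plus": [0.6, 0.6, 0.9, 0.1],
            "phi_minus": [0.1, 0.1, 0.5, 0.0],
        },
        index=["a", "b", "c", "d"],
    )
    rel = promethee1_relations(flows)
    assert (np.diag(rel.to_numpy()) == "self").all()
    assert rel.at["a", "b"] == "I" and rel.at["b", "a"] == "I"  # equal flows
    assert rel.at["c", "a"] == "R" and rel.at["a", "c"] == "R"  # both flows higher
    assert rel.at["a", "d"] == "R"  # a stronger but also weaker
    assert rel.at["c", "d"] == "R"
    # dominance in the flow pair
    flows2 = pd.DataFrame(
        {"phi_plus": [0.8, 0.2], "phi_minus": [0.0, 0.4]}, index=["x", "y"]
    )
    rel2 = promethee1_relations(flows2)
    assert rel2.at["x", "y"] == "P" and rel2.at["y", "x"] == "O"


def test_competition_ranking_with_ties():
    flows = pd.DataFrame(
        {
            "phi_plus": [0.5, 0.4, 0.4, 0.1],
            "phi_minus": [0.0, 0.1, 0.1, 0.5],
        },
        index=["w", "x", "y", "z"],
    )
    flows["phi_net"] = flows["phi_plus"] - flows["phi_minus"]
    ranked = promethee2_rank(flows)
    assert ranked["rank"].to_dict() == {"w": 1, "x": 2, "y": 2, "z": 4}


def test_two_alternative_ranking():
    m = DecisionMatrix(["a", "b"], [Criterion("c1", "max", 1.0)], [["VH"], ["L"]])
    ranked = promethee2(crispify(m, SCALE), PF("usual"))
    assert ranked["rank"].to_dict() == {"a": 1, "b": 2}


@pytest.mark.parametrize("seed", [21, 22])
def test_unicriterion_decomposition_reconstructs_net_flow(seed):
    problem = generate_random_problem(6, 4, seed=seed)
    crisp = crispify(problem, SCALE)
    spec = PF("gaussian", s=0.4)
    phi = unicriterion_net_flows(crisp, spec)
    net = outranking_flows(preference_index(crisp, spec))["phi_net"]
    recon = (phi * crisp.weights).sum(axis=1)
    assert np.allclose(recon, net, atol=1e-12)


def test_unicriterion_constant_column_is_zero():
    m = DecisionMatrix(
        ["a", "b", "c"],
        [Criterion("c1", "max", "H"), Criterion("c2", "max", "H")],
        [["H", "VH"], ["H", "L"], ["H", "M"]],
    )
    phi = unicriterion_net_flows(crispify(m, SCALE), PF("usual"))
    assert (phi["c1"] == 0.0).all()


def test_unicriterion_dominant_alternative_nonnegative(fixture):
    crisp = crispify(fixture.matrix, fixture.scale)
    phi = unicriterion_net_flows(crisp, PF("usual"))
    assert (phi.loc["[18F]RO-948"] >= 0).all()


@pytest.mark.parametrize("seed", [31, 32])
def test_single_cell_improvement_never_hurts(seed):
    """Raising one rating on a maximize criterion cannot lower the
    alternative's net flow (preference functions are nondecreasing)."""
    scale = SCALE
    problem = generate_random_problem(6, 3, seed=seed)
    crisp = crispify(problem, scale)
    terms_desc = scale.terms  # best first
    for spec in (PF("usual"), PF("gaussian", s=0.5)):
        base = outranking_flows(preference_index(crisp, spec))["phi_net"]
        for j, crit in enumerate(problem.criteria):
            if crit.is_cost:
                continue
            cells = problem.cells.copy()
            current = cells.iat[0, j]
            pos = terms_desc.index(current)
            if pos == 0:
                continue  # already the top term
            cells.iat[0, j] = terms_desc[pos - 1]
            improved = DecisionMatrix(problem.alternatives, problem.criteria, cells)
            net2 = outranking_flows(
                preference_index(crispify(improved, scale), spec)
            )["phi_net"]
            alt = problem.alternatives[0]
            assert net2[alt] >= base[alt] - 1e-12


def test_insufficient_alternatives_rejected():
    m = DecisionMatrix(["only"], [Criterion("c1", "max", 1.0)], [["H"]])
    with pytest.raises(ValueError, match="two alternatives"):
        preference_index(crispify(m, SCALE), PF("usual"))
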