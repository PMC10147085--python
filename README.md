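# tracerank

Fuzzy multi-criteria decision analysis for ranking alternatives rated on
linguistic scales — built around fuzzy PROMETHEE I/II with Yager-index
defuzzification, with weighted-sum and TOPSIS comparators, one-at-a-time
weight sensitivity analysis, and a bundled tau PET radiotracer case study.

## The problem

Choosing a radiotracer for tau PET imaging (or any option from a set of
candidates judged on several conflicting criteria) is a multi-criteria
decision problem. Evidence about candidate tracers — specificity for tau
over other proteins, target binding affinity, brain uptake/penetration,
rates of adverse reactions — is mostly qualitative, so evaluations are
expressed on a five-term linguistic ladder (VH, H, M, L, VL). Each term maps
to a triangular fuzzy number (l, m, r) on [0, 1]; the Yager index

    F(x) = (3N − a + b) / 3,   N = mode,  a = N − l,  b = r − N

collapses it to a crisp value (VH → 0.9167, H → 0.75, M → 0.5, L → 0.25,
VL → 0.0833).

PROMETHEE then compares alternatives pairwise. For each criterion *k* with
normalized weight *w_k* and preference function *P_k*, the preference index

    π(a, b) = Σ_k w_k · P_k(d_k(a, b))

aggregates the oriented advantages *d_k* of *a* over *b*. Averaging over
opponents gives the positive flow Φ⁺ (strength), negative flow Φ⁻
(weakness), and net flow Φ = Φ⁺ − Φ⁻; PROMETHEE II ranks by net flow with
competition ranking for ties, and PROMETHEE I yields a partial order with
explicit incomparabilities. TOPSIS (closeness to the ideal vs anti-ideal
point) and a sum-normalized weighted-sum score serve as cross-checks, and a
one-at-a-time weight sensitivity analysis probes ranking stability.

All six standard preference functions (usual, U-shape, V-shape, level,
linear, Gaussian) are supported, plus a monotone *staircase* generalization
(piecewise-constant levels at arbitrary thresholds) used by the replication
calibration.

## Worked example

Rank the bundled 15-tracer dataset with the strict (usual) preference
function:

```bash
tracerank rank --matrix fixture --method promethee
```

```
              phi_plus  phi_minus  phi_net  rank
alternative
[18F]RO-948     0.7162     0.0000   0.7162     1
[11C]RO-643     0.6236     0.0811   0.5425     2
[11C]RO-963     0.6236     0.0811   0.5425     2
[18F]MK-6240    0.5463     0.0849   0.4614     4
...
[18F]THK5105    0.0000     0.7432  -0.7432    14
[18F]THK5117    0.0000     0.7432  -0.7432    14
```

[18F]RO-948 is rated weakly best on every criterion, so its negative flow
is exactly zero and it ranks first under *any* valid configuration;
THK5105/THK5117 are weakly worst, with zero positive flow. RO-643 and
RO-963 carry identical ratings and share rank 2 (competition ranking).
A weight perturbation report:

```bash
tracerank sensitivity --criterion Specificity --weight H
# ...
# ranking stable: no rank changes
```

The same pipeline is available as a library:

```python
from tracerank import load_fixture, crispify, promethee2
fx = load_fixture()
flows = promethee2(crispify(fx.matrix, fx.scale))
```

Any decision problem can be supplied as a matrix CSV (header of criterion
names, `aim` and `weight` rows, then one row per alternative) plus optional
scale/criteria JSON or YAML configs; see `tracerank rank --help`.

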