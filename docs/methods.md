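# Methods

## Model and pipeline

The package ranks alternatives evaluated on criteria whose ratings and
importance weights are linguistic terms, crisp numbers, or a mixture.

1. **Fuzzification.** Each linguistic term maps to a triangular fuzzy
   number (TFN) on [0, 1]. The shipped five-term ladder is
   VH (0.75, 1, 1), H (0.5, 0.75, 1), M (0.25, 0.5, 0.75), L (0, 0.25, 0.5),
   VL (0, 0, 0.25); any ordinally consistent scale can be supplied as
   JSON/YAML. Crisp cells are modeled as degenerate TFNs so every value
   follows one code path.

2. **Defuzzification.** The Yager index F = (3N − a + b)/3 (N the mode,
   a/b the left/right spreads) converts TFNs to crisp values. It uses all
   three vertices, equals the mode for symmetric triangles, and is applied
   uniformly to ratings *and* weights — no other crisp conversion exists in
   the pipeline. Weights are then normalized to sum to one, which keeps
   the preference index π in [0, 1].

3. **PROMETHEE.** Pairwise advantages are oriented so that a positive
   difference always means "row better than column" (sign flip for
   minimize criteria; the data are never transformed). Preference
   functions map advantages to degrees in [0, 1]; flows average preference
   indices over the n − 1 opponents. PROMETHEE II ranks by net flow;
   PROMETHEE I classifies pairs as preferred / outranked / indifferent /
   incomparable from the two flows, with equality at absolute tolerance
   1e−12. Rank ties are detected on net flows rounded to 4 decimals (the
   reporting precision), and ranking is competition style ("1, 2, 2, 4").
   The unicriterion decomposition φ_k(t) satisfies Φ(t) = Σ_k w_k φ_k(t)
   exactly and feeds the strengths/weaknesses bar chart.

4. **Comparators.** The weighted-sum method converts cost criteria by
   complementation v → 1 − v on the defuzzified [0, 1] scale, then
   normalizes scores to sum to one. TOPSIS applies per-column vector
   normalization, weights, takes the per-criterion best (max for benefit,
   min for cost) as the ideal point and the worst as the anti-ideal, and
   reports closeness C = D⁻/(D⁺ + D⁻) ∈ [0, 1] (defined as 0.5 in the
   degenerate all-identical case). Both convention choices sit behind
   named flags (`cost_handling`, `normalization`) because the method
   definitions leave them open; the defaults are the conventions selected
   by the replication search (below).

5. **Sensitivity.** One-at-a-time weight perturbation re-runs the whole
   pipeline (re-defuzzify, re-normalize, re-rank) and reports rank moves;
   a sweep over the linguistic ladder per criterion gives empirical
   stability ranges. Ranking agreement is summarized by Kendall tau-b.

## Preference functions

The six standard shapes are implemented exactly: usual (step at 0),
U-shape (step at q), V-shape (linear to p), level (0/½/1), linear
(0/(d−q)/(p−q)/1), Gaussian (1 − exp(−d²/2s²)). All are nondecreasing,
zero for non-positive advantages, and bounded by 1. A seventh *staircase*
shape — piecewise-constant monotone levels at arbitrary thresholds — is a
strict generalization of the level function. It exists because plateau
preference values at levels other than ½ and 1 are unreachable by the six
standard shapes, and the case-study calibration needs them (below). It is
a legitimate preference function (monotone, [0, 1], zero for d ≤ 0) and is
available to users like any other type.

## The case study and its calibration

The bundled dataset rates 15 tau PET radiotracers on specificity (weight
VH), target binding affinity (H), brain uptake and penetration (VH), and
adverse reactions (M, minimized). Its published results comprise a
baseline PROMETHEE flow table, a sensitivity flow table after changing
the specificity weight VH → H, and a weighted-sum/TOPSIS comparison; the
preference functions and thresholds used were not published. The
calibration harness recovers a configuration from the printed numbers.

**What the printed tables admit.** Because flows are linear in the
preference values attained at the finitely many rating gaps, linear
programming over monotone per-gap values settles exactly what any valid
configuration can reproduce:

- No single preference function shared across criteria can reproduce the
  published baseline rank order (the LP is infeasible even with free
  monotone values). Per-criterion configurations can.
- The printed flow values cannot be hit exactly by *any* monotone
  configuration: the best achievable maximum net-flow deviation is about
  0.0013 (an exact fit would require non-monotone preference values).
- The published sensitivity table swaps two mid-field tracers
  ([11C]PBB3 and [18F]THK5351). Both carry the same specificity rating,
  so their unicriterion specificity flows are identical, and changing the
  specificity weight rescales their net-flow difference by a positive
  factor — the sign can never flip. The published swap is therefore
  unreachable under the published dataset, for every preference
  configuration and weight convention.
- A single-cell variant of the dataset (PBB3's specificity M instead of H)
  makes the baseline, sensitivity *and* comparison tables simultaneously
  consistent to roughly print precision. This points to a transcription
  inconsistency in the published dataset. The bundled fixture remains the
  dataset as published; the package reproduces what it admits and reports
  the rest as residuals.

**Calibration algorithm** (deterministic, no randomness):

1. *Shared grid search* over the six standard types × a threshold grid
   (0.05 … 2.0, step 0.05), scored lexicographically by (rank-order
   inversions vs the published baseline, maximum absolute net-flow
   deviation). Reported for diagnosis.
2. *Staircase fit.* One staircase per criterion, levels at the rating
   gaps occurring in the data, fitted by two LPs: stage A minimizes the
   worst net-flow deviation subject to monotone levels, the published
   rank order with a margin of 1.05e−4 (one unit of reporting precision,
   so rounding cannot merge distinct ranks), and stability of that order
   under the published weight perturbation — mirroring the study's own
   robustness conclusion without fitting to the sensitivity flows; stage
   B minimizes the summed deviations with the worst case capped. The
   result reproduces the complete published baseline ranking (both tied
   pairs included) with a maximum net-flow deviation of about 0.0016, and
   the sensitivity ranking in all positions except the unreachable swap.

The published ranks list the two identically rated bottom tracers as 14
and 15 despite identical flows; competition ranking necessarily yields
14/14, and order comparisons treat the pair as tied.

**Score conventions.** The weighted-sum and TOPSIS definitions leave cost
handling and normalization open. The harness enumerates the small
convention space (complement vs negate for weighted sum; vector vs no
normalization × min-is-ideal vs complement for TOPSIS) and selects the
convention minimizing the maximum deviation from the published columns:
complementation for the weighted sum, vector normalization with
min-is-ideal for TOPSIS. Under these, the published TOPSIS column is
matched to within 0.004 for 14 of 15 tracers and the weighted-sum column
to within 0.009 (the exception is again PBB3, consistent with the data
caveat above). The forced endpoints — closeness 1 for the componentwise
weakly dominant tracer, 0 for the weakly dominated ones — hold exactly
under every convention.

## Synthetic problems

`generate_random_problem` draws cells uniformly from the linguistic
ladder, weights uniformly from the ladder, and directions maximize with
probability 3/4 (matching the benefit-heavy composition typical of
evaluation criteria; the case study uses 3 of 4). It emulates the
*structure* of linguistic decision problems — it does not emulate
correlated criteria, expert disagreement, or missing ratings, so passing
property tests on generated problems demonstrates algebraic correctness
of the engines, not robustness to real-world elicitation noise.

## Numerical choices

- Flow equality (PROMETHEE I) at absolute tolerance 1e−12; rank-tie
  detection on 4-decimal rounded net flows.
- Staircase threshold lookup tolerates 1e−9 of float noise, since
  thresholds are derived from differences of scale values.
- Degenerate inputs: fewer than two alternatives, all-zero weights, empty
  calibration grids, and malformed TFNs/scales raise informative errors;
  identical rating vectors are allowed (the case study contains two such
  pairs) while duplicate alternative *labels* are rejected at load time.
- LP solves use scipy's HiGHS backend; the two-stage scheme (min–max then
  capped L1) pins down an otherwise degenerate optimum deterministically.

## Problem sizes

Everything here is desk scale: the case study is a 15 × 4 matrix, the
calibration grid has ~1,700 candidates, and the LPs have a dozen
variables; the full test suite and the acceptance script each run in
seconds on one CPU. Property tests use random problems of 3–8
alternatives and 1–4 criteria, sizes at which the triple-loop oracle is
exact and instant.

## Known limitations

- The calibration recovers *a* configuration consistent with the
  published ordering, not necessarily *the* one used originally; the
  per-alternative flow residuals quantify the remaining gap, and the
  printed-data inconsistency above bounds what any reconstruction can
  achieve.
- Only one-at-a-time weight perturbations are implemented; analytic
  stability intervals and walking-weights analyses are out of scope, as
  are fuzzy-flow PROMETHEE variants (defuzzification happens before
  ranking, as in the case study) and criteria hierarchies or group
  weighting.
- Alternative defuzzifiers (centroid, mean-of-maxima) are not provided;
  the Yager index is the single supported bridge from fuzzy to crisp.
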