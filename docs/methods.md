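# Methods

## Scoring model

All three instruments operate on the same nine-item encoding of the
painDETECT questionnaire: seven sensory grades g_i ∈ {0,…,5}, a course-
pattern score c ∈ {0, −1, +1, +1} (persistent with slight fluctuations,
persistent with attacks, attacks without pain between them, attacks with
pain between them), and a radiating score r ∈ {0, 2}. The PD-Q total is
Σg_i + c + r ∈ [−1, 38]. A weighted instrument computes

    total = Σ w_i·g_i + w_course·c + w_rad·r − constant,

and screens positive at total ≥ cutoff. The built-in SPDQ
(w = +1,+2,−2,−4,−3,+8,+1; w_course = 0; w_rad = +1; constant 12) and
SF-SPDQ (electric shock ×(−4), numbness ×(+9); constant 7) both use
cutoff ≥ 0. Scoring is exact integer arithmetic throughout.

Missing responses follow a complete-case rule *per instrument*: a record
missing any required item yields no total for that instrument but may still
be scorable by another (the SF-SPDQ needs only two items). The SPDQ
requires the course-pattern item even though its weight is zero: the
published scoring form includes it, and requiring it keeps "complete SPDQ"
aligned with the validation study's accounting of analyzable respondents.
Out-of-range grades are rejected, never clamped; silent clamping would
mask data-entry faults.

## Development pipeline

**Discriminant weighting.** For a labeled cohort the raw item coefficients
are the two-group Fisher (canonical) discriminant direction
w ∝ W⁻¹(μ_case − μ_control), with W the pooled within-group scatter. This
maximizes the ratio of between- to within-group variance of the projected
scores. A (near-)singular W is a hard error with advice to drop collinear
items; an optional ridge term (a multiple of mean(diag W) on the diagonal)
is available but off by default — regularization changes the estimand and
should be a deliberate choice. Identical group means are flagged degenerate.

**Integerization.** A hand-scorable instrument needs small integer weights.
The raw direction d is scaled by c > 0 and rounded, where c minimizes the
relative rounding error ‖c·d − round(c·d)‖/‖c·d‖ subject to
max|round(c·d)| ≤ 9 (the cap matching the largest built-in weight). Among
equally good scales the largest is taken, using the full available integer
resolution. The scan covers every scale mapping some coefficient to an
integer plus a dense grid. The published instruments' own raw-to-integer
rule was never stated; this is one defensible reconstruction, and the
built-in weights are shipped as fixed constants rather than re-derived.

**Cutoff.** Candidate thresholds are the observed score values with
positivity rule score ≥ t; the chosen t maximizes sensitivity +
specificity, ties breaking toward the lowest threshold (a screening tool
favors sensitivity). The threshold is folded into the instrument as a
subtracted integer constant (round(t)), so the deliverable rule is always
"positive at ≥ 0" — the same convention that produced the constants 12
and 7.

**Stepwise selection.** Short-form items are chosen by stepwise
discriminant analysis on the partial F statistic derived from Wilks'
lambda: for two groups, F = (Λ_S/Λ_{S∪{v}} − 1)(n − 2 − |S|) on
(1, n − 2 − |S|) degrees of freedom. Items enter at p ≤ 0.15 (largest F
first; ties by input order) and are removed at p > 0.15, worst first —
the conventional defaults of stepwise discriminant procedures. Forward-only
mode is available. A revisited selected-set state terminates the loop,
guarding enter/remove cycles. With entry significance 0.15 and many
uninformative candidates, occasional spurious entries are *expected*
(roughly one per run under the null); the meaningful recovery property is
that truly informative items enter first and dominate the final weights.

**A known bias worth stating.** When labels are generated by thresholding a
linear score of the items (as in the recovery harness), the Fisher
direction is *not* a consistent estimator of the generating weights:
conditioning on a threshold deflates within-class variance anisotropically,
tilting the recovered ratio of the two SF-SPDQ weights to ≈2.9 rather than
9/4 = 2.25 (measured by simulation at n = 200 000; it approaches 2.25 only
as label noise grows). The pipeline's recovery guarantees are therefore
stated in terms of sign pattern, dominance order and item identity, not
exact weight ratios.

## Evaluation statistics

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp), NPV
tn/(tn+fn), LR+ = sens/(1−spec), LR− = (1−sens)/spec are computed as exact
rationals from integer counts; display views round half-up to one decimal
(percents and ratios), the convention needed to reproduce the published
tables digit-for-digit (e.g. 25/29 → 86.2; 0.8621/0.3125 → 2.8). A metric
with zero denominator is reported as "undefined", never silently NaN.

The AUC is the tie-aware Mann–Whitney estimator
P(score_case > score_control) + ½P(tie), computed from midranks. Integer
questionnaire scores tie often; the tie-unaware pair count would understate
the area. Whether the original analyses tie-corrected is unknown; the
tie-aware choice is the defensible default.

Cohen's kappa is computed on the binary positive/negative classifications
of two administrations, κ = (p_o − p_e)/(1 − p_e), with bands ≤0.20 poor,
≤0.40 fair, ≤0.60 moderate, ≤0.80 good, else very good (the published
bands leave (0.20, 0.21) unassigned; closed upper edges resolve it, and
negative κ is poor). Degenerate marginals (p_e = 1) give an undefined κ,
flagged. No confidence intervals are produced by default, matching the
original reporting.

## Synthetic cohorts

The generator draws each field of each group independently from categorical
marginals. The built-in profiles are the published response-count tables of
the two validation cohorts: `multicenter` (29 cases / 16 controls; missing
responses — one case for cold/heat and course pattern, four cases and three
controls for radiating — renormalized over observed counts) and `websurvey`
(250/250, complete). Group sizes default to these nominal values.

Published tables constrain only marginals, so independence is the default
dependence model. A Gaussian copula with user-chosen equicorrelation ρ is
available to mimic correlated symptom reporting; any ρ is an assumption,
not a published value. Missingness can be re-injected at a per-field rate.

Reproducibility: each (group, field) pair owns a dedicated substream seeded
as SeedSequence([master_seed, group_index, field_index]), so draws for one
item do not depend on the order or presence of others; the copula adds one
latent stream per group.

What passing simulation tests shows — and does not: cohorts sampled from
these profiles match the real cohorts item by item in distribution, so
marginal-driven quantities (per-item proportions, approximate operating
points of marginal-dominated scores) transfer well; joint structure
(inter-item correlation, per-patient score distributions, AUCs that depend
on it) is *not* constrained by the published tables, so agreement there is
suggestive, not evidential.

**Recovery harness.** Items are sampled from a profile, a known instrument
scores each record, Gaussian noise (default SD 3.0 score points, ≈⅓ of the
web-cohort SF-SPDQ score SD — "low" noise) is added, and the sign of the
noisy score assigns the label; the development pipeline then runs on one
half and is judged on the other. The headline property: over 50 seeded runs
at n = 500/group the two largest-|weight| items of the developed instrument
are exactly {numbness, electric shock} in ≥ 90% of runs. Permuting labels
gives the null harness: near-empty selections and held-out AUC ≈ 0.5.

## Problem sizes and numerical choices

Simulation-based tests use the smallest sizes at which the checked property
is stable: goodness-of-fit at n = 100 000 per group (χ², α = 0.001),
recovery at 50 seeds × 1 000 records, null harnesses at 8–10 seeds. The
full suite runs in seconds; the acceptance script in under a minute.
Threshold scans and integer scoring are exact; the only floating-point
steps are the scatter solve, the F-tail probabilities and the AUC ranks.

## Limitations

* The original development cohort (85/45) was never published at patient
  level; the built-in weights are constants, and the pipeline's fidelity to
  the original derivation is validated on synthetic data only.
* Real-cohort sensitivities, specificities, AUCs, mean scores and the
  published κ = 0.5 cannot be recomputed from printed information; only
  PPV/NPV/LR (which follow arithmetically from printed counts) are
  reproduced exactly.
* Independence across items is a modeling choice forced by the published
  marginals; real symptom items correlate, and copula ρ is user-supplied.
* The instruments screen; they do not diagnose. Nothing here implements
  the clinical grading system used as the gold standard.
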