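# Methods

## Scope and model

`liverdss` implements a comparison pipeline for four rule-based difficulty
scoring systems (DSS) used to grade laparoscopic liver resections (LLR):
Halls (Southampton), Hasegawa, Kawaguchi (IMM), and the Iwate score (the
consensus revision of the Ban score). Each DSS maps pre/intra-operative
features — resection extent, tumor size and location, liver status, patient
history — to an ordinal difficulty class. The pipeline scores a cohort,
binarizes peri-operative outcomes, evaluates three composite measures, and
compares the scores through rank concordance, per-class logistic odds
ratios, and random-forest permutation importance.

## Scoring rules

Point values and class bins follow the published schemes:

- **Halls** (0–15): major resection 4; anatomical resection of one or two
  segments including a posterosuperior segment 2; tumor 3–5 cm 2, >5 cm 3;
  malignant 2; previous open liver resection 5; neoadjuvant chemotherapy 1.
  Classes: low ≤2, moderate 3–5, high 6–9, extremely high 10–15.
- **Hasegawa** (0–7): wedge/left lateral sectionectomy 0, segmentectomy 2,
  major 3; location S7–8 2, S5–6 1, S2–4 0; BMI ≥30 1; platelets ≤100×10⁹/L
  1. Classes: low ≤1, medium 2–3, high ≥4.
- **Kawaguchi**: group I wedge/LLS; group II left hepatectomy and
  anterolateral segmentectomy; group III posterosuperior segmentectomy and
  right/central/extended hepatectomy.
- **Iwate** (0–12): size ≥3 cm 1; location 1–3 points (anterolateral) or
  4–5 (posterosuperior), maximum over involved segments; extent wedge 0,
  LLS 2, segmentectomy 3, sectionectomy and more 4; vessel proximity 1;
  Child–Pugh B 1; hybrid/hand-assisted −1 (total clamped at 0). Classes:
  low ≤3, intermediate 4–6, advanced 7–9, expert 10–12.

Design choices where the published rules are silent or ambiguous:

- **Segment vocabulary.** Segment 4 is split into 4a/4b because only 4a is
  posterosuperior; a bare "4" in input expands to 4b (configurable). The
  posterosuperior set defaults to {1, 4a, 7, 8} and is configurable.
- **Iwate location weights.** Only the ranges (anterolateral 1–3,
  posterosuperior 4–5) are fixed by the scheme; the per-segment default
  table is S3=1, S2=S6=2, S4b=S5=3, S1=S4a=4, S7=S8=5, adapted from the
  published consensus table, and lives in `SegmentConfig`. Configurations
  violating the ranges are rejected.
- **Major hepatectomy.** Brisbane definition — at least three contiguous
  segments — evaluated on a whole-segment anatomical adjacency graph
  (4a/4b count as one segment), plus the named hemi-/extended/central
  hepatectomies.
- **Halls 2-point tier.** Awarded to non-major anatomical resections of
  ≤2 segments only when a posterosuperior segment is involved (the literal
  reading); a configuration switch extends it to all small anatomical
  resections.
- **Bin gaps.** Halls score 2 and Iwate score 0 are not covered by the
  published bins; both map to "low" (Halls upper bound configurable).
- **Unlisted combinations.** Hasegawa: non-LLS sectionectomies score the
  segmentectomy tier (2) unless major; segment 1 carries 2 location points
  (treated as difficult). Kawaguchi: non-LLS sectionectomies are III when a
  posterosuperior segment is involved, else II. Benign disease contributes
  0 tumor-type points.
- **Multiple resections.** Each score takes its maximum over the targets of
  a procedure ("most challenging one"), independently per score.
- **Collapsing.** For cross-score comparison the two top classes of the
  four-class systems (Halls high/extremely high, Iwate advanced/expert) are
  merged, giving 3-level ordinals for all four scores.

## Outcomes

Dichotomies use inclusive favorable boundaries: operative time ≤240 min,
blood loss ≤500 ml, stay ≤5 days; complications Clavien–Dindo ≥1 (any) and
≥3 (severe). Composites: operative outcome = no conversion ∧ time ≤240 ∧
loss ≤500; postoperative outcome = no complication ∧ stay ≤5 d; textbook
outcome = Satava ≤ I ∧ Clavien–Dindo ≤ II ∧ stay ≤ 75th percentile of the
series ∧ R0 ∧ no 90-day readmission/mortality. The 75th percentile is
nearest-rank (type 1): the smallest observed stay with cumulative
proportion ≥ 0.75 — stated explicitly because stays are integers and
interpolating definitions disagree. The fixed 5-day threshold and the
percentile threshold are deliberately separate parameters; they need not
coincide.

## Synthetic cohorts

`generate_cohort` emulates a single-center LLR registry. Baseline features
are drawn independently from configured marginal frequencies (defaults:
male 0.581, age ≥65 0.537, BMI ≥25 0.564, ASA 3–4 0.329, cirrhosis 0.344,
platelets ≤100 0.127, malignant 0.826, portal hypertension 0.182,
neoadjuvant chemotherapy 0.13, Child–Pugh B 0.033, and comorbidity rates of
the same order). Resection targets come from a configurable type mix with
anatomically coherent segment sets; 10% of patients receive a second wedge
target, exercising the most-challenging-resection rule.

Difficulty effects are injected through the features themselves: each
binary outcome is Bernoulli with
`logit p = b + β·(collapsed Kawaguchi level − 1)`. The per-level log odds
ratio β is configurable per outcome (defaults around 0.5–1.0 for operative
endpoints, 0 for margin/readmission/mortality). Intercepts are solved at
generation time by Brent root-finding on the realized level distribution so
that the cohort prevalence equals the configured target (conversion 8.1%,
prolonged stay 39.3%, …) for any effect size; an explicit `baseline_logit`
override bypasses the solve. Continuous outcomes (time, loss, stay) are
drawn from flag-conditioned discretized log-normal/uniform families, so
binary flags never contradict their underlying values; Clavien–Dindo grades
are drawn consistently with the complication flags and mortality forces
grade 5. Overall-complication draws use an independence decomposition
(severe ∨ extra), so the union hits the overall target in expectation.

Randomness: one root seed; each variable has a named sub-stream
(`SeedSequence([seed, crc32(name)])`), so adding a variable never perturbs
existing draws and regeneration under a fixed (config, seed) is
byte-identical.

What the generator does **not** emulate: joint dependence among baseline
features beyond the difficulty link (e.g. cirrhosis–platelet coupling),
inter-center or learning-curve drift, and any real joint distribution of
resection type with tumor biology. Passing tests therefore demonstrate that
the machinery recovers known structure from data of this form, not that the
generator reproduces any particular patient population.

## Statistical machinery

- **Concordance**: pairwise Spearman ρ with average ranks for ties,
  computed on the collapsed 3-level ordinals by default (a switch selects
  native classes, since either convention is defensible). Zero-variance
  scores yield NaN entries, flagged rather than fabricated.
- **Odds ratios**: one logistic model per score and endpoint (nine
  endpoints: five single outcomes and failure of the three composites),
  indicator-coded against the lowest class — scores are never adjusted for
  one another. Newton ML with fall-back to L-BFGS under perfect separation;
  convergence requires the optimizer flag, no zero/all-event class, and all
  class standard errors ≤50 on the log-odds scale. Non-converged rows keep
  the point estimate and Wald p but report undefined intervals, matching
  how separated fits are conventionally displayed. Intervals are
  `exp(β ± 1.96·SE)`; no multiplicity correction is applied. The pooled
  per-level OR (inverse-variance combination of per-class contrasts divided
  by their level distance) summarizes recovery of a linear-in-level effect.
- **Importance**: classification random forests (500 trees, √p features
  per split) with out-of-bag permutation importance — per tree, the
  accuracy drop on that tree's out-of-bag rows when one predictor is
  permuted, averaged over trees; deterministic given the seed, ties broken
  by variable name. The endpoint set is binary and uncensored, so
  classification mode is the primary interpretation; a regression-mode
  switch is exposed in the settings object for sensitivity checks.
  Candidate predictors: the four collapsed scores plus BMI, ASA, sex,
  liver histology (indicator-expanded), cardiologic/vascular comorbidity,
  chronic kidney disease, diabetes, and portal hypertension.

## Problem sizes and numerical checks

Deterministic guarantees are verified by enumeration (≈24k-point discrete
feature domain for score extrema and monotonicity) and closed forms (2×2
ML odds ratio vs the cross-product estimator to 6 significant figures;
Spearman vs a direct average-rank oracle up to n=200). Stochastic
guarantees use fixed seed panels: injected per-level OR 4 recovered within
±15% in ≥90% of 20 replicates at n=20,000, and a single informative score
ranked first by the forest in ≥95% of 20 replicates at n=5,000 with 500
trees. These sizes make the checks sharp while keeping the whole suite in
the minutes range on one CPU.

## Known limitations

- The scoring engines reproduce the published point schemes, not the
  original derivation cohorts; parses of under-specified rules are explicit
  configuration, so sensitivity to them can be tested but defaults remain
  choices.
- Separation handling reports Wald p values from divergent fits for
  display compatibility; these are not calibrated test statistics (a
  penalized-likelihood fit would be the inferential fix and is out of
  scope).
- The generator's independence assumptions understate real feature
  collinearity; concordance magnitudes among generated scores are
  structural (shared resection features), not fitted to any target values.
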