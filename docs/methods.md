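# Methods

## The screening model

A playback-device screening test presents a participant with T short
perceptual trials (default T = 6). Each trial response either is or is not
consistent with the headphone percept; the test calls a participant
*positive* (a headphone user) when the number of headphone-indicating
responses reaches a threshold t ∈ {1..T}. Against the true device this
yields the four confusion cells (TP/FN/TN/FP), from which

* sensitivity Sen = TP/(TP+FN) — the hit rate among true headphone users,
* specificity Spe = TN/(TN+FP) — the correct-rejection rate among true
  loudspeaker users,

are intrinsic to the test, while the predictive values

* PPV = Sen·π / (Sen·π + (1−Spe)(1−π)),
* NPV = Spe·(1−π) / ((1−Sen)·π + Spe·(1−π)),

depend on the headphone prevalence π of the screened population. The
overall utility U = π·Sen·U_TP + π(1−Sen)·U_FN + (1−π)·Spe·U_TN +
(1−π)(1−Spe)·U_FP weighs the four outcome probabilities by desirabilities
in [0, 1]; the default weights (1, 0, 1, 0) make U the probability of a
correct classification. Lowering the threshold t never decreases Sen and
never increases Spe, which is what the ROC module exploits.

All proportions get Wilson score confidence intervals (the "score interval"
recommended by Agresti & Coull), computed with the exact normal quantile
z = Φ⁻¹(1 − α/2); at the printed one-decimal precision this is
indistinguishable from z = 1.96. Displayed percentages round halves up
(96.25 → 96.3), matching how such tables are conventionally printed;
internal computation is at full precision. An empty truth group makes
Sen/Spe an error rather than 0 — it signals malformed input.

## ROC and AUC

Each threshold contributes one operating point (1−Spe, Sen). The empirical
curve is anchored at (0,0) and (1,1) — the always-negative and
always-positive rules — sorted by false-alarm rate (hit rate as tie-break),
deduplicated, and integrated trapezoidally. No convex-hull or binormal
smoothing is applied: the AUC is that of the raw empirical polygon.
Anchoring is required: the packaged tables only reproduce the published AUC
values (.768/.844/.807 main study; .642/.735 pre-study) with both anchors
included.

The packaged fixtures store printed one-decimal percentages; loading
reconstructs the integer cell counts as round(pct/100 × group size) and
verifies the count re-prints to the stored percentage. ROC integration runs
on these count-based proportions. This choice is deliberate: integrating
percentages rounded to three decimals instead gives .769 for the main-study
Test A, while count reconstruction reproduces all five published AUCs
exactly. (The packaged tables' printed CI bounds were evidently computed
from the rounded percentages — they deviate from count-based Wilson
intervals by up to 0.1 percentage points; `score_ci` stays count-based.)

## Combining tests by weighted vote

Up to three tests run in parallel and are fused by a vote
G(A, B, C) = 1 iff ω_A·A + ω_B·B + ω_C·C ≥ 1. Weights are exact
`fractions.Fraction`s so the comparison with 1 never hits floating-point
ties. The catalogue holds the 18 logically distinct sensible rules — 3
singles, AND and OR for each of the 3 pairs, and for the triple: OR,
majority (½,½,½), AND (⅓,⅓,⅓), the three (X∨Y)∧Z rules (¼,¼,¾) and the
three (X∧Y)∨Z rules (½,½,1) — each under an *evaluation key* (EK). Only a
few EK numbers are externally anchored (6 = B AND C, 11 = majority,
12 = three-way AND, 13 = (A∨B)∧C); the rest of the numbering is a package
convention and can be remapped via `enumerate_combiners(ek_map=...)`.
Crossing the catalogue with per-test thresholds gives 3T + 6T² + 9T³
procedures — 2,178 at T = 6.

Combined characteristics are computed two ways:

* **Product rule** (`combine_independent`) — valid under conditional
  independence of the tests given the true device: within each device
  stratum the probability of an outcome tuple is the product of per-test
  marginals, and combined Sen/Spe sum these over tuples the vote calls
  positive/negative.
* **Empirical** (`combine_empirical`) — the ensemble is treated as a single
  test on item-level data; this is the fallback when independence fails.

Conditional independence of two dichotomized tests within a device stratum
is tested on the 2×2 table with a chi-square test (no continuity correction
by default, exposed as an option) at α = .10 — deliberately high because
the *null* is the hypothesis of interest and the type-II error is the one
to guard against. When any expected cell count falls below 5 an exact
multinomial test replaces it: null cell probabilities are the products of
the observed margins and the p-value sums the probabilities of all tables
with the same total that are no more probable than the observed one. Full
enumeration of that table space is O(n³), so above n = 200 the p-value is
estimated from 200,000 seeded Monte-Carlo tables drawn from the null —
reproducible and accurate to ±0.002 at p ≈ .10. A table with a constant
margin is flagged degenerate (independence not rejectable) rather than
tested. `combine()` checks every involved pair in both strata when
item-level data are present and either falls back to the empirical route or
refuses (`on_dependence="raise"`).

## Strategies and sample-size planning

Three recruitment strategies are modelled (target device: headphones by
default; choosing loudspeakers swaps Sen↔Spe and replaces π by 1−π):

* **FWR** — screen without disclosing the required device; accept
  test-positives. The success probability of an accepted participant is the
  PPV at the undisturbed prevalence π̂.
* **FAR** — request the device, then screen; the PPV is evaluated at the
  caller's post-request prevalence estimate.
* **SCC** — split by self-report (D1 = reported users, taken at face value
  under the unbiased-self-report assumption), prompt D0 to switch
  (each non-user switches with probability ς), screen only D0, and accept
  D1 ∪ D0⁺. The success probability is
  p̃ = (π̂ + (1−π̂)·ς̂·Sen) / (π̂ + (1−π̂)(ς̂·Sen + (1−ς̂)(1−Spe))).

The number of true users H in an accepted sample of size n is
Binomial(n, p) with p the strategy's success probability — exact, because
acceptance and truth are i.i.d. across recruits. Planning inverts
ϑ ≤ P(H ≥ k) for n using the De Moivre–Laplace normal approximation with
continuity correction: n = −a/2 + √((a/2)² − b) with
a = −p⁻¹(2k − 1 + (1−p)·Φ⁻¹(1−ϑ)²) and b = p⁻²(k − ½)², rounded **up**
(the reference worked example evaluates to 73.74 and plans 74) and floored
at k. The approximation is stated for ϑ > 0.5; for ϑ ≤ 0.5, for a negative
discriminant, and at p = 1 an exact binomial search (exponential +
bisection over the monotone tail) is used instead, and every plan reports
which route produced its n. Across the tested grid (k up to 200, ϑ 0.6–0.95,
p 0.5–0.99) the approximation is within ±1 of the exact search.

Post-hoc, the quantile k(ϑ) = max{k : P(H ≥ k) ≥ ϑ} gives the data-quality
lower bound k/n for FWR/FAR; for SCC the prompted group gets the same bound
at its own PPV (base rate ς̂) and D1 counts in full, so the pooled bound is
(|D1| + k_{D0⁺})/(|D1| + |D0⁺|). Procedure ranking uses either minimal n
(maximal data quality per recruit) or maximal overall utility — with π
replaced by ς̂ under SCC, because the screening test only operates in the
prompted group. Ties break deterministically: fewer involved tests, then
lexicographic procedure spec.

## The synthetic-cohort generator

`simulate_cohort` draws, per participant: initial device ~ Bernoulli(π);
a self-report of it (flipped with probability `misreport`, default 0 —
unbiased self-report is the framework's standing assumption, and violations
are a simulation scenario, not a planner feature); if the study requests
the target device, each non-user switches with probability ς; then each
test's T trial responses are Bernoulli(q_pos) or Bernoulli(q_neg) according
to the device actually in use at test time. One integer seed fully
determines a cohort; replicate r of a strategy simulation derives its seed
from `seed + r`.

Defaults are the documented study conditions: π = 0.1767 (the larger
prevalence estimate, 211/1194), ς = 0.55 (the planning example's switching
estimate), T = 6. The per-trial probabilities are moment-matched to the
main-study tables — the mean of the Sen (resp. 1−Spe) column over
thresholds 1..6 equals the expected fraction of headphone-indicating
trials — giving q_pos/q_neg of A 0.848/0.509, B 0.842/0.311, C 0.940/0.515.
The per-trial semantics: a trial bit is 1 when the response is consistent
with the headphone percept, so a loudspeaker user answering *correctly*
produces a 0; `q_neg` is therefore the loudspeaker user's
headphone-indicating (error) rate.

Dependence: real response data show within-participant correlation that
independent Bernoulli trials cannot produce, but no magnitude was
published, so the generator's mechanism is deliberately minimal and its
default is 0. With probability d a participant is an "all-or-nothing"
responder whose trials within each test repeat a single latent
Bernoulli(q) draw; marginal per-trial rates are preserved while both
within-test and across-test dichotomized outcomes become positively
dependent (across tests through the shared responder state). This suffices
to exercise the independence test and the empirical-combination fallback;
it is illustrative, not calibrated.

What passing simulation tests do and do not show: the generator reproduces
the *assumed* statistical structure (binomial counts, conditional
independence at d = 0, exact binomial acceptance sampling), so agreement
validates the formulas and the code, not the behaviour of any real
participant population — real cohorts have threshold-dependent dependence,
device-quality heterogeneity and possibly biased self-report, none of which
are modelled.

## Numerical choices and problem sizes

* Wilson intervals snap to exactly 0/1 at boundary counts; bounds clamp to
  [0, 1].
* The empirical vote compares the weighted sum against 1 − 1/24; weight
  denominators are 2, 3 or 4, so every attainable sum is at least 1/12 away
  from 1 on the failing side.
* Monte-Carlo checks in the suite use 10,000 participants per device group
  for parameter recovery (3–3.5 standard-error bands), 300–400 replicates
  for calibration rates, and 10⁶ draws for closed-form cross-checks; the
  planner calibration simulates a few hundred SCC cohorts at the planned n.
* `required_n` raises for k < 1 and p = 0; a candidate with zero success
  probability is dropped from rankings (no finite n exists).

## Known limitations

* The full published EK numbering beyond the four anchored keys is not
  recoverable from public material; the package's ordering is a documented
  convention.
* The empirical combined characteristics of all 2,178 procedures on the
  original response data are not re-derivable here (the item-level data are
  not public); the planning example reproduces the published n = 74 from
  the published p̃ = 0.9614.
* Utilities are unit-interval weights; no monetary cost model, and no
  serial (gated) testing — the framework combines parallel tests only.
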