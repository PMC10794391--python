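# screenplan

Evaluation, combination and study planning for binary **playback-device
screening tests** in Internet experiments on auditory perception.

Online listening studies often require a specific playback device —
typically headphones (e.g. for binaural stimuli) — but cannot verify it
directly. Short perceptual screening tests classify each participant as a
headphone or loudspeaker user, and behave exactly like diagnostic tests in
epidemiology: each has a sensitivity *Sen* = P(test positive | headphones)
and specificity *Spe* = P(test negative | loudspeakers), and the practical
quality of an accepted sample depends on the headphone base rate π through
the positive predictive value

```
PPV = Sen·π / (Sen·π + (1 − Spe)·(1 − π)).
```

`screenplan` implements the full planning framework around this idea:

* **metrics** — sensitivity, specificity, PPV/NPV, overall utility
  (a desirability-weighted sum of the four outcome probabilities), and
  Wilson score confidence intervals for all proportions;
* **roc** — anchored empirical ROC curves over per-threshold operating
  points and trapezoidal AUC;
* **combiner** — parallel combination of up to three tests by weighted
  voting (G = 1 iff ω_A·A + ω_B·B + ω_C·C ≥ 1; 18 catalogued rules from
  single tests to three-way majority and mixed AND/OR rules, 2,178
  procedures at six thresholds per test), product-rule characteristics
  under conditional independence, chi-square / exact-multinomial
  independence checking, and empirical combination from item-level data;
* **strategy** — sample-size planning and post-hoc data-quality bounds for
  three screening strategies: Filter Without Request (FWR), Filter After
  Request (FAR) and Split–Convince–Compare (SCC). The count of true target
  users in an accepted sample of size n is Binomial(n, p); the planner
  inverts P(H ≥ k) ≥ ϑ via a continuity-corrected normal approximation
  (exact binomial search as fallback) and ranks candidate procedures;
* **simulate** — a seeded synthetic-cohort generator (device prevalence π,
  post-request switching probability ς, per-trial response probabilities
  per test, optional within-participant dependence) for end-to-end
  validation;
* **fixtures / cli** — the published per-threshold characteristics tables
  of three screening tests (a pre-study and a main study) ship as packaged
  fixtures, and a `screenplan` command line exposes everything.

## Worked example

Plan an SCC study that needs **k = 70** true headphone users with certainty
**ϑ = 0.80**, given a headphone prevalence estimate π̂ = 17.67% and a
switching-prevalence estimate ς̂ = 55%, ranking all product-rule
combinations of the packaged main-study characteristics:

```
$ screenplan plan --strategy SCC --device headphones --k 70 --theta 0.80 \
      --pi 0.1767 --sigma 0.55 --fixture mainstudy --top 1
{
 "provenance": {
  "software": "screenplan 0.1.0",
  "characteristics": "fixture:mainstudy"
 },
 "strategy": "SCC",
 "criterion": "min_n",
 "k": 70,
 "theta": 0.8,
 "pi_hat": 0.1767,
 "sigma_hat": 0.55,
 "ranking": [
  {
   "procedure": "EK12:A5,B6,C6",
   "label": "Test A AND Test B AND Test C",
   "success_prob": 0.9893989258954553,
   "n_required": 71,
   "n_source": "normal-approximation",
   "utility": 0.7120003201772082
  }
 ]
}
```

Reading: requiring all three tests positive (evaluation key 12) at
thresholds 5/6/6 gives a success probability p̃ ≈ 0.989 — the probability
that a member of the final SCC sample (self-reported headphone users plus
prompted, test-positive participants) truly uses headphones — so 71
accepted participants suffice for at least 70 true headphone users with
probability 0.80. (The published online tool, working from *empirical*
combined characteristics rather than the product rule, selects the same
all-AND rule with p̃ = 0.9614 and n = 74.)

The same machinery is available as a library:

```python
>>> import screenplan as sp
>>> sp.ppv(0.90, 0.90, 0.18)            # 90/90 test at 18% prevalence
0.6639344262295083
>>> sp.required_n(70, 0.80, 0.9614)     # the published worked example
74
>>> sp.roc_points(sp.load_fixture("mainstudy:A")).auc
0.7682729007633587
```

Other subcommands: `screenplan eval` (per-threshold characteristics from an
item-level CSV), `roc` (curves/AUC, optional plot), `combine` (one
procedure, product-rule or empirical with independence guard), `posthoc`
(data-quality lower bound for a conducted study) and `simulate` (synthetic
cohorts).

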