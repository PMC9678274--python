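# Methods

## Task and data model

A reviewer panel is a cohort of subjects who each rated the same roster of
14 face pairs — 12 scored pairs (8 GFMT + 4 MEDS; 6 mated, 6 non-mated) and
2 celebrity attention pairs — on a 7-point similarity-confidence scale coded
−3 … +3 with 0 = "I am not sure". Each reviewer belongs to one condition
(`control`, `no_mask`, `mask`, `alg65`, `alg95`) and one survey variant
(A/B). In non-control conditions every scored trial carries the algorithm's
displayed decision; within a variant 6 trials show "SAME PERSON" and 6 show
"DIFFERENT PEOPLE", balanced so each label covers 3 mated and 3 non-mated
pairs (the only layout consistent with balanced labels *and* balanced
mated status, and hence with well-defined per-label TPR/FPR denominators).

Reviewers failing either attention trial are excluded before analysis.
Correctness on an attention pair uses the same θ = 0.5 binarization as
scoring: a mated pair is answered correctly iff the rating is ≥ 1, a
non-mated pair iff ≤ 0. Attention trials are then dropped, so downstream
stages always see 12 scored trials per surviving reviewer. Reviewers with
no attention records at all are retained, which makes the filter
idempotent on already-filtered panels.

## SDT statistics

Ratings are binarized at half-integer thresholds θ ∈ {−2.5, …, +2.5}
("same" iff rating > θ; the working threshold is 0.5). Per reviewer and
label cell we count hits over mated trials and false alarms over non-mated
trials; per-reviewer rates are averaged with equal weight across reviewers
(identical to pooled counting under the balanced design). Sensitivity and
criterion come from the probit of the *averaged* rates:

    d′ = z(TPR) − z(FPR),  c = −(z(TPR) + z(FPR)) / 2.

The cognitive-bias statistic is Δc = c_different − c_same; TPR/FPR shifts
are reported as same-minus-different so positive values always mean "the
label pulls responses toward SAME".

**Extreme rates.** A rate of exactly 0 or 1 cannot be probit-transformed.
The default path adjusts only the *aggregate* rate, mapping a pooled count
of 0 or n to (h + 0.5)/(n + 1) — with ≥ 40 reviewers this essentially never
triggers. Applying the same correction per reviewer (available as
`adjust="reviewer"`) is deliberately *not* the default: with 3-trial
per-label denominators it pulls expected rates several points toward 0.5
(E[adjusted] ≈ 0.25 when the true rate is 0.18) and would bias Δc and d′
estimates by far more than the quantities being measured.

## ROC and isobias geometry

Sweeping θ yields a 6-point empirical ROC per condition × label, anchored
at (0,0) and (1,1); AUC is the trapezoid under the FPR-sorted polyline
(chords under a smooth binormal curve give a small systematic
underestimate, ≈ 0.01 at d′ = 1.5 with this 6-point grid). An isobias curve
for criterion c is {(Φ(−d/2 − c), Φ(d/2 − c)) : d ≥ 0}, rendered over a d
grid of 0…4 in 200 steps; at d = 0 it meets the chance diagonal at
(Φ(−c), Φ(−c)). Curves for distinct c never intersect, so the band between
the SAME- and DIFFERENT-label criteria at one threshold can be compared
with any other band purely in criterion space: bands overlap in ROC space
exactly when their closed criterion intervals intersect, which is how
overlap is decided (no polyline tolerance issues).

## Inference

The exchangeable unit is the reviewer. Bootstrap CIs are 95% percentile
intervals over B resamples of reviewers with replacement (default
B = 10,000; analyses in the test suite and acceptance script use
B = 1000–2000, comfortably past percentile-interval stability for these
statistics). Within a condition the resample is paired across the two
label cells, since every reviewer contributes trials under both labels;
across conditions the two reviewer pools are resampled independently.
Two-sided p-values double the smaller tail fraction of replicates at or
beyond zero, clipped to [0, 1]; significance is declared at p < 0.05
throughout. Every routine derives its generator from the master seed plus
a CRC of (condition, metric, threshold) tags, so results are independent
of execution order.

Classical tests mirror the study designs: a mixed two-way ANOVA on
per-reviewer accuracy (between: condition; within: algorithm label;
between effect tested against subjects-within-groups, so its denominator
df is total reviewers − 2), delegated to `pingouin.mixed_anova` and
verified in the tests against a hand-written balanced sums-of-squares
decomposition; a one-way between-subjects ANOVA on per-reviewer mean
|rating| (`scipy.stats.f_oneway`); Welch two-sample t tests for pairwise
condition contrasts (uncorrected — the design reports bare pairwise
p-values) and for per-pair rating shifts by label; and a paired t across
the 12 per-pair Δμ values (df = 11) for comparing shift profiles between
conditions. Degenerate zero-variance inputs are flagged rather than
returned as NaN.

## The synthetic observer

Each simulated reviewer is an equal-variance Gaussian observer: latent
familiarity x ~ N(d_i, 1) on mated trials, N(0, 1) on non-mated trials,
mapped to the 7 ratings through six increasing criteria. The criteria are
a fixed base grid centred on the distributions' midpoint d_i/2, plus a
per-condition offset, a per-reviewer offset, and a label-coupled
translation of ±Δc/2 (+ for DIFFERENT, − for SAME). A rigid translation is
the minimal mechanism consistent with the finding that algorithm decisions
shift the criterion at every threshold while leaving sensitivity and
accuracy untouched; it makes the injected Δc the expected measured shift
at each θ.

Parameters, defaults and rationale:

- **Base criteria**: spacing 0.35 in criterion units, grid ±(0.175 …
  0.875). One confidence step must correspond to a criterion step lying
  *between* the two measured bias magnitudes (0.21 unmasked, 0.45 masked):
  overlap of adjacent isobias bands is the signature that a shift spans a
  full scale step, observed with masks but not without. 0.35 is the
  midpoint of that bracket. (A wider grid, e.g. spacing 0.5, would make
  mask-condition band overlap impossible in expectation since 0.45 < 0.5.)
- **Condition presets** (`study1_config`, `study2_config`): reviewer
  counts 49/51/50 and 162/172/163, d′ of 1.56/1.70/0.93 and
  0.95/1.00/1.54, Δc of 0/0.21/0.45 and 0.16/0.25/0 — the values the two
  studies report. Per-condition criterion offsets are set so the simulated
  label-averaged criterion at θ = 0.5 echoes the corresponding reported
  criteria.
- **Reviewer heterogeneity**: sd 0.3 on d_i (truncated at 0) and sd 0.2 on
  a shared criterion offset, giving the across-reviewer variance a
  subject-level bootstrap needs. Heterogeneity flattens pooled rates by
  the exact factor 1/√(1 + τ²) ≈ 1.031 (τ² = 0.15² + 0.2²), so pooled
  plug-in estimates sit ~3% below injected values; parameter-recovery
  checks therefore run with heterogeneity off, testing the estimator under
  the homogeneous model it assumes, while calibration checks (coverage,
  type-I) keep the heterogeneous default and define truth as the
  generator's asymptotic estimand.
- **Attention errors**: with probability `attention_error_rate` (default
  0) a reviewer is inattentive and sign-flips both attention responses, so
  the exclusion fraction directly estimates the rate.
- Per-pair difficulty offsets are not modelled (pairs are exchangeable
  given mated status); response times and super-recognizers are out of
  scope.

What passing simulation-based tests shows — and does not: the generator
realizes the SDT model the estimators assume, so recovery/coverage results
certify the *statistical machinery*, not the behavioural adequacy of
equal-variance SDT for real reviewers (real panels have pair-specific
difficulty, non-Gaussian latent noise and response-style differences the
generator omits).

## Problem sizes and numerical choices

The test suite and acceptance script use: 5000 reviewers per condition for
recovery (binomial noise ≈ 0.01 on d′), 200–500 panels of 50 reviewers for
coverage and type-I calibration at B = 1000, 21 seeded study replicates
for the band-overlap contrast, and B = 1000–2000 bootstrap replicates in
pipeline runs — sizes at which every check's Monte-Carlo error is well
inside its acceptance band. Displayed tables round to 2 decimals; machine
outputs keep full precision. Reports are byte-identical under a fixed
master seed; provenance (config SHA-256, seed, B, package version) is
embedded in every JSON report.

## Known limitations

- Equal-variance SDT only; no unequal-variance or dual-process variants,
  and no smooth (binormal-fit) ROC estimation.
- The aggregate-level extreme-rate handling means per-reviewer d′ values
  are not exposed; all headline statistics are population (averaged-rate)
  quantities.
- Trust responses are modelled as independent Bernoulli draws per phase;
  no within-reviewer pre/post correlation.
- The mixed ANOVA relies on the balanced-label design; reviewers missing a
  label cell raise an error rather than being dropped silently.
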