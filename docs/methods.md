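# Methods

## Setting and data model

The package operates on lesion-level feature records from patients with
2–10 contrast-enhancing brain lesions, labeled mGB (glioblastoma with
multiple foci; subtypes *multifocal* = T2/FLAIR-connected, *multicentric*
= unconnected) or mCNSL (multifocal CNS lymphoma; subtypes primary and
secondary, PCNSL/SCNSL). A lesion carries geometry (mean three-axis
diameter, perilesional edema extent, distance to the nearest other lesion,
all in mm), a morphology and a location category from closed vocabularies,
contralateral-normalized ADC and FLAIR ratios of the tumor and of the
perilesional tissue at 5/10/20 mm, and modality-dependent flags (perfusion:
increased rCBV, lymphoma-typical time–signal-intensity curve; SWI:
hemorrhage, vascularization). Modality flags are absent exactly when the
patient lacks the modality; the 10/20 mm perilesional ratios may be absent
when the edema does not extend that far. Tables are CSV (one lesion per
row, empty cell = absent) or an equivalent JSON document; writing is
deterministic and round-trips bit-exactly.

## Synthetic cohort generator

The generator emulates the two source cohorts (50 patients per entity; 181
and 187 lesions). Its defaults are the published summary statistics and are
not tuning knobs.

**Continuous features.** Each feature is a truncated normal on the
published range, with parent location/scale solved numerically (closed-form
truncated-normal moments, two-equation root-finding) so that the
*truncated* law attains the published mean and SD to 1e-6 relative
tolerance. Ratio features have no published range; their laws use a lower
bound of 0 (ratios are positive) and an upper bound of mean + 12 SD, far
enough out to be inert.

Some published mean/SD/range triples are infeasible for this family: given
the mean, the SD supremum on an interval is reached in the exponential-tilt
limit (density ∝ e^{θx}), and the published SD exceeds it for the lesion
counts (3.6 ± 1.5 on [2,7]; 3.8 ± 2.4 on [2,10]), the mGB inter-lesion
distance (14.0 ± 14.4 on [1,73]) and the edema extents (6.6 ± 8.4 on
[0,40]; 6.6 ± 8.3 on [0,44]) — all strongly right-skewed quantities whose
printed medians sit far below their means, so a symmetric family cannot
carry that much spread on a bounded interval. The calibrator therefore has
two modes: the strict mode raises, naming the maximal feasible SD; the
relaxed mode, used by the cohort sampler, matches the mean exactly and
takes the closest attainable SD (e.g. lesions/patient for mCNSL realize
SD 1.64 instead of 2.4). Means — the quantities the recovery checks
exercise — are unaffected.

**Lesion counts** are drawn from the (relaxed-)calibrated law, rounded to
the nearest integer and clamped to the published range; the exact
post-rounding expectation is 3.779 for mCNSL and 3.581 for mGB (bias below
0.03, not re-calibrated).

**Dependence structure.** Distinct features are independent within a
lesion; the source reports no correlation structure and none is invented.
The one exception: the 5/10/20 mm perilesional ratios of one modality share
a single uniform quantile (comonotone coupling) mapped through the three
calibrated laws. This preserves every marginal exactly while making the
within-lesion distance profile follow the published gradient smoothly; an
earlier design that sorted three independent draws was discarded because
sorting distorts the marginal means (the mCNSL 5 mm ADC ratio fell from
2.10 to ≈1.3) and thereby inverts the published "> 1.88 detects mCNSL"
rule direction at fit time.

**Categorical features** are Bernoulli/multinomial at the published
frequencies (the published mCNSL location column sums to 194/187 and is
renormalized). The typical-curve flag is drawn per lesion at 23/73 for
mCNSL and 0 for mGB; the patient-level rate (9/17) emerges approximately
and is not separately enforced.

**What the generator does not emulate:** inter-feature correlations (size
vs. edema, ADC vs. cellularity), the skewness of the real distributions
(medians are not matched), spatial lesion geometry (distances are scalars),
missingness of the 10/20 mm ratios, and scanner/field-strength effects.
Passing recovery tests therefore shows that the pipeline recovers the
published *summary statistics* under a neutral data model — not that it
would behave identically on real, skewed, correlated data; the published
empirical AUCs are reproduced only approximately by the Gaussian surrogate
(closed form 0.625 vs. printed 0.63 for the tumor ADC ratio; 0.610 vs.
0.62 for diameter).

## Deterministic fixture

A fixture cohort reconstructs every published count exactly (morphology,
location, enhancement, FLAIR connections, perfusion/SWI availability at
both patient and lesion level, typical-curve counts 23 lesions / 9 of 17
patients, rCBV, hemorrhage, vascularization). Continuous fields are filled
with the published group median where one is printed, else the group mean,
so the fixture supports count-based tests only; distributional tests use
the generator. Two bookkeeping defects of the source are carried as-is:
the mCNSL morphology rows sum to 184/187 (the remaining 3 lesions are
tagged `extra_axial_nodular`; the prose reports 6 dural-nodular lesions
overlapping the solid class without reconciliation), and the mCNSL
location column over-counts, so location assignment truncates at 187.

## Statistics

Welch's t-test is the default two-sample comparison (Student's available
by flag); the sign of the statistic equals the sign of mean(A) − mean(B).
The two-proportion "binomial" comparison is implemented as Fisher's exact
two-sided test, appropriate for the small modality denominators, and is
verified against direct hypergeometric enumeration. Tukey's HSD uses the
studentized-range distribution with Tukey–Kramer standard errors for
unequal group sizes. The Bonferroni per-test alpha is family-alpha/m with
m supplied explicitly (the source's 20-parameter family gives 0.0025); the
membership of that family is not enumerated in the source, so m is an
argument, not a constant. The SD of a single observation is reported
absent, not zero.

## ROC and threshold selection

AUC is computed by ranks (Mann–Whitney with half credit for ties), which
equals the trapezoidal area under the empirical curve and is invariant
under strictly monotone score transforms. The positive class may sit at
the low or high end of the scale; when unspecified, the orientation giving
AUC ≥ 0.5 is chosen. Candidate thresholds are midpoints between adjacent
distinct scores plus sentinels outside the range; the Youden optimum
maximizes J with ties broken toward higher specificity (mirroring the rule
list's preference for specific rules), then toward the cut nearest the
grand score median, then toward the lower threshold. The optimizer is
verified against exhaustive search, and empirical AUCs against the
Gaussian closed form Φ(|μ₁−μ₂|/√(σ₁²+σ₂²)).

## The rule-list classifier

`RuleListClassifier` is a scikit-learn-style estimator over a patient-level
feature table (continuous lesion features reduced to patient means —
matching the published "mean ratio" row labels — and boolean/category
features with any-lesion semantics, which is the only reduction that
reconciles the published perfusion patient counts).

Fitting derives one rule per candidate feature: thresholds via the Youden
optimum (direction chosen automatically), boolean/category rules voting
with whichever direction is enriched in the positive class. Rules must
pass a significance gate (Welch t / Fisher) at alpha = 0.0025 by default;
pre-registered thresholds (the published < 20 mm, < 0.87, > 1.88) can be
injected, bypassing both the fit and the gate, for reproduction runs.
Ordering is structural: the perfusion rule first, then all rules with
specificity 1.0, then the rest by descending J — reproducing the published
row order from the published sensitivity/specificity pairs.

Classification semantics (`first_hit`, the flowchart reading): rules whose
modality is missing are skipped and logged in the trace. A rule whose
*present* marker has perfect specificity but imperfect sensitivity is
one-sided — it fires only on presence (presence is proof, absence
non-diagnostic) — while every other rule splits both ways (condition true
votes the positive class, false the other). A perfectly separating rule is
therefore two-sided, which makes overall accuracy 1 on separable data
under both aggregation modes. If no rule applies the classifier abstains
(or falls back to the majority class, by policy). The alternative
`weighted_vote` aggregation sums J-weighted votes of all applicable rules;
it exists because the source does not state what happens when the early
rules do not fire. Per-rule evaluation treats each rule as a standalone
two-sided test over the records where its modality is available — the
convention of the published per-rule table, whose perfusion row (tp=9,
fp=0, tn=37, fn=8) the fixture reproduces exactly. Whether the published
non-perfusion rows were computed at lesion or patient level is not stated
in the source; both units are supported and reproduction claims are
limited to the perfusion row.

## Problem sizes and seeding

Recovery runs sample 5000 patients per entity (≈19 000 lesions; standard
error of the tumor-ADC mean ≈ 0.003 against a ±0.02 tolerance). Empirical
AUCs use 10⁵ lesions per group. The headline significance check replays
100 seeded replicates at the published group sizes (181 vs. 187). All
randomness flows from one integer seed through named `numpy` SeedSequence
streams, so every quantity is exactly reproducible; identical pipeline
configuration and seed produce byte-identical artifacts.

At the published effect size (means 1.05 vs. 0.89, SDs 0.35/0.36, n =
181/187) the noncentrality of the two-sample t-test is ≈ 4.3, giving
theoretical power ≈ 0.86 for two-sided p < 0.001; a single cohort draw is
thus expected to reach p < 0.001 (median replicate p ≈ 1e-5), but a
stricter "nearly every replicate" requirement is not attainable under
these conditions, and the test suite reports this honestly.

## Known limitations

- The generator's neutral (independent, symmetric-truncated) data model
  understates the skewness and dependence of real MRI cohorts; realized
  SDs are below the published ones for the infeasible laws listed above.
- The rule list is fit and evaluated on the same cohort (as in the
  source); no cross-validation or external validation machinery is
  provided, by design.
- Image processing (DICOM/NIfTI, segmentation, perfusion curve fitting,
  SWI analysis) is out of scope: perfusion and SWI findings enter as
  boolean features.
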