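# Methods

## The classifier

The target construct is radiographic knee osteoarthritis (rKOA) severity on
a 0–4 scale analogous to Kellgren–Lawrence, derived from two quantitative
inputs rather than holistic reading: osteophyte burden at four tibiofemoral
margins and medial joint-space narrowing (JSN).

**mJSW.** Each compartment's minimum joint space width is the smallest
distance between the femoral and tibial articular contours, represented by
ordered landmark subsets (defaults, 1-based inclusive: femur 24–30 and
tibia 68–73 medially; femur 15–20 and tibia 57–62 laterally). The distance
operator is the bidirectional point-to-polyline minimum: every vertex of
one subset is projected onto the other subset's segments and vice versa.
For two non-crossing polylines this equals the true continuum minimum
(the minimum between non-intersecting segments is always attained at an
endpoint of one of them); articular surfaces never cross, so the operator
is exact there. A closest-vertex-pair mode (`distance_mode: point`) is
provided for replication against implementations that only compare
annotated points; it can only overestimate. Pixel distances are calibrated
by the scan's isotropic pixel spacing (mm/px); anisotropic spacing is
rejected rather than silently averaged.

**JSN grade.** Thresholds on medial mJSW *w* in mm: grade 0 for w > 3,
1 for 2.5 < w ≤ 3, 2 for 2 < w ≤ 2.5, 3 for w < 2. The bands leave w = 2
exactly unassigned; the package assigns grade 3 (the more severe reading)
and exposes the choice (`jsn_boundary_grade`). At 0.25 mm pixel spacing a
measurement landing exactly on a cut is a half-pixel event, so the choice
is practically inert but must be total. The lateral JSN grade is computed
and reported but never enters the composite: the medial compartment is the
classifier's JSN input because it is the compartment dominantly involved in
primary knee OA.

**Osteophyte grade.** Site area in mm² is the shaded pixel count times the
squared pixel spacing (or a precomputed area). Grade 0 iff the area is 0;
otherwise bands (0, t1], (t1, t2], (t2, ∞) give grades 1–3. The default cut
points t1 = 10, t2 = 25 mm² are placeholders chosen to be commensurate with
published per-site mean areas (≈11.6–26.9 mm²); the calibrated values that
map to manual grading are not public, so any serious application must set
`osteophyte_area_thresholds_mm2` from its own calibration sample. All
interval conventions in the package are left-open/right-closed, matching
the JSN and rKOA band style.

**Composite.** Sum score S = 0.5·Σ(four osteophyte grades) + JSN grade.
The weighting halves the osteophyte contribution (max 12 → 6) so that the
maximum S is 9. rKOA grade: 0 at S = 0; 1 for 0 < S ≤ 1.5; 2 for
1.5 < S ≤ 3; 3 for 3 < S ≤ 4.5; 4 for S > 4.5. Any nonzero component forces
grade ≥ 1. Grades 3 and 4 are collapsed to one "3–4" category for the
association stage, where grade-4 counts are too small to contrast stably.

**Height normalisation.** As a sensitivity analysis, mJSW can be normalised
for stature before JSN grading. The published formula is not in the public
text; the package uses multiplicative rescaling to the population mean
height, w′ = w · h̄/h, which is the identity at the mean and dimensionally
preserves mm. Dividing by height alone (units mm/cm) is selectable via
`height_norm_mode` for comparability studies. This is a documented
assumption, not a reproduction.

## Association stage

Binary outcomes (knee pain lasting more than three months; hospital-
diagnosed knee OA) are modelled with logistic regression; total knee
replacement with Cox proportional hazards on time from scan, administrative
censoring at the follow-up horizon. Each exposure level is contrasted
against the grade-0 reference. Confidence intervals are Wald intervals on
the log scale (the construction used is not dictated by the grading rules;
Wald is the convention the point-estimate/CI/p triplets reported in this
literature are consistent with). Cox ties are handled by Efron's method —
the accurate default at cohort scale, where measurement-time ties are
common. The proportional-hazards assumption is checked per covariate by the
scaled-Schoenfeld-residual test against rank-transformed event time.
Adjustment set: age, sex, height, weight, ethnicity (categorical, majority
group as reference). Sex-stratified fits drop sex from the adjustment;
interaction fits add exposure×sex product terms to the pooled model and
report the Wald p per level. Numerics delegate to statsmodels (logistic),
lifelines (Cox, Schoenfeld) and scikit-learn (Cohen's κ for interobserver
agreement); the module's contracts, not the backends, are normative, and
tests cross-check κ against its closed form and the 2×2 odds ratio against
the cross-product ratio. Quasi-separation (logistic) and monotone
likelihood (Cox) are detected by runaway standard errors and returned as
flagged results; exposure levels with zero events are dropped from the
contrast with a flagged placeholder rather than silently.

Newton iteration for the Cox partial likelihood can overflow at the default
step size when true hazard ratios are large (≈20+); the fitter retries with
damped steps (0.5, then 0.1) before reporting failure.

## Synthetic data

**Knees.** The 129 points are partitioned into femur (1–44), tibia (45–96),
fibula (97–112) and patella (113–129) contours of a supine AP right knee
(x rightward, y downward, medial at larger x). The articular subsets are
horizontal parallel segments with overlapping x-extent whose vertical
separation equals the requested compartment gap exactly; remaining contour
points are piecewise-linear connective geometry. Random jitter is Gaussian
(σ 0.6 mm) off the articular surfaces and uniform (±0.4 mm) *along* them —
orthogonal to the gap direction — so the generator/measurer closure is
exact up to floating point, comfortably within the half-pixel acceptance
band. Osteophyte masks are compact blobs of exactly round(area/spacing²)
pixels nearest a site-specific margin centre, colour-coded red/green/
yellow/blue for medial femur / lateral femur / medial tibia / lateral
tibia; exact pixel count makes the rasterisation error at most half a
pixel's area. The generator does not emulate positioning rotation, patella
superposition artefacts, beam hardening or annotation error beyond jitter —
passing closure tests therefore demonstrates correctness of the geometry
and grading code, not robustness of the classifier to real acquisition
artefacts.

**Cohorts.** Defaults echo the magnitudes of the motivating ~19.6k-scan
cohort: age ~N(63.7, 7.6) truncated to 45–82 y; 51.8% female; sex-specific
height/weight normals (163.6/177.3 cm, 68.0/83.1 kg); ethnicity categorical
at the published proportions; per-site osteophyte presence 1.6–6.8%, medial
JSN presence 9.4%, conditional grade splits (0.65, 0.25, 0.10) and (0.60,
0.25, 0.15). Components are drawn independently and the rKOA grade is
*computed* from them with the scoring module, so the generator and the
classifier cannot drift apart; real components are positively correlated,
so the emergent grade-0 fraction (~74%) is a few points below the observed
80.5% — accepted as a simplification. Outcomes: logistic links with
per-collapsed-grade log-ORs (defaults ln 2.04, ln 3.80, ln 7.08 for pain;
ln 2.67, ln 5.20, ln 10.24 for hospital-diagnosed OA) and exponential TKR
times with log-HRs (ln 3.97, ln 8.75, ln 21.11), censored at an 8-year
horizon. Baselines (pain 0.12, hospital OA 0.033, TKR hazard 0.0009/yr)
were solved once so the marginal rates land near the published 14.7%, 4.7%
and 1.4%. Covariates are independent of grade, so crude and adjusted
estimates share one estimand and collapsibility checks are exact. The
constant-hazard event model is a simplification; the Cox stage is
semi-parametric, so hazard-ratio recovery is unbiased regardless.

## Verification problem sizes and numerical choices

Geometry closure is verified at gaps 2.0/2.6/3.2/4.0 mm × 100 seeds at
0.25 mm/px (half-pixel tolerance). The distance operator is compared to an
exact independent oracle (shapely point–LineString distance) at 1e-6 on 200
random non-crossing configurations, plus a one-sided dense-resampling check
bounded by the chord-discretisation error h²/(8d) — dense vertex sampling
can only overestimate, so the implementation must sit at or below it.
Estimator bias is measured as the mean log-estimate over 15–20 replicate
cohorts of n = 50 000 with all per-grade effects set to ln 3 (binary
grade ≥ 1 contrast; tolerance 5% of the true log effect); CI coverage over
200 null replicates at n = 1500 (logistic) and n = 8000 (Cox — Wald
intervals need on the order of 50 events for nominal behaviour), accepting
92–98%. Pipeline determinism is asserted byte-for-byte on 100 synthetic
scans: inputs are sorted, floats written at fixed precision, and manifests
serialised with sorted keys.

## Known limitations

- The osteophyte area cut points are placeholders (see above); absolute
  rKOA prevalences from this package are not comparable across calibrations.
- Supine DXA mJSW is systematically larger than weight-bearing radiographic
  JSW; no correction is applied or defined.
- Sclerosis and cysts are not scored.
- Left knees are handled only via a mirrored-index configuration; the
  default subsets encode the right-knee convention.
- The synthetic cohort's independent-components assumption understates
  grade correlation; simulated composite-grade prevalences are indicative,
  not calibrated.
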