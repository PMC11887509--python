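# Methods

This note documents the models, conventions and design choices behind
`faceharmony`: what each quantity means, which constants are genuinely
normative and which are package defaults, and what the synthetic data
do and do not emulate.

## Coordinate conventions

All landmark geometry lives in a 2D Cartesian frame with **x
anterior-positive** and **y superior-positive**; the subject faces the
+x half-plane. "Caudal" is therefore the −y direction, and
ventral/dorsal (protrusive/retrusive) deviations are +x/−x. Coordinates
may be raw pixels or millimetres; every `LandmarkSet` carries a
`scale` factor (mm per coordinate unit) so heights are always reported
in mm. `calibrate_scale` derives the factor from any segment of known
physical length (generalising a print-at-1:1 workflow).

Nine named landmarks are used: G (glabella), N (soft-tissue nasion),
Prn (pronasale), Sn (subnasale), Ls (labrale superius), St (stomion),
Li (labrale inferius), Pg (soft-tissue pogonion), Me (soft-tissue
menton). A full analysis requires all nine and the ordering
y(N) > y(Sn) > y(St) > y(Me).

## Construction lines and the seven measurements

* **NFL (nasofrontal line)** — the line through G and N, oriented
  caudally, anchored at N. The choice of G and N as endpoints is a
  package convention (the construction is classical but its endpoints
  are not standardised); it is isolated in `construct_nfl` so an
  alternative definition can be substituted.
* **VAL (vertical analysis line)** — the NFL rotated by exactly 15°
  about N so that its caudal end moves posteriorly. The rotation
  magnitude and sense are config keys (`val_angle_deg`,
  `val_rotation_sense`); the posterior sense is the default because the
  analysis line must lean away from the face for the inclination signs
  to read ventral-positive.
* **Heights** (mm): NasFH = N→Sn, MaxFH = Sn→St, MandFH = St→Me, each
  the *absolute scalar projection onto the VAL direction*, times the
  scale. Projection (rather than raw Euclidean distance) keeps the
  three heights commensurable on one axis, so NasFH + MaxFH + MandFH
  equals the N→Me projection exactly.
* **Inclinations** (degrees): signed angles between the VAL and the
  structure lines N→Prn (NRI), Sn→Ls (OLI), St→Li (ULI), St→Pg (MI),
  positive when the structure's caudal end lies anterior (ventral) to
  the VAL. The landmark pairs are config keys
  (`structure_pairs`): the structures are anatomically fixed but their
  defining points are a package convention. Pairs are stored
  superior-point-first and the direction is taken exactly as given, so
  all four angles are invariant under any similarity transform of the
  landmark set (verified to 1e-9 in the tests).

NRI is measured against the VAL, like the other three inclinations.
Whether the original analysis referenced the VAL, the NFL or the true
vertical is not documented anywhere accessible; referencing the VAL
keeps all four angles in one frame and only shifts the sagittal band
intercepts, which are configurable anyway.

## Normative model

* **Vertical**: the optimal mandibulofacial height is the golden
  section of the upper lip height, MandFH_opt = φ·MaxFH with
  φ = 1.6180339887, and the normal range is MandFH_opt ± 10 %
  (`band_fraction = 0.10`). Below the lower limit the lower face is a
  short-face configuration (SF), above the upper limit long-face (LF),
  otherwise normal (NF). The golden-section-at-stomion rule is the most
  direct reading of a golden-ratio facial norm; the authoritative
  published coefficients of the original analysis are not reproduced
  here, so **every constant (φ, band fraction, rule) is a config key**
  and an alternative rule can be injected without code changes
  (`NormativeModel.with_vertical_rule`).
* **Sagittal**: each of OLI/ULI/MI has a normal band whose centre
  depends linearly on the nasal-bridge inclination:
  centre = intercept + slope·NRI, band = centre ± halfwidth. The
  defaults — intercept 0°, slope 0.5, halfwidth 5° — are **explicit
  placeholders** with the dependence structure of the original norms
  but not their published values; they are config keys
  (`sagittal.<param>.intercept/slope/halfwidth`) and should be
  overridden where calibrated values are available.
* **Boundary policy**: a value exactly on a band limit is *in range*
  (clinically, a tie is reported as within normal limits). This is the
  only implemented policy and is recorded in the config for
  explicitness.

Facial harmony holds when all four dimensions are in their normal
range; per-dimension **success** after surgery is defined on the
post-operative state alone (kept within or transferred into range count
equally).

The advisory rules in `recommend_procedures` encode two common
heuristics (Class II with a low chin inclination → augmentation
genioplasty or bimaxillary advancement; Class III with a long-face
configuration → bimaxillary rotation with setback and/or reduction
genioplasty). Their output is prefixed as advisory and non-normative;
it is rule-table lookup, not clinical guidance.

## Exact test of independence

`fisher_freeman_halton` implements the Freeman–Halton generalisation of
Fisher's exact test to r×c tables: conditioning on both margins, a
table has multivariate-hypergeometric probability
(∏ rᵢ!)(∏ cⱼ!)/(N!·∏ nᵢⱼ!), and the two-sided p-value sums the
probabilities of all tables no more probable than the one observed.
Enumeration is exhaustive (recursive fill with forced last row/cell),
with probabilities computed through log-gamma. Because float
enumeration produces near-ties among mathematically equal
probabilities, a table is counted when its probability is ≤ observed
+ 1e-7 (additive). Self-checks: the enumerated probabilities must sum
to 1 ± 1e-9, and p ≥ the observed table's probability. On 2×2 input
the result equals the classical two-sided Fisher test (verified against
`scipy.stats.fisher_exact` to 1e-9, and against an exact
rational-arithmetic brute force on 3×2 tables). The 3×2 tables arising
from a 160-patient cohort enumerate a few hundred tables; the test is
effectively instantaneous.

## Logistic regression and model selection

`logistic_irls` is plain maximum likelihood via Fisher scoring written
as iteratively reweighted least squares, with step-halving so the
deviance path is non-increasing; convergence is declared on a relative
deviance change below 1e-10. Inference is Wald: standard errors from
the inverse observed information, z-tests, and CIs reported on the
odds-ratio scale (published tables of this kind often use profile
likelihood CIs; Wald is used here and the difference is immaterial at
the cohort sizes involved). **Quasi-separation** — typical in small
surgical cohorts where some predictor level has no failures — is
flagged when any standard error exceeds 100 (or is non-finite) rather
than raised; separated fits still report estimates and the flag.

Categorical predictors are dummy-coded against fixed reference levels:
the normal-range harmony category (NF/N), Angle class I, Le Fort 1
surgery, male sex — so coefficients are the H/L (or SF/LF) deviations
and the female/BSSO/bimaxillary contrasts. `stepwise_aic` performs
forward-backward search minimising AIC from the intercept-only model,
taking the single best add-or-drop move per step; ties break by
candidate order, making the search deterministic. Note that AIC admits
a null variable whenever its deviance drop exceeds 2, i.e. with
probability P(χ²₁ > 2) ≈ 0.157 — the expected ~16 % false-inclusion
rate is a property of AIC selection, not a defect.

Because no individual-level data are published for the cohort the
package models, the regression layer is validated by simulation only:
coefficient recovery within 3 SE, ~95 % Wald CI coverage over 500
replicates, deterministic selection of a true OR = 3 effect, and
flagged separation on a constructed separated cohort.

## Power analysis

`power_fisher_sim` models the design as **two independent binomial
groups** of `n_per_group` (default 160), the second group's prevalence
shifted by a fixed odds ratio, and estimates the power of the two-sided
Fisher exact test by Monte Carlo (p-values memoised by the observed
counts). The pre/post comparison in the modelled study is actually
paired; treating it as two independent groups is what a Fisher-test
power calculation implies and is the package's documented choice. At
α = 0.05, OR = 2, 160 per group, and baselines swept over the
pre-operative harmony range (0.42–0.68), simulated power runs from
roughly 0.87 down to 0.71 (2,000 replicates; Monte-Carlo SE ≈ 0.01),
decreasing as the baseline approaches the ceiling. The null case
OR = 1 recovers the test's (conservative) size ≤ α.

## Synthetic data

* **Profile template**: a canonical harmonious profile in mm
  (`TEMPLATE_COORDS`), constructed so its measurements sit inside every
  default band: NasFH 29.74, MaxFH 21.25, MandFH 35.36 (optimum
  φ·MaxFH = 34.38, band 30.95–37.82), NRI 52.57, and OLI/ULI/MI within
  ±5° of 0.5·NRI. The frozen measurement vector is verified against an
  independent closed-form oracle in the tests.
* **Deformations** act perpendicular to the template's VAL (the
  analysis' own sagittal axis), so the three projection heights are
  *exactly* invariant under the shifts and each deformation perturbs
  only the measurements it targets: mandibular shift translates
  {Li, Pg, Me} (targets ULI and MI; stomion stays with the upper face —
  it anchors the St→Pg and St→Li lines, and a block containing both
  endpoints of a line could never change its inclination); maxillary
  shift translates Ls fully and Sn at ratio 0.5 (a crude soft-tissue
  response; targets OLI); elongation rescales {Li, Pg, Me} radially
  about St (targets MandFH while preserving the St-anchored
  directions). Gaussian landmark noise (default demo value 0.25–0.8 mm)
  emulates tracing error. Deformations that break the
  superior-to-inferior ordering raise an error.
* **Cohorts**: `CohortSpec` fixes exact demographic margins (class
  4/64/92, surgery 13/24/123, sex 99/61, lognormal age with median 23
  truncated to 13–61) and draws harmony states as Bernoulli variables —
  pre-operative harmony per dimension, post-operative success
  conditional on Angle class (optionally modulated by the pre state).
  `table_calibrated_spec` sets these probabilities to the bundled
  reference rates, so expected per-class success counts equal the
  reference by-class counts exactly; across 200 seeds the mean
  simulated prevalences match within Monte-Carlo error.

What the synthetic data do **not** emulate: real landmark digitisation
(no automatic detection, no perspective or printing distortion beyond
isotropic noise), anatomical covariance between dimensions (harmony
states are drawn independently per dimension given class), and any
true individual-level relationship between a patient's landmark
geometry and their cohort record (the two generators are not linked).
Passing tests therefore demonstrate the correctness and calibration of
the pipeline's computations, not clinical validity on photographs.

The bundled reference cohort consists of **summary margins only**
(prevalence counts, by-class counts, demographic margins of a published
160-patient cohort); `margin_matched_cohort` builds a deterministic
patient table reproducing every margin exactly, but its joint structure
across dimensions is a construction, which is why the regression layer
is never validated against it.

## Numerical choices and problem sizes

Geometric tolerances: similarity invariance and oracle agreement at
1e-9 (absolute, degrees/mm); template reproduction at 1e-6. Exact-test
tie tolerance 1e-7 additive; probability-sum check 1e-9. IRLS: max 50
iterations, 30 step-halvings, separation threshold SE > 100.
P-values are displayed at 3 decimals with "< 0.001" below. The test
suite uses 1,000 random profiles for the geometry sweeps, an exhaustive
enumeration of all 3×2 tables with total ≤ 8 (≈1,500 tables with
positive margins) plus 150 random tables with totals to 30 against the
rational-arithmetic oracle, 500 replicates for CI coverage, 100 for
stepwise selection, 2,000 Monte-Carlo replicates per power point, and
200 seeds for cohort calibration; these sizes put every Monte-Carlo
standard error well below the margins being checked.

## Known limitations

* The sagittal band coefficients are placeholders; classifications in
  the sagittal dimensions are only as meaningful as the configured
  norms.
* Wald (not profile-likelihood) intervals; for separated fits both are
  unbounded and only the flag is informative.
* The power model ignores pairing; with positive pre/post correlation
  a paired design would have higher power at the same n.
* TPS input relies on the fixed nine-point ordering since TPS files
  carry no point names.
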