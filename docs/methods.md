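# Methods

## The screening problem

Some drivers notice the precursor cues of a developing hazard (a
"dangerous omen": an occlusion that could release a pedestrian, a vehicle
drifting toward a lane line) several seconds before the hazard
materialises; others do not.  The pipeline infers that ability from
physiological recordings: a perceived omen produces a sustained shift in
EEG band power, which a change-point detector can localise; combined with
the driver's own interview account it yields a binary label (D1 = cannot
perceive, D2 = can), and a latent-variable composite of nine features
turns the labeling study into a deployable screening score.

## Change-point model

The detector assumes a band-power series that is weakly stationary before
the perception moment and shifts its mean level by θ at a single time,
with the new level persisting to the end of the record (a sustained
regime change, not a pulse — the jump estimator averages *all* samples
after the estimated change, which is only meaningful under persistence).

Two statistics compose:

* **Sliding mean-difference statistic.**  T(t) compares the w samples
  left and right of centre t in pooled two-sample t form,
  T(t) = (R̄−L̄)/(σ̂√(2/w)).  The exceedance rule μ + 3σ is applied to
  T itself, with μ, σ estimated over a user-declared change-free baseline
  segment: thresholding the decision variable (rather than the raw
  series) is what makes the 3σ rule meaningful for a detector whose null
  distribution is approximately pinned down by the baseline.  A run must
  stay above threshold for at least 0.5 s (125 samples at 250 Hz), which
  excludes blink and myoelectric transients (< 200 ms).
* **Local comparison scan.**  Within each flagged epoch (extended by w on
  each side so the true onset cannot sit on the boundary),
  Yᵢ = Σ(d samples from i) − Σ(d samples before i); the maximiser is the
  location estimate and W = Y* is tested against C = σ√(2d)·A(α).  Under
  an iid null with variance σ², Var(Yᵢ) = 2dσ², which motivates the
  √(2d) scaling; A(α) defaults to the two-sided standard-normal quantile
  Bonferroni-corrected over the number of candidates actually scanned in
  the epoch.  σ is the sample SD of the *baseline* segment, not the full
  series — a step in the series would inflate a full-series SD and
  destroy power.  The quantile function is pluggable through
  `DetectionConfig` for users who prefer an extreme-value or permutation
  calibration.

Degenerate cases are defined, not special-cased away: a zero pooled SD
with equal window means gives T = 0; with unequal means it gives a signed
infinity, so noiseless steps are always flagged.  Ties in the scan
maximum resolve to the smallest index (the earliest change is the
quantity of interest downstream).  Scan half-width d defaults to w/4,
clipped to [2, w]; it trades location sharpness against variance of Yᵢ
and is configurable per band.

Indexing: the public API is 0-based with times in seconds; a change point
at index m means the new regime starts *at* sample m, so
θ̂ = mean(x[m:]) − mean(x[:m]).

Per-band defaults (window 4 s/1000 samples for α and β, 3 s/750 samples
for θ, δ, γ; k = 3; minimum duration 0.5 s; per-band scan levels α =
0.042, 0.087, 0.035, 0.061, 0.029) ship in
`src/omenscreen/data/band_config.yaml`.  The per-band levels are adopted
as given; their derivation is not part of this package's model, and they
simply parameterize the scan test.

## Label fusion

D2 requires the *conjunction* of a significant in-window detection and an
affirmative interview; every other combination is D1, including ambiguous
answers — a deliberate conservative policy, since the screening aim is to
identify drivers who demonstrably perceive omens.  The hazard window
defaults to [hazard − 6 s, hazard end], matching the typical 3–6 s
anticipation horizon.  When several bands fire, significant detections
are clustered by single-linkage in time (gap 1 s) and the earliest
cluster representative is the perception moment: an omen precedes its
hazard, so the earliest neural response is the estimate of interest.
Out-of-window detections never create D2 labels but are retained on the
label object for diagnostics.

## Group comparison battery

All inference is at the driver level (one median per driver and feature)
to avoid pseudoreplication.  The screens are: Kolmogorov–Smirnov
normality with the Lilliefors correction — required because the normal's
moments are estimated from the same sample, which makes the uncorrected
K-S null anti-conservative (switchable to the plain test for comparison);
and Brown–Forsythe (median-centred Levene) for variance homogeneity.  The
primary comparison is the two-sided Mann–Whitney U: exact enumeration of
all group assignments of the pooled mid-ranks when n_A + n_B ≤ 12
(two-sided by distance of U from its null mean), otherwise the normal
approximation with tie and continuity corrections.  Z is signed positive
when the D2 group has the larger mean rank, so the report's sign pattern
reads directly as "perceivers higher/lower".  No multiple-testing
adjustment is applied across the nine features; the report carries that
caveat.

Two numerical notes.  With a group of 2 the exact and approximate p can
differ by slightly more than 0.05 purely through the discreteness of the
exact null; the agreement property is asserted for groups of ≥ 3.  And
the Lilliefors test's power against a uniform alternative is only ~28% at
n = 50, reaching ~94% around n = 200; power properties are therefore
tested at n = 200.

## Measurement model and the PDO score

The nine features load on two correlated latent factors — bioelectrical
(α, β, θ, δ, γ, ECG) and eye movement (GV, LPD, RPD) — each indicator
with its own error term.  The screening score is the linear composite
PDO = ρ₁Σλ₁ⱼz(Eⱼ) + ρ₂Σλ₂ⱼz(Gⱼ) over *standardized* features: raw EEG
powers (~10⁻¹³ μV²/Hz) and pupil diameters (~mm) differ by thirteen
orders of magnitude, so the composite is only dimensionally coherent on
z-scores.  Standardization parameters are always frozen on training data
and reused verbatim on held-out drivers.

ρ₁ is fixed at 1 for identification.  In refit mode ρ₂ is taken as the
estimated inter-factor correlation: the ability score has no indicators
of its own, so its structural paths are not separately identifiable from
the covariance matrix, and the factor correlation is the natural
standardized weight for how much the eye-movement factor contributes
beyond the anchored bioelectrical path (it also preserves |ρ₂| < ρ₁ = 1
by construction).

Estimation is maximum likelihood on the sample covariance: minimise
F_ML = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p over loadings (simple structure,
factor variances fixed at 1), uniquenesses (log-parameterized to stay
positive) and the factor correlation (tanh-parameterized), via L-BFGS-B
from fixed starting values — deterministic given the data.  The
standardized solution divides by implied indicator SDs; each factor's
sign is anchored so its loading sum is non-negative.  Heywood cases
(vanishing uniqueness or |standardized loading| > 1) are flagged, not
silently repaired.  Fit indices use the standard ML formulas:
χ² = (N−1)F_ML, RMSEA = √(max(χ²−df, 0)/(df(N−1))), CFI/NFI/TLI against
the independence baseline (whose ML discrepancy is −log|R|), GFI from the
ML residual trace ratio; TLI > 1 is flagged rather than clipped.

Raw composites are min-max normalized to [0, 1] on the training cohort —
the simplest mapping that attains both endpoints of the published
decision interval — and held-out scores are clipped.  The decision
boundary is 0.3125 in published mode (adopted as a published constant);
refit mode tunes its own boundary by maximizing balanced accuracy on
training scores, taking the midpoint of the optimal plateau.  The
boundary is D2-inclusive.

Ablation subsets restrict the indicator sets; a side reduced to one
indicator degrades to that standardized feature with weight 1, and a
missing side drops its term.  In refit mode with a degraded structure,
ρ₂ is the training correlation between the two block scores.

## Evaluation protocol

Per-stratum hold-out counts are the half-up rounding of fraction × size
(0.2 × 56 = 11.2 → 11, 0.2 × 78 = 15.6 → 16) — deterministic in the
sizes, with only membership depending on the seed.  Cross-validation is
stratified k-fold (k = 5) on the 107 training drivers; fold metrics are
macro-averaged.  The test set is evaluated exactly once per protocol run,
by the model calibrated on the full training portion.  The positive class
is D2.  Wilson 95% intervals accompany test metrics, each metric read as
the proportion its definition expresses (F1 = 2TP/(2TP+FP+FN), a
proportion of 2TP).  The ± values reported for CV metrics are SDs over
folds.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *group-level marginal structure* of the
study population: per-group per-feature distributions calibrated to
printed summaries, in two deliberately distinct modes, because the
printed mean/SD and median/quartile summaries are mutually inconsistent
for skewed features.  Moment matching reproduces mean and SD exactly
(lognormal via σ² = ln(1+s²/m²)); quantile matching sets the location to
the (log-)median and the scale to IQR/(2Φ⁻¹(0.75)) on the (log-)scale —
a two-parameter family matches the median and the IQR exactly, but not
each quartile of an asymmetric triple individually.  The mode is always
explicit, never silently chosen.  EEG band powers and gaze velocity use
lognormal families (strictly positive, right-skewed); ECG amplitude and
pupil diameters use normal families.

Two printed-value caveats, handled differently on principle.  The
published γ/D2 quartile row is internally inconsistent (its median lies
below its P25 by an order of magnitude); no single-digit repair makes it
monotone, so quantile-matched sampling of that one cell raises a
`CalibrationError` unless the user supplies an override — parameter
solving is lazy precisely so the other 17 cells stay usable.  The RPD/D2
P75 printed as 3895 mm is an evident missing decimal point (every other
pupil value lies in 1.9–4.8 mm) and is stored as 3.895.

Time series are baseline + Gaussian noise at 250 Hz (defaults: 60 s
duration, noise SD 10% of the driver's own band level, hazard at 30 s),
with a sustained +8 baseline-SD step from the hazard time for D2 drivers
— chosen as a clearly supra-threshold neural response, comfortably above
the 5σ level at which the detector's power properties are asserted.
Features are drawn independently within a driver in the default modes (no
published covariances exist to calibrate against); the separate
two-factor mode generates indicators from correlated latent draws with
known loadings and is the ground truth for refit-recovery tests.

What passing tests on this generator do **not** show: real EEG band power
is autocorrelated, nonstationary and artifact-laden, not white noise
around a constant; real features covary within driver; real perception
responses are not step functions.  Detector power, false-alarm control
and screening accuracy measured here are properties of the method under
its own model assumptions, not field performance estimates.

## Problem sizes and numerical choices

Test and acceptance runs use the published cohort geometry (56 + 78
drivers), 60 s series at 250 Hz, 100-series batches for detector
operating characteristics, 2000 replicates for rank-test calibration,
50 replicates for group-separation medians, 10⁵ draws for calibration
recovery, and N = 5000 for loading recovery — sizes at which the
Monte-Carlo error is small against every asserted tolerance.  Scan
equivalence against the brute-force oracle is exact up to cumulative-sum
rounding (≤ 10⁻¹⁰ absolute).  All randomness flows through explicit
`numpy` Generator seeds; there is no global random state anywhere in the
package.

## Known limitations

* Single change point per flagged epoch; no multi-step segmentation.
* The critical-value calibration treats scan candidates as independent
  (Bonferroni), which is conservative for overlapping windows.
* The refit-mode ρ₂ is a definition, not an estimate of a structural
  path; alternative identifications (e.g. fixing the composite's
  residual) would scale it differently.
* Published-weights mode with the fixed 0.3125 boundary presumes score
  distributions comparable to the original calibration cohort; on
  synthetic raw-scale cohorts the min-max bounds are driven by lognormal
  tails and the trained-boundary refit mode is the meaningful operating
  point.
* Screening metrics on synthetic cohorts reflect the generator's
  separation, which is calibration-faithful but idealised.
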