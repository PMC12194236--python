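# Methods

## Angle model and conventions

All computations happen in a *limb-local* frame: +x medial for the limb in
question, +y superior, coordinates in millimetres. Raw image coordinates
(raster convention, x right / y down, anterior view) are converted by
`to_limb_frame`: for a right limb medial is image-right (x preserved, y
negated); for a left limb x is additionally negated. This makes the clinical
sign rule side-independent: every alignment angle of a straight limb is
exactly 180°, varus < 180°, valgus > 180°.

Axes are represented as direction vectors between landmark-derived points:

| angle | proximal axis | distal axis |
|---|---|---|
| PKA (photograph) | ASIS → knee centre (condyle midpoint) | knee centre → malleolar midpoint |
| HKA (radiograph) | femoral head centre → femoral notch centre | tibial eminence centre → ankle articular centre |
| FMA–FTA (radiograph) | femoral head → notch | ASIS → notch |

PKA and HKA are computed as 180° − ψ, where ψ is the signed counter-clockwise
rotation taking the proximal onto the distal direction (two-argument
arctangent of cross and dot products — numerically stable near collinearity,
where clinical limbs live). The FMA and TMA do not share a vertex (notch vs
eminence), so the angle is defined between directions, not at a point; this
reproduces the straight-limb = 180° anchor exactly. FMA–FTA is reported
unsigned in [0, 90): it is a magnitude of axis offset, with no varus/valgus
meaning, and classification of it is rejected.

Degenerate inputs (missing landmarks, coincident required landmarks,
zero-length axes, non-positive scales) are hard errors that name the
offending landmark: a measurement tool must refuse to fabricate an angle.
The neutral classification band defaults to exact equality with 180°
(`tolerance=0`), configurable because no established neutral band exists.

## Agreement statistics

The reliability coefficient is the two-way random-effects,
absolute-agreement ICC for the *mean* of k ratings — ICC(2,k) in
Shrout–Fleiss numbering, ICC(A,k) in McGraw–Wong's. From the two-way ANOVA
decomposition without replication (MSR between subjects, MSC between
measurements, MSE residual):

    ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

Absolute agreement charges systematic rater offsets (MSC) against the
coefficient. The confidence interval follows McGraw & Wong's single-rating
procedure — F-quantiles with a Satterthwaite-approximated denominator df —
stepped up to k ratings by the Spearman–Brown relation; this is the same
computation the `psych` R package performs, and the implementation is
cross-checked against `pingouin` in the test suite. Two degenerate cases are
explicit errors rather than NaN: a constant matrix (no variance to
apportion) and a non-positive denominator (residual variance swamping
subject variance, i.e. a negative variance-component estimate, under which
the ratio is meaningless). If the Satterthwaite df itself degenerates (only
possible with strongly negative estimates), the residual df is used and the
bounds are clamped to [−1, 1]; bounds are always widened to bracket the
point estimate.

Interpretation uses the Koo–Li bands with boundary values assigned to the
lower band: poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 < excellent.

Bland–Altman limits of agreement use the sample (n−1) standard deviation
and a multiplier of 1.96 by default — the convention under which the
published bias and SD reproduce the published limits exactly; a t-quantile
multiplier is available (`loa_t_multiplier`) for small samples. The
difference orientation in the accuracy pipeline is HKA − PKA, so the
topographic offset appears as a negative bias, matching the sign convention
of the published figures. Pearson correlation and ordinary least squares
are implemented from the defining sums; SEE = √(SSE/(n−2)).

## Calibration

`PUBLISHED_MODEL` (intercept −10.54, slope 1.0364, SEE 1.2427°) ships as a
named default so photographs can be interpreted without radiographs; its
provenance (33 limbs of 17 orthopedic patients, one rater) travels in report
metadata. Predictions carry the SEE and an extrapolation flag outside
(90°, 270°); no full prediction interval is attempted. Slope must be
positive (orientation preserving). Refitting uses the same OLS kernel as the
accuracy study.

## The simulator

The generator replaces the unavailable photographs/radiographs with 2-D
skeletons whose true angles are known by construction, so every validation
is a parameter-recovery experiment run through the same geometry code that
analyses real landmark tables.

Per limb: true HKA ~ N(μ, σ²); the tibial axis is rotated by the varus
deviation δ = 180° − HKA; the FMA–FTA angle ~ N(3.1°, 1.0°) truncated at 0
(by rejection — the truncation point is 3.1 SDs below the mean, so the
effect on the moments is negligible) positions the ASIS; an ankle-centre
offset ~ N(0.8°, 0.3°) captures the skin-surface vs articular ankle-centre
discrepancy, chosen so the mean photographic-minus-radiographic offset is
3.9°. PKA is additive by construction: PKA = HKA + FMA–FTA + ankle offset,
the structure implied by a near-unit empirical slope with a near-constant
offset. Cohort presets:

- **orthopedic** (accuracy study): 17 subjects, 33 limbs (one subject
  contributes a single limb), HKA 178.8° ± 5.2°;
- **healthy** (reliability study): 50 subjects, right limb; true-HKA
  parameters solved from the additive construction to hit PKA 182.6° ± 2.5°
  (mean 178.7°, SD √(2.5² − 1.0² − 0.3²) ≈ 2.27°).

Measurement variability acts on landmark coordinates in millimetres, never
on angles directly:

- `landmark_noise_sd_mm = 1.0` — isotropic per-marking noise; through the
  ~400 mm axis lengths this propagates to ≈ 0.2° of angle noise per reading;
- `rater_bias_sd_mm = 1.0` — a per-rater systematic shift of each landmark,
  fixed across subjects and sessions (≈ 0.2° systematic angle offset per
  rater);
- `session_sd_deg = 0.3` — stance/repositioning between photographs,
  modelled as a rotation of the malleolar landmarks about the knee centre,
  shared by every rater and reading of that photograph. (A rigid rotation of
  *all* landmarks would leave every angle unchanged — angles are similarity
  invariants — so the perturbation must act at segment level to matter.)

No landmark-level error magnitudes are published for this method; these
three defaults are **calibrated, not measured** — set once so that the
resulting intrarater/interrater/test–retest ICCs land in the high-0.97-to-
0.99 range reported for the real raters, and not revisited. Under these
defaults the variance ordering intrarater (marking only) ≥ interrater
(marking + rater bias) ≥ test–retest (marking + stance) emerges from the
same decomposition.

Randomness is one integer seed fanned into hierarchical substreams
(subject → session → rater → marking) via hashed `SeedSequence` keys, so
identical configs are bit-identical and adding raters or sessions does not
perturb subject draws.

The reliability designs mirror the three standard matrices: per-rater
intrarater (readings 1 vs 2 of photograph 1, k=2), interrater (first
readings of photograph 1, k=3 pooled for the ICC, pairwise for
Bland–Altman), and test–retest (photograph 1 vs 2, k=2). For test–retest the
per-subject value of each photograph is the mean of the three raters' first
readings — the natural reading of a "for all raters" k=2 design; rater
biases cancel between photographs, leaving stance variation as the dominant
error term, which is the quantity test–retest reliability is meant to
capture.

### What the simulator does not emulate

- **Offset–severity correlation.** The generator draws the topographic
  offset independently of deformity severity. The published moments
  (PKA SD 4.8° < HKA SD 5.2°) imply the real offset was *negatively*
  correlated with HKA, which is also why the published slope (1.0364)
  exceeds 1. Under independence the population OLS slope of HKA on PKA is
  attenuated to σ²_HKA/(σ²_HKA + σ²_offset) ≈ 0.96 at the orthopedic
  defaults. Parameter-recovery experiments therefore use a configuration
  with the subject-level offset SDs (and rater bias) set to zero, where the
  generating slope is exactly 1.0 and the generating bias exactly 3.9°; at
  the full defaults the recovered slope is expected near 0.96, not 1.
- No bilateral correlation between a subject's limbs (limbs are independent
  draws).
- No body-composition covariates (adipose thickness, musculature), which in
  practice inflate landmark error for some subjects; noise is homoscedastic.
- No image formation at all: perspective, parallax and camera placement
  effects are outside scope — landmarks enter as digitized coordinates.

Consequently, passing tests demonstrate the correctness of the geometry,
statistics and pipeline plumbing, and the *internal consistency* of the
published figures — not the field accuracy of the photometric method on new
patients.

## Problem sizes and runtime choices

Monte-Carlo checks use sizes chosen to keep estimates stable at modest cost:
10,000 draws for distribution-moment recovery, 2,000 limbs for
parameter recovery (sampling SE of the slope ≈ 0.005), 100 replicates of
the full 50-subject reliability study for the excellent-band rate, and
200–300 random small matrices per brute-force oracle sweep (1,000 in the
dedicated validation test). All stochastic tests run with fixed seeds.

## Known limitations

- The ICC confidence interval is an approximation (Satterthwaite df); for
  very small n or near-degenerate variance decompositions it is clamped
  rather than exact.
- The calibration is a single pooled line: no stratification by sex, age,
  side or deformity severity, and no nonlinear terms.
- The pipeline is complete-case only: incomplete pairs/rows are dropped
  loudly, never imputed.
- Radiographic ankle and knee centres are treated as directly digitized
  points; the package does not derive the radiographic ankle centre from
  malleolar markers.
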