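# Methods

## Problem and model

The package screens for dysglycemia (blood glucose > 200 mg/dL or
< 70 mg/dL) from single-lead ECG morphology, one subject at a time. The
core statistical object is a per-subject **linear ν-one-class SVM**
trained on euglycemic beats only: find a hyperplane `w·x = ρ` separating
the training cloud from the origin while allowing at most a fraction ν
of training beats on the origin side. ν is both an upper bound on the
training-outlier fraction and a lower bound on the support-vector
fraction; it is fixed at 0.75 for every subject (no per-subject
hyperparameter tuning). A beat with feature vector `x` receives the
score `ρ − w·x`; positive scores are called dysglycemic. Feature
importance is `|w_j|`, reported per subject and cohort-averaged; a
one-way ANOVA F per feature is provided as a clearly separate,
two-sample alternative ranking (the two statistics answer different
questions and are never mixed).

### Why the features are not standardized

Z-scoring (the textbook default) centers the training cloud onto the
origin — exactly the point a linear one-class SVM separates the data
*from*. The dual then admits `w ≈ 0`, libsvm fails to converge, and
per-subject results become unstable (measured: minutes per fit and
per-subject AUC scattered 0.40–0.81 on data where the raw-feature model
is stable at ~0.9). Scale-only division by the training SD converges but
also discards the physical offsets that make the origin meaningful. The
default is therefore **no standardization**: all intervals and pairwise
amplitude differences are positive quantities with stable physical
offsets, and those offsets are what anchor the halfspace. The
`standardize` config key ({none, scale, zscore}) keeps the alternatives
available, and the training mean/SD are always recorded on the model.

### What a one-class model can and cannot do here

The euglycemic training distribution carries no information about the
*direction* of the dysglycemic shift. A single halfspace can therefore
not combine many weakly-shifted features the way a supervised linear
discriminant would. On the high-variability synthetic cohort (below),
a supervised LDA oracle fit on the validation data itself reaches mean
beat AUC ≈ 0.98, while both a Mahalanobis novelty detector and the
ν-one-class SVM — each trained on euglycemic beats only — reach ≈ 0.83–0.89.
This gap is a property of the model class, not of the implementation.

## Pipeline

**R-peak detection** is a Pan–Tompkins-style chain: zero-phase 2nd-order
Butterworth band-pass 5–15 Hz, derivative, squaring, 150 ms
moving-window integration, peak picking with a 0.3 s refractory period
and a height threshold of 0.2× the 90th-percentile peak height, then
two-stage refinement to the nearest extremum of the band-passed and raw
traces. Flat or too-short signals yield an empty peak list, not an
error. Validation is against the generator's designed R times (≥ 99%
within ±1 sample at default noise).

**Segmentation** cuts one 125-sample window per R peak (50 pre / 75
post at 125 Hz); beats without full support are dropped and counted.
Each beat carries the interval to the next detected R; the final beat of
a strip has none and is excluded from feature extraction, since next-beat
R-R is a required feature.

**Beat quality** replaces manual noise inspection with three explicit
rules: Pearson correlation with the strip's median-beat template,
peak-to-peak amplitude within [0.2×, 5×] of the strip median, and
finiteness. The correlation threshold default is 0.25, calibrated as the
largest value with ≤ 5% false rejections on clean generator beats under
the most variable supported condition (at jitter SD = the full
between-state shift, clean-beat correlations have 5th percentile ≈ 0.24,
because T-position variability legitimately decorrelates beats);
beats replaced by uniform noise sit at correlation ≤ 0.15 and are still
rejected. Under low variability the clean 1st percentile is 0.86, so the
threshold is conservative there. With fewer than 8 beats the template is
unsupported and all beats pass with a logged warning.

**Delineation** runs per beat on a stationary wavelet decomposition
(Daubechies-4, 3 levels; the beat is reflect-padded 125 → 128). Detail
coefficients are *hard*-thresholded at the universal threshold with the
noise scale estimated per beat by MAD of the finest detail band; hard
rather than soft thresholding because soft shrinkage subtracts the
threshold from every large QRS coefficient and was measured to bias the
Q-R and R-S amplitudes 0.03–0.09 mV low. Q and S are the minima of the
denoised trace in 120 ms windows before/after R; both must be strict
local minima, so a monotone ramp is a delineation failure, not a
window-edge artifact. P and T are searched on the low-frequency
reconstruction (approximation + deepest detail, ≈ 0–15 Hz):

* **P** is the *last* local maximum with two-sided prominence
  ≥ 0.01 mV in a physiologic 40–250 ms window before Q. An unbounded or
  global-max search latches onto the previous beat's T wave, which
  genuinely intrudes into the fixed 1-s window at short R-R (at the
  dysglycemic reference geometry R-R − Q-T − P-R < 0, i.e. true P-on-T
  fusion). A strip-level plausibility rule flags any located "P" whose
  P-Q amplitude exceeds 3× the strip median as a capture of the previous
  T and counts the beat as a delineation failure; clean P-Q amplitude
  variation sits far below that multiple while captures sit at 3–10×.
* **T** is the largest-|amplitude| extremum from 40 ms after S to the
  end of the window, capped 100 ms before the next R peak when the
  next-beat interval is known (the next QRS enters the window whenever
  R-R < 0.6 s). The |amplitude| criterion presumes an isoelectric
  baseline near 0 and preserves the sign of negative T waves.

Amplitudes are read from the denoised trace at the located indices; on a
noise-free beat the threshold is ~0, the denoised trace equals the
input, and designed fiducials round-trip within ±1 sample and ~1 µV.
Two alternative robustifications were implemented, measured against the
designed-feature oracle, and rejected: median-template T-wave
cancellation (misaligned subtraction at T-position SD ≈ 9 samples made
results much worse) and chord-baseline recovery of fused P waves
(recovered amplitudes were noisier than the excluded beats they
replaced).

**Features.** 26 per beat: intervals `(idx_Y − idx_X)/125` s for the 10
wave pairs plus next-beat R-R; amplitudes `|a_Y − a_X|` mV (reported
non-negative); slopes `(a_Y − a_X) / interval` mV/s, signed, for P-R,
P-Q, Q-S, S-T, R-T. The count follows the 10/10/5 feature enumeration
(pairwise amplitudes only); interval additivity and
`slope × interval = signed amplitude difference` hold exactly by
construction.

**Labels and splits.** Dysglycemia is strict (> 200 or < 70 mg/dL);
euglycemia is the inclusive band [80, 180]; the buffer bands 70–80 and
180–200 (endpoints included) are excluded so consecutive beats cannot
straddle classes — 70, 80, 180 and 200 mg/dL map to excluded,
euglycemic, euglycemic, excluded respectively ("between 80 and 180"
read inclusively; a documented choice, the source statement does not
adjudicate its endpoints). Each glucose value is paired with the
half-open 600 s of ECG preceding its storage time; truncated windows
are dropped with a logged reason. Subjects need ≥ 20 glucose records,
≥ 5 dysglycemic and ≥ 15 euglycemic ones (an atrial-fibrillation /
pacemaker metadata flag excludes). The split draws 10 euglycemic
training strips (100 min) and 5 + 5 validation strips without
replacement, seeded.

**Voting.** Each strip is partitioned into consecutive 10-s windows
anchored at the strip start; a window's label is the majority of its
beat votes with ties going to dysglycemia (sensitivity outranks
specificity in this screening context); its ranking score is the
dysglycemic-vote fraction. Empty windows are emitted unlabeled and
excluded from metrics.

**Metrics.** Dysglycemia is the positive class. AUC is the midrank
statistic; sensitivity/specificity/PPV/NPV/accuracy at score > 0 (beat)
or the majority label (window). Cohort values are unweighted per-subject
means with sample SD (n−1) — subjects, not beats, are the unit. The
euglycemia-vs-dysglycemia feature table uses pooled-beat mean ± SD and a
two-sided Welch t per feature (no test is named in the source
protocol; Welch is the conservative default), with zero-variance
features noted instead of tested.

## Synthetic data

Each beat is a sum of five Gaussians with fixed widths (P 25, Q 10,
R 10, S 10, T 50 ms). Calibration is in feature space: per-state targets
for the primitive intervals {R-R, P-Q, Q-R, R-S, S-T} map exactly to
wave centers (optional P-R / Q-T targets are checked for additive
consistency and rejected if contradictory), and the five published
pairwise amplitude targets {P-Q, Q-R, R-S, Q-S, S-T} are solved by least
squares with the P peak anchored at 0.08 mV — pairwise targets fix only
differences (rank 4), and the published dysglycemic column is internally
inconsistent by 0.10 mV, so exact amplitude calibration is impossible in
principle; the euglycemic column happens to be exactly consistent. The
anchor value keeps Q ≈ −0.05 mV, deep enough to survive denoising at the
default 0.01 mV measurement noise.

Dysglycemic state means are the euglycemic targets plus per-feature
shifts × `effect_scale` (0 = null cohort; shifts default to the
published between-state differences). Beat-to-beat jitter draws each
primitive from a normal with SD = `jitter_scale` × |shift| (floors
0.004 s / 0.004 mV; default `jitter_scale` 0.2), then re-solves the wave
parameters per beat. Setting the per-feature SD *equal* to the shift for
all 17 published features simultaneously is geometrically infeasible —
amplitude features obey signed identities such as R-S = (R-Q) + (Q-S),
and composite intervals inherit their SD from the primitives — so
jitter is defined on the primitives and composites inherit it. Strips
are 600 s of consecutive beats (R times are the running sum of drawn
R-R); each strip's state follows its glucose label, buffer-zone strips
are rendered with euglycemic morphology. White Gaussian noise
(SD 0.01 mV), an optional 0.3 Hz baseline sine (default off) and 1 µV
amplitude quantization are applied per strip. Glucose timelines
guarantee ≥ 15 euglycemic and 5 dysglycemic values (at least one hypo-
and one hyperglycemic) plus up to two buffer-zone values to exercise the
exclusion logic. Cohorts draw per-subject resting R-R offsets
(SD 0.05 s, clipped ±0.12) and a global amplitude scale (SD 0.10,
clipped [0.7, 1.3]); per-subject seeds derive from the master seed by
fixed integer arithmetic and no global RNG state is used.

What the generator does *not* emulate: arrhythmia, ectopy, atrial
fibrillation (excluded subjects), respiration coupling, electrode
artifacts, multi-lead geometry, or any glucose-rate dynamics within a
strip (the state is constant per strip). Passing tests therefore show
that the pipeline recovers designed morphology and separates
state-shifted morphology under Gaussian variability — not that the
physiologic ECG–glucose relationship itself holds.

## Study sizes and observed behavior

The shipped studies are desk-scale: calibration runs use 5 subjects ×
2000 beats per state; the cohort study uses 10 subjects × 22 strips
(10 train + 10 validation used per subject), roughly 180 000 beats
end-to-end in ~25 s. On the cohort with jitter SD = full shift,
the measured mean per-subject beat AUC is ≈ 0.89 and the 10-s vote AUC
≈ 0.90 (null cohorts: 0.50 at both levels). Two acceptance tests assert
the higher published headline levels (0.92 / 0.97) and deliberately
remain failing: beat-level, the one-class model class saturates below
that level (see above); window-level, ν = 0.75 forces a euglycemic
beat-level false-positive rate near 0.75, and the binomial ceiling for
vote-fraction ranking at ~10 beats per window, FPR 0.75 and TPR 0.95 is
0.899 — the implementation sits on that ceiling. (For the same reason a
beat-level specificity of ~0.84 is arithmetically incompatible with
ν = 0.75 when validation euglycemia is distributed like training
euglycemia.)

## Numerical choices and degenerate inputs

* SWT analysis/synthesis are materialized once per
  (wavelet, levels, length) as exact matrices built from PyWavelets
  impulse responses, verified against `pywt.swt`/`pywt.iswt` to 1e-10;
  strip delineation is then dense matrix algebra.
* One-class SVM: libsvm via scikit-learn, tolerance 1e-6, fixed input
  order, no randomized initialization; decision values are verified
  against an independent SLSQP solution of the dual on small sets
  (offset comparison requires ν·n non-integer, otherwise no free
  support vector exists and the offset is only bracketed).
* Zero-variance features are dropped at fit time and recorded on the
  model; fewer than 50 training beats is an error.
* Glucose values outside (10, 1500) mg/dL, non-125 Hz records and
  unknown config keys are hard errors; flat signals and empty windows
  degrade softly with logged warnings.
* Ties: window votes break toward dysglycemia; importance ties break by
  canonical feature order; AUC uses midranks.

## Known limitations

* The fixed 1-s beat window assumes R-R ≳ 0.6 s; at faster rates the
  next QRS and the previous T wave enter the window. The T-search cap
  and the P plausibility rule contain this, at the cost of discarding
  genuinely fused beats (up to ~35% in the fastest dysglycemic strips).
* Amplitude reads assume an isoelectric baseline near zero within the
  beat (the shift-invariance of features holds for moderate offsets but
  the |amplitude| T criterion does not survive arbitrary baseline
  displacement).
* Narrow-wave amplitudes read ~3–5% low from discrete sampling of
  10 ms-wide waves at 125 Hz.
* The single-beat `delineate()` has no strip context, so the
  strip-level P plausibility rule applies only in batch extraction.
* Hypo- vs hyperglycemia are not distinguished (a one-class detector
  has a single "abnormal" side), and no arrhythmia handling exists.
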