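# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the test suite does and does not demonstrate.

## Data model

A recording is five synchronized sensor units — left/right wrist (LW, RW),
left/right ankle (LL, RL), each a tri-axial accelerometer, and a waist unit
with accelerometer plus gyroscope — sharing one sampling rate. Acceleration
is in g, angular rate in deg/s, time in seconds from session start. The
default rate is 64 Hz; nothing downstream depends on it, because all window
lengths are given in seconds and converted to samples by rounding. 64 Hz
covers the tremor band (< 12 Hz) with ample margin.

Severity labels use the clinical 0–3 scale per symptom, with clinical
grades 3 and 4 merged into one class (their separation is unreliable at
window level); freezing of gait is binary. Annotation intervals are
half-open `[start, end)`: a window center on a shared boundary belongs to
the later interval, and unannotated time is class 0. This makes window
labelling total and deterministic.

## Recognizers

**Tremor.** Two supervised hidden Markov models with diagonal-Gaussian
emissions. Training is supervised throughout — emissions from labelled
windows, transitions from empirical label-transition counts with Laplace
smoothing α = 1 (never bridging session boundaries), initial distribution
from class frequencies — because annotated data is assumed; no Baum–Welch
re-estimation is performed. Decoding is the scaled forward–backward
recursion; the posterior matrix is the confidence-versus-time output, and
ties in the argmax resolve toward the lower severity (the conservative
clinical reading). The severity HMM runs per limb on segment-local
features; the posture HMM runs once per recording on gravity features over
states {rest-like, postural-like, active} — the minimal state set that
supports the rest/postural tremor distinction. Merge rule: severity 0
forces type `none`; rest-like posture gives `rest`; postural-like *or
active* posture gives `postural` (a limb held against gravity while
moving). The active case is a design choice; the alternative (suppressing
the type during activity) is defensible but loses information.

**LID.** C4.5 decision tree written in-package: candidate thresholds are
midpoints between consecutive sorted values where the class changes, scored
by gain ratio (information gain over split information), with
pessimistic-error pruning at confidence factor 0.25 (normal-approximation
upper confidence bound on the leaf error rate, as in classic C4.5).
scikit-learn's CART was not used because it implements neither gain-ratio
splitting nor pessimistic pruning. Leaf class frequencies are the reported
confidences.

**Bradykinesia.** RBF SVM (C = 1, γ = 1/p) on standardized features, with
pairwise-coupled sigmoid calibration for probabilistic output, one-vs-rest
decision shape. The default feature set is the selected subset —
approximate entropy, cross-correlation, range — computed on 1–3 Hz
band-passed signals; sample entropy and RMS are available behind a flag.
`feature_combination_search` scores every non-empty combination of
operator families by cross-validated accuracy, reproducing in spirit how
that subset is identified.

**FoG.** Ten trees, each grown to maximum depth without pruning on a
bootstrap resample with √p feature subsetting per split (base trees are
scikit-learn decision trees; the bagging, vote counting and bootstrap-index
bookkeeping are in-package so the resamples are recorded on the model).
Confidence is the vote fraction, hence always a multiple of 1/10.

**Wrapper selection.** Best-first search over feature subsets from the
empty set, scoring candidates by internal cross-validated accuracy of a
supplied learner; stops after 5 non-improving expansions or a configurable
expansion budget. It is implemented and tested but is *off* by default in
the LOPO protocol: running a wrapper search inside every fold multiplies
runtime by orders of magnitude, and the diagonal-Gaussian HMM tolerates the
full feature set well.

## Feature operators

* `basic_stats`: mean, population SD, RMS, range.
* `signal_entropy`: Shannon entropy (bits) of the amplitude histogram with
  10 equal-width bins over [min, max]; 0·log 0 := 0; constant window → 0.
  Invariant under positive affine amplitude scaling.
* `spectral_features`: periodogram band energies (log10-transformed in the
  extraction recipes, which makes them far closer to Gaussian for the HMM),
  spectral entropy of the normalized power spectrum, dominant frequency
  above 0.5 Hz, and the 0.5–3 Hz / >0.5 Hz energy ratio that flags
  low-frequency movement.
* `approx_entropy` / `sample_entropy`: Pincus ApEn (self-matches included)
  and Richman–Moorman SampEn (self-matches excluded, both template lengths
  compared over N − m templates), Chebyshev distance, defaults m = 2,
  r = 0.2·SD — the standard parameterization in the movement-analysis
  literature. SampEn with no matching template pair is capped at log(n − m)
  to keep matrices finite. Both are computed from boolean match matrices
  built by diagonal-shifting the scalar |xᵢ − xⱼ| ≤ r·SD matrix, which is
  exactly the naive O(n²) computation, vectorized.
* `cross_correlation`: zero-lag Pearson correlation; constant input → 0.
  The per-window feature is the maximum absolute value over homologous
  contralateral axis pairs and each limb's z axis against the waist.
* `posture_features`: gravity estimate = mean of the < 0.5 Hz low-passed
  acceleration; inclination = angle to the unit z axis; intersegment angles
  between paired gravity vectors. Gravity magnitude < 0.2 g flags the
  window invalid (free-fall-like); extraction imputes the column median so
  matrices stay finite.
* Band-pass filtering is a 4th-order Butterworth applied forward–backward
  (zero phase).

Window counts follow ⌊(T − L)/S⌋ + 1 with the trailing partial window
dropped. The fused FoG matrix has 18 entropy columns (4 limb units × 3
axes + waist 3 accel + 3 gyro).

## Synthetic study conditions

Each channel is gravity projection (posture-dependent unit vector, softened
at phase changes) + a voluntary-movement process (< 2 Hz low-passed
Gaussian, phase-dependent amplitude: ~0.01 g lying to ~0.08 g during
tasks) + white measurement noise (SD 0.02 g). Legs and waist carry a
1.6 Hz locomotion sinusoid during walking (anti-phase legs).

Symptom overlays:

* tremor: sinusoid + 0.3× second harmonic at 4–6 Hz (rest) or 5–8 Hz
  (postural); peak amplitude {1: 0.05, 2: 0.15, 3: 0.4} g — well-separated
  severity classes by design;
* dyskinesia: 1–4 Hz band-limited non-rhythmic noise on limbs and waist,
  RMS {1: 0.04, 2: 0.12, 3: 0.3} g;
* bradykinesia: multiplicative gain {1: 0.55, 2: 0.3, 3: 0.12} on the
  voluntary-movement and locomotion envelopes;
* freezing: locomotion collapses to 10% and is replaced by 3–8 Hz
  *bursty* trembling (band noise times the magnitude of an independent
  band-noise envelope). The heavy-tailed amplitude distribution mirrors the
  jerky character of real trembling-in-place and is what makes freezing
  distinguishable from quiet standing by histogram entropy alone — a pure
  Gaussian trembling model would be nearly indistinguishable in that
  feature family.

Episode placement respects activity phases (freezing only while walking,
rest tremor while lying/sitting, postural tremor during tasks, dyskinesia
and bradykinesia during active phases). Left/right asymmetry is expressed
mean-preservingly: left amplitudes ×2a/(1+a), right ×2/(1+a) for ratio a,
keeping both sides inside the trained dynamic range.

Default cohorts are 8 patients × 2 sessions with per-patient parameter
jitter (tremor frequency drawn per patient, amplitude scale in
[0.8, 1.25]), so leave-one-patient-out is a genuine generalization test.
The tremor cohort follows the full lie → sit → walk → task protocol
(240 s); dyskinesia/bradykinesia/freezing cohorts use activity-dominated
scripts, because those symptoms are defined relative to voluntary movement
— a long lying phase would make "still because lying" indistinguishable
from "still because bradykinetic" in a 1–3 Hz band, a confound the
in-clinic protocol avoids by assessing during tasks. The freezing cohort
uses 480 s sessions with ~2.5% frozen time, so that the 4% no-freeze
subsampling rule leaves the no-freeze class in the majority, as the strong
clinical imbalance it presumes.

The long-term diary session alternates half-hour lying/sitting phases with
one sustained rest-tremor episode covering ~90% of every other bin —
slow ON/OFF-like fluctuation at the resolution a half-hour self-report can
express. Diary labels are the duration-weighted majority per 1800 s bin,
ties toward the higher severity; predictions are aggregated per bin by the
duration-weighted *mean* severity before the absolute error (a modal
variant is available), since mean aggregation is what makes fractional
error values meaningful.

What the simulator does **not** model: biomechanical gait dynamics, arm
swing, falls, meals/medication events, sensor drift or saturation, or
artifactual non-stationarity of real homes. Passing tests on simulator
output therefore demonstrates correctness of the pipeline and recoverability
of well-separated class structure — not clinical performance.

## Evaluation protocol

One fold per patient; all of a patient's sessions test together. The normal
class is subsampled in the *training* folds only (20%, or 4% of no-freeze
windows for freezing); test folds are untouched, and a regression test
asserts their feature matrices are bit-identical before and after a run.
The pooled confusion matrix over folds is primary (per-fold metrics are
reported alongside): accuracy = trace/total, average recall = unweighted
mean of per-class recalls with zero-support classes excluded. Within the
fused evaluation features, the tremor recognizer is scored whole-body; the
per-limb timelines come from the segment-local models.

The asymmetry index is the left over right duration-weighted severity sum;
0/0 → 1.0, a zero right side with nonzero left is reported as the capped
sentinel 99.0.

Problem sizes in the shipped acceptance run — 8 × 2 cohorts per symptom,
one 2-hour (4-bin) long-term session — were chosen to exercise the full
protocol at desk scale; all sizes are arguments, and larger cohorts only
tighten the estimates.

## Known limitations

* HMM topology and emission family for the original clinical models are not
  public; the supervised diagonal-Gaussian design is a declared stand-in.
* The C4.5 pruning uses the normal approximation to the binomial upper
  bound; exact-binomial pruning can differ on very small leaves.
* SVM probability calibration (Platt-style, internal CV) is seeded and
  deterministic, but calibrated confidences on tiny training folds are
  noisy.
* Diary comparison assumes the diary clock and the recording clock agree;
  no clock-drift handling.
* No streaming/on-device inference; recordings are processed offline.
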