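# Methods

## The recognition problem

A manual-wheelchair dancer performs eight *propulsion gestures* (PGs):
left-forward, left-backward, right-forward, right-backward, forward,
backward, clockwise and anti-clockwise rotation. Every PG decomposes
into at most two basic per-arm strokes, *forward* or *backward*, so the
system trains one 3-class classifier per body side (forward / backward /
dance) and reconstructs the eight PGs by fusing the two label streams
through a fixed 3×3 lookup. Everything that is not a propulsion —
including *fake propulsions* (FPGs), arm movements that mimic a stroke
without touching the hand rim — belongs to the catch-all *dance* class.

Ground truth for training comes from palm force sensors (FSR): a true
propulsion is exactly a hand–rim contact interval; an FPG leaves the FSR
silent. The FSR channels are never model inputs.

## Sliding windows and labeling

Recordings are processed causally in windows of `w` samples advanced by
`s`; a trial of `n` samples yields `m = ⌊(n − w)/s⌋ + 1` full windows
(`[k·s, k·s + w)`, trailing partial windows dropped). A window takes a
stroke's label when (1) it fully contains the gesture, (2) the gesture
fully contains it, or (3) their overlap is at least 70 % of the window
size (inclusive, measured in samples against `w`); otherwise it is
dance. Two contradictory strokes both claiming one window raise an
explicit conflict error instead of a silent resolution (it cannot occur
in the shipped choreographies).

Per-side datasets pool windows over trials and randomly undersample the
dance class (seeded) down to `max(#forward, #backward)`.

## Features

Each window contributes N signals — hand accelerometer X/Y/Z, hand
gyroscope X/Y/Z and the per-sample Euclidean norms |a| and |ω|
(two-sensor mode, N = 8); three-sensor mode adds trunk accelerometer Z
and the trunk gyroscope channel (N = 10) — with 19 features per signal
(152 / 190 total):

* **Time domain (13), on the raw window:** mean, RMS, variance
  (population), standard deviation, median, maximum, minimum, zero
  crossings, number of peaks, 25th and 75th percentile (linear
  interpolation), excess kurtosis and skewness (both defined as 0 for a
  constant window). Zero crossings are strict sign changes of the
  mean-centred series — raw accelerometer channels carry the gravity
  offset and would otherwise never cross zero. Peaks are strict local
  maxima (`x[i−1] < x[i] > x[i+1]`).
* **Frequency domain (6), on a filtered copy:** the window is passed
  through a 2nd-order low-pass Butterworth at 4 Hz, applied forward-only
  with the filter state initialised from the window's first sample and
  reset per window (the online contract forbids future samples), then
  mean-removed; the PSD is a one-sided periodogram of those `w` samples
  (no Welch averaging — windows are ≤ 30 samples). Features: number of
  PSD peaks, PSD mean, RMS, median, standard deviation, and spectral
  entropy −Σ pᵢ ln pᵢ over the non-DC bins normalised to sum 1 (0 for an
  empty spectrum).

A note on the trunk gyroscope: the recording schema stores a single
`trunk_gyro` channel; which physical axis it carries is configuration
metadata (`trunk_gyro_axis`, default "y"), never chosen silently per
run.

## Training

Feature selection ranks features by univariate ANOVA F-score between the
three classes and keeps the top `Nfmax = 30` (deterministic, name-order
tie-break). By default the selector is fitted *inside every training
fold*, so cross-validated accuracy carries no selection leakage; a flag
(`select_in_fold=False`) reproduces the optimistic whole-set variant.

Hyperparameters are searched exhaustively: SVM (linear/RBF kernel,
C ∈ {0.1, 0.3, 0.6, 1.0, 3, 6, 10}), k-NN (k ∈ {3, 5, 10, 15, 20, 40},
uniform/distance weights, four neighbour algorithms) and random forest
(50/100/200 trees, gini/entropy, depth {5, 8, 11, 14}, max-features
{auto→sqrt, sqrt, log2}). All grid points share one set of seeded
stratified 10-fold splits, so the winner is invariant to enumeration
order; ties break on the canonical parameter string. SVM and k-NN are
distance-based, so their pipelines standardise the selected features;
random forest runs unscaled.

Consecutive windows overlap heavily, so windows of one trial are kept in
a single fold by default (stratified *group* K-fold). Because pooled
window-level CV is what sliding-window studies usually report, the
selected model's pooled score is computed as well; on the shipped
synthetic corpus the two protocols agree to within a point. A
label-shuffle control (expected accuracy ≈ 1/3) guards against overlap
leakage masquerading as skill.

The deployed per-side families are random forest (right) and SVM
(left), the outcome of the window-parameter sweep
(`w ∈ {10, 20, 30} × s ∈ {3, 5}`, `sweep_window_params`); `w = 30`,
`s = 5` is the shipped default. Full three-family search remains
available (`train_side(..., algos=...)`).

## Fusion, spike filtering and events

The fused timeline maps each synchronized (left, right) window pair
through: (F,D)→left-forward, (B,D)→left-backward, (D,F)→right-forward,
(D,B)→right-backward, (F,F)→forward, (B,B)→backward, (F,B)→clockwise,
(B,F)→anti-clockwise, (D,D)→dance. Non-dance segments shorter than
50 ms are relabeled dance (idempotent spike filter).

**Replay stride.** The online replay re-classifies the last `w` samples
every new sample (stride 1, 33 ms at 30 Hz), painting each label onto
the newest sample span. This is what makes the 50 ms spike filter
meaningful: a single misclassified window then occupies 33 ms and is
removed as a confusion, whereas painting at the training step `s = 5`
would make every isolated error 167 ms wide and unfilterable. The
training step remains a dataset-construction parameter only.

**Detection latency.** A causal window first qualifies as propulsion
once the gesture covers 70 % of it, i.e. `0.7·w` samples after true
onset — pure window geometry, independent of any data. Event onsets are
therefore compensated by `(0.7·w − stride)` samples (667 ms at w = 30);
durations are *not* compensated: the overlap criterion clips roughly
`0.4·w` samples off each gesture, and this systematic underestimation
(≈ 15–50 % depending on gesture length) is reported as observed, since
it is a property of the method worth surfacing, not hiding. An
uncompensated mode (`compensate_latency=False`) and full-window painting
(`paint="full-window"`) are available.

**Events.** One event per maximal contiguous non-dance span. Two
adjacent runs of different gestures (the two sides resolving a bilateral
onset a few samples apart) are one propulsion, labeled by the
duration-weighted majority run; dance holes shorter than 50 ms inside a
span are bridged — the same confusion class the spike filter removes.
Detected events are matched to reference intervals greedily by nearest
onset within ±1 s; onset error is signed (negative = early), duration
error is |ref − det| / ref.

The overall accuracy of the fused system is reported as the product of
the two side accuracies, which assumes the two classifiers err
independently; correlated bilateral errors that land on a valid fused
gesture are not modelled.

## Synthetic data generator

The generator emulates the study protocol: per subject one choreography
of the eight PGs plus one FPG in uniformly random order, each lasting
600–1500 ms, separated by dance filler of 1–3× the neighbouring
propulsion time; trials resample the noise but keep the subject's
choreography. Channels follow the 17-variable schema (trunk
accelerometer Z, trunk gyroscope, 3-axis accelerometer + gyroscope per
hand, sampling time, two FSR channels) at 30 Hz. Units: m/s² (gravity
+9.81 on vertical axes) and deg/s.

Signal model (per active arm):

* **Stroke:** a front-loaded half-sine angular-velocity pulse on the
  hand gyroscope Y axis (peak 150 deg/s, phase warped by `t^0.6` so the
  push phase carries the peak), sign + for forward and − for backward,
  with fixed cross-talk onto the other gyro axes; a correlated full-sine
  acceleration pulse (±3 m/s², push then brake) on the hand X axis.
  Per-gesture amplitude varies ±15 % between subjects.
* **Rim contact (true PGs only):** a grab/release jerk (±4 m/s², ~50 ms)
  at stroke onset and end, plus a sustained 7 Hz contact vibration
  (1.5 m/s²) — the loaded rim pushes back; its frequency sits above the
  4 Hz feature filter, so it reaches the classifier through time-domain
  dispersion features.
* **FPG:** the same motion at 0.65 amplitude, with the gyro pulse
  rotated off the wheel-plane axis and no contact signature — an
  unloaded mime is gentler and the ungripped hand is not constrained to
  the wheel plane. FSR stays exactly 0.
* **Dance:** per-channel Ornstein–Uhlenbeck noise (τ = 300 ms; 25 deg/s
  and 0.8 m/s² stationary SD on hand channels, 40 % of that on the
  trunk) with sparse sinusoidal arm-wave bursts (0.5–2 Hz, vigour up to
  3× the channel SD — free swings in the same rate band as mimed
  strokes, well below a loaded push).
* **FSR:** binary 0/1 by default (`fsr_level` allows analog emulation);
  active exactly inside true-PG spans of the contacting hand.

White measurement noise (`noise_sd`, default 0.35 m/s² on
accelerometers, 3.5 deg/s on gyros) is added over propulsion templates.
At `noise_sd = 0` synthesis is bit-reproducible and templates are
exactly recoverable by matched filtering.

**What the generator does and does not show.** It reproduces the
*structure* of the recognition problem — bilateral stroke composition,
FPGs that must be rejected without FSR evidence, class imbalance,
overlap between windows — with classes that are separable at the default
noise level and confusable at high noise. It does not model wheelchair
dynamics, inter-stroke biomechanical variability, sensor drift or
individual style; passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the stated signal model, not
field performance on human dancers (whose published per-window
accuracies depend on their private data).

## Numerical and design choices

* Windows are half-open, indexed from 0; the window-count formula is
  exact under this convention.
* The 70 % overlap criterion is inclusive (≥), measured in samples
  against the window size.
* Intervals are half-open `[onset, offset)` in integer milliseconds;
  sample k sits at `round(1000·k/fs)`. The sampling rate of a read
  trial is inferred from the *mean* timestamp step (at 30 Hz the
  integer-millisecond steps alternate 33/34, biasing the median).
* Variance/SD are population moments; kurtosis is Fisher (excess); both
  kurtosis and skew return 0 for constant windows; percentiles use
  linear interpolation.
* `max_features="auto"` (a deprecated alias) maps to `sqrt`.
* Model artifacts are versioned joblib archives carrying the config,
  selected feature names and a metadata hash verified on load.
* Problem sizes used by the test suite and the acceptance script — an
  8-subject × 10-trial training corpus (~14 000 windows per side before
  balancing) and 3–6 held-out evaluation choreographies — are the
  package's default desk-scale study; they exercise every stage at
  statistically meaningful size while keeping a full run in minutes on
  one CPU.

## Known limitations

* The side classifiers are trained independently; nothing enforces
  bilateral consistency beyond the fusion lookup, and the product rule
  for overall accuracy ignores error correlation.
* Duration estimates inherit the `−0.4·w` clipping of the labeling
  criterion (documented above), so absolute durations are conservative.
* The despike threshold (50 ms) and the bridge threshold for dance
  holes (50 ms) are tied to the replay granularity; much lower sampling
  rates would need revisiting both.
* Specific dance-gesture recognition (beyond the catch-all class) is out
  of scope.
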