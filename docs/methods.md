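# Methods

This note documents the models, conventions and numerical choices behind
`gaitfall`, what the synthetic data does and does not emulate, and the
limitations a user should keep in mind.

## Signal model and coordinate convention

Keypoint trajectories use image coordinates: y increases downward, so the
vertical position of a foot is *largest* when the foot is on the ground.
Ground-contact events are therefore local **maxima** of the y signal.  For
datasets whose y axis points up, `detect_events(..., y_up=True)` negates the
signal first.  Frame indexing is 0-based and the default frame rate is 30 fps
(the TUG recording convention); all durations are frame counts divided by
fps, so they are quantised to the frame grid.

Samples whose pose-estimator confidence falls below 0.1 (configurable) are
treated as missing: interior gaps are linearly interpolated between valid
neighbours and leading/trailing gaps are held at the nearest valid value —
interpolation never extrapolates.  Filled samples are flagged on the signal.

## Savitzky–Golay smoothing

Each sample is replaced by the value of a least-squares polynomial fitted
over a centred window (defaults: window 11 samples, order 3 — chosen to
generalise across age groups' heel/toe signals).  Interior samples use the
standard convolution form ŷᵢ = Σⱼ cⱼ yᵢ₊ⱼ; the first and last half-window
samples are fitted on the *truncated* window rather than padded or
extrapolated, so no samples are fabricated at the start and end of the walk,
where events matter.  If a truncated window has fewer points than the
polynomial order requires, the order is reduced to window length − 1.

## Event detection

Candidates are samples strictly greater than both neighbours; a flat plateau
counts once, at its first sample (deterministic tie rule).  Two constraints
follow:

* **min_distance** (default 15 frames ≈ 0.5 s at 30 fps): candidates are
  accepted greedily, highest value first (ties: earlier frame), and any
  candidate closer than min_distance to an accepted peak is discarded — the
  higher peak wins a conflict.  0.5 s is below any plausible interval between
  successive same-signal contacts at normal pace.
* **prominence** (default 10 px in `detect_events`; off in the bare
  `find_local_maxima`): discards shallow maxima.  The extreme of smoothed
  keypoint jitter over a whole recording stays below ~7 px for raw pixel
  noise of a few px (an order-statistics effect over hundreds of flat
  frames), while the smallest genuine contact peak — a reduced-amplitude
  turning adjustment — rises ≥ ~20 px above swing level on a 1080p foot
  trajectory; 10 px separates the two populations with margin on both sides.
  The threshold is a pixel-scale quantity: rescale it for very different
  video resolutions or camera distances.

Heel strikes are detected on the {L,R}Heel y signals and toe-offs on the
{L,R}BigToe y signals.

## Turning window

The turn of a TUG walk forces the subject to pause and adjust both feet;
those adjustment contacts produce the lowest-valued heel-strike maxima of the
recording.  Pooling both feet's heel strikes, the detector takes the lowest
(deepest) and second-lowest peak (ties broken toward the earlier frame),
finds the strike immediately before the second-deepest and immediately after
the deepest, and sets the window bounds to the two-point medians, i.e. the
floored midpoints of those pairs.  Exclusion bounds are inclusive.  Design
choices where the procedure was underdetermined:

* a two-integer median is their midpoint, floored to a frame index;
* both feet's strikes are pooled when searching for the flanking strikes
  (a per-foot restriction would skip the contralateral strike next to the
  turn); only heel strikes — not toe-offs — feed the deepest-point search;
* if no strike exists before the second-deepest (or after the deepest), the
  bound falls back to that peak's own frame and the window is flagged;
  if the computed start exceeds the end (deepest pair in reversed temporal
  order), the bounds are swapped and flagged;
* exactly one turning window per recording is assumed; multi-turn protocols
  are out of scope.

## Temporal features

With HS = heel-strike frame, TO = toe-off frame:

* stance time = (TO − HS)/fps, same foot, within one gait cycle;
* stride time = (HSᵢ₊₁ − HSᵢ)/fps, same foot;
* step time = (oppTOᵢ − HSᵢ)/fps — heel strike to the **opposite** foot's
  following toe-off.  This is the source convention and the default.  It is
  unconventional: for a stance fraction ρ > 0.5 it equals (ρ − ½) × stride
  time (the double-support duration), not half the stride.  The conventional
  definition — heel strike to the opposite foot's next *heel strike* — is
  available via `step_time_convention="contralateral_hs"` and satisfies
  stride = 2 × step and cadence = 60/step on symmetric gait.
* cadence = steps per minute.

Pairings are restricted to the gait cycle at hand: the partner event must
follow the strike but precede the same foot's next strike, and no pair may
span the excluded turning window (each foot's events are segmented at the
window; cycles are formed within segments).  Cadence counts *completed step
intervals* per straight-walk segment — steps = Σ(per-segment heel strikes −
1), duration = Σ(per-segment last − first heel-strike frame)/fps — so the
turning pause contributes neither steps nor duration.  An event-count
convention (steps = number of strikes over the full first-to-last span) was
considered and rejected: on a short TUG walk it biases cadence by over 10%
because the span includes the pause and the count/interval mismatch does not
vanish at small n.

One aggregate row per subject is produced (mean over valid cycles), in the
per-foot schema (`left_stride_time, right_stride_time, left_step_time,
right_step_time, left_stance_time, right_stance_time, cadence, label`) or the
averaged schema (`average_stride_time, average_step_time,
average_stance_time, cadence, label`), which is the exact pairwise left/right
mean of the former.  External gait-lab tables are mapped onto the per-foot
schema: stride/step columns rename directly, single-support columns map to
stance times, cadence is the mean of the left and right cadence columns, and
spatial columns (stride length, speed, ...) are dropped — spatial features
are out of scope throughout.

## Classification protocol

* **SMOTE** to class parity: each synthetic sample is a minority vector plus
  a Uniform(0,1) fraction of its difference to one of its k = 5 nearest
  minority neighbours (Euclidean).  Synthetic rows are appended and flagged;
  originals are never modified.  By default SMOTE runs **before** the
  train/test split, reproducing the source protocol's counts (65 subjects →
  88 rows → 61 train / 27 test with synthetic rows in both): this is
  leakage-prone, since test synthetic rows interpolate training originals.
  `smote_after_split=True` gives the statistically sound variant; the
  null-table checks (below) use it.
* **Standardisation**: z = (x − μ)/s with μ, s (population SD) fitted on
  training data only and reused on the test set.
* **Split**: shuffled and stratified; test size = ⌈0.30 n⌉, per-class counts
  are floored proportional quotas with the remainder assigned by largest
  fractional part, ties toward the faller class.  The rounding rule is
  pinned so an 88-row balanced table always yields 61/27 with a 13 non-faller
  + 14 faller test set.
* **Models**: twelve classifiers behind one registry — SVM, decision tree,
  random forest, three gradient-boosted tree variants (LightGBM with
  leaf-wise histogram boosting, XGBoost, and sklearn's gradient boosting),
  AdaBoost, k-nearest-neighbours, Gaussian naive Bayes, MLP, bagging, and a
  hard-voting ensemble (tree + kNN + naive Bayes).  Hyperparameters come
  from small default grids (fully overridable) searched by 5-fold stratified
  cross-validated accuracy; the best configuration is refitted on the full
  training set.  Grids and CV depth are deliberately small: the tables are
  tens of rows, not thousands.
* **Evaluation**: accuracy and a 2×2 confusion matrix (rows true, columns
  predicted, order [non_faller, faller]); feature importances where the
  model exposes them.  `run_experiment` crosses all of this with the four
  ablations: full pipeline, without SMOTE, without scaling, without both.

`FallRiskClassifier` packages model choice, grid search and optional internal
standardisation as a scikit-learn estimator, so it composes with sklearn
pipelines and model selection; the estimator shape is used only for the
modelling stage — parsing, event detection and feature extraction are not
fit/predict-shaped and remain plain functions over dataclasses.

## Synthetic data

**Trajectory simulator** (`simulate_tug`): each ground contact appears in the
foot's y signal as a raised-cosine bump (width = stance duration, amplitude =
foot lift, default 40 px on a 600 px baseline) peaked exactly at the
frame-snapped event time, riding on a flat swing-level baseline; feet are
phase-offset by half a stride.  A contact-equals-peak signal was chosen over
a stance-plateau-with-swing-dip profile deliberately: a symmetric bump
centred on a frame keeps the smoothed maximum at the true frame exactly
(symmetric filter, symmetric signal), whereas smoothing a plateau's corners
can overshoot and displace the maximum, making "noiseless recovery is exact"
untestable.  The walk is out-and-back (default 3 strides per foot each way at
a 1.2 s stride, matching a 3 m walkway at normal pace) around a turn pause
(default 2 s) holding two reduced-amplitude adjustment contacts, the later
one the deepest — precisely the premise the turning detector relies on.
Gaussian pixel noise is added per sample.  Ground truth records every event
frame, the pause interval (half-open: the first post-turn strike is not part
of the pause) and, via `ground_truth_features`, the feature row computed from
the true events with the same pairing rules as the pipeline.

What this simulator does **not** emulate: pose-estimator artefacts
(correlated jitter, identity switches, confidence dropouts at occlusion),
asymmetric or pathological gait, variable stride timing within a walk,
camera perspective (pixel scale changing with distance), and the
stand-up/sit-down phases of a real TUG.  Passing recovery tests therefore
demonstrates the pipeline's correctness on idealised signals, not its
robustness to real video.

**Population simulator** (`simulate_feature_table`): per-class feature
vectors drawn from truncated normals (positive support).  Defaults encode
the study composition (44 fallers, 21 non-fallers) and the faller contrasts
reported for elderly gait: longer stance (0.72 ± 0.06 vs 0.66 ± 0.04 s) and
stride times (1.12 ± 0.10 vs 1.06 ± 0.05 s), higher cadence (115 ± 8 vs
108 ± 6 steps/min), shorter step times (0.48 ± 0.04 vs 0.53 ± 0.03 s) and
wider stride-time spread.  Values are in the conventional clinical ranges
for these instruments; left/right values add a small (±0.02 s SD) asymmetry
perturbation.  Features are drawn independently, so the cadence–stride
anticorrelation of real gait is not reproduced; classifier accuracies on
these tables characterise the protocol, not any real population.
`PopulationParams.null()` gives balanced classes drawn from one pooled
distribution — chance-level accuracy on such tables is the leakage check for
the protocol.  Balanced (not 44/21) null tables are used there on purpose:
with imbalance, a majority vote alone scores 0.68 and would confound the
leakage question.

## Degenerate inputs and numerical notes

Even smoothing windows, orders ≥ window, signals shorter than the window,
non-positive fps, reversed event orderings, unpairable events, zero-variance
features, unknown labels/models/schemas and too-small minority classes all
raise typed exceptions (`gaitfall.exceptions`).  Oracle equivalence of the
smoothing and peak primitives is asserted to 1e-9 against brute-force
references.  All stochastic components (simulators, SMOTE, split, CV, model
seeds) take explicit seeds and are bit-reproducible.

## Known limitations

* Only one camera view is processed per run (the side view for y-signal
  events); fusing front and side views is out of scope.
* One turning window per recording; 360° turn or multi-turn protocols are
  not supported.
* The published headline accuracies of the protocol depend on the real
  clinical datasets; the numbers this package reproduces exactly are the
  protocol's counts and its internal consistency properties, while
  accuracies reported by `scripts/acceptance.py` describe the synthetic
  study population only.
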