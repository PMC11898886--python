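# Methods

## The measurement being modelled

Each nanobiosensor couples a fluorophore-labelled consensus peptide to a
few-layer-graphene quencher. Serum protease activity cleaves the
peptide, the fluorophore escapes the quench radius, and the well
fluorescence rises; the endpoint intensity after incubation is the
activity readout, in arbitrary fluorescence units (a.u.). The plate
protocol runs three solutions in triplicate per sample × protease:
sample control (SC: serum + buffer — serum autofluorescence), assay
control (AC: sensor + buffer — intrinsic leak through the quencher) and
assay (sensor + serum). Both controls are low compared with the assay
signal.

`summarize_wells` defines the net activity as `mean(ASSAY) − mean(AC)`,
floored at zero. AC is the subtrahend because it shares the fluorophore
source with the assay wells; SC is demoted to QC. Negative nets are
floored (not propagated) so the lognormal feature model downstream stays
valid, and the event is flagged. Triplicates whose coefficient of
variation exceeds `cv_threshold` (default 0.2) are flagged, never
dropped. These choices are this package's own processing conventions:
different labs reduce control wells differently, and the pipeline keeps
the decision in one place.

## Synthetic cohort calibration

The generator ships per-group activity means and SDs for the
seven-sensor panel. They are synthetic calibration values, not
measurements, chosen once to encode the qualitative cohort structure the
analysis assumes:

- healthy > localized > metastatic expected activity for MMP3, MMP28,
  CTSK, MMP24 and ADAM10/12 (most panel proteases are *under*-expressed
  in tumour tissue relative to healthy controls, and healthy serum shows
  the highest sensor signal);
- ADAM15 elevated in metastatic relative to localized samples, with the
  healthy mean near the metastatic one;
- ADAM17 flat: its three group means sit within 5% of one another, so
  it is a deliberate near-null marker;
- group SDs of 100–150 a.u. against means of 350–1000 a.u., giving
  localized-vs-control effect sizes large enough that six of seven
  proteases are significant in essentially every simulated cohort while
  ADAM17 stays at its ~5% false-positive rate.

Noise is lognormal by default (fluorescence intensities are positive
and right-skewed), parameterised by the target mean/SD; a normal option
exists (rare negative draws are clipped at 0). Group sizes default to
50 healthy / 46 localized / 50 metastatic (n = 146). Plate simulation
adds a shared per-cell baseline (mean 50 a.u., SD 8) to all nine wells
of a sample × protease cell plus i.i.d. well noise (SD 5 a.u.);
because the baseline is shared, AC subtraction removes it exactly and
the net estimate has error SD `plate_sd · √(2/3)`.

ADAM10 and ADAM12 are a single feature ("ADAM10/12"): their active
centres are too similar for the substrate to distinguish. The panel also
exposes `subset(...)` for the six-sensor variant without ADAM17 and
`with_separation(f)` to shrink every protease's between-group spread by
a factor `f` — used to verify that accuracy degrades as the signature
weakens.

What the generator does **not** emulate: inter-plate drift,
plate-position effects, enzymatic time courses (a single endpoint is
drawn), cross-reactivity between proteases, and between-feature
correlation within a sample (activities are drawn independently given
the group). Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the assumed group structure — not
performance on real serum, where correlated proteolytic networks and
assay artefacts will matter.

## Statistics

For each biomarker and group pair (localized-vs-control,
metastatic-vs-control, localized-vs-metastatic): a two-sided F-test
`F = s²_x/s²_y` with (n−1)-denominators and p = 2·min(tail
probabilities) gates the location test at level 0.05 — the same level
used everywhere else, since no separate gate level is standard. If the
gate does not reject, a pooled-variance Student t-test
(df = n_x+n_y−2); otherwise Welch's t with Welch–Satterthwaite df. Raw
p-values, no multiplicity adjustment (the comparison table reports raw
values). Calls: significant at p ≤ 0.05, borderline strictly between
0.05 and 0.10, else ns; p = 0.05 is significant and p = 0.10 is ns by
the strict reading of "between".

The composite gate-then-test procedure is calibrated under the null:
with identical group distributions the pooled significant-call rate
across all 21 cells is 0.05 (verified over 2000 simulated null
cohorts; the acceptance script recomputes a 500-cohort version).

## Classifiers

**Hierarchical kNN.** Stage 1 votes healthy vs non-healthy; stage 2,
fitted only on non-healthy labeled samples, votes localized vs
metastatic. Posterior: P(healthy) = stage-1 healthy vote fraction;
P(localized) = (1 − P(healthy)) · stage-2 localized vote fraction;
P(metastatic) the remainder — so the hierarchy's probability identity
holds exactly. Distances are Euclidean on per-feature z-scores fitted on
the current labeled set (refit every iteration); zero-variance features
are dropped from the distance with a warning. k defaults to 5, must be
odd (no vote ties), and clips down to the largest odd feasible value per
stage when the labeled set is small. Equidistant ties at the k-th
neighbour resolve to the smallest training index, making predictions
deterministic. Posteriors are raw vote fractions — no distance
weighting or smoothing. When fewer than two non-healthy classes are
present, stage 2 is absent and the non-healthy mass splits uniformly.

**Two-layer linear-activation network.** Two affine layers with an
identity hidden activation — the composed map is affine of rank ≤
min(p, 3), kept as two layers for fidelity to the stated architecture —
followed by a normalized-exponential output so class posteriors exist.
Inputs are z-scored on the labeled set (which also makes input
translations exactly absorbed). Training: full-batch gradient descent
on cross-entropy, learning rate 0.1, 800 epochs, hidden width 8,
N(0, 0.1) init from a seeded sub-stream. These are deliberately simple
defaults: the data are 7-dimensional and near-linearly separable, and
full-batch GD at fixed epochs keeps retraining deterministic. A
single-class labeled set short-circuits to a bias that pins that class
(gradient descent cannot saturate the posterior in finite epochs).

## Active learning

Split: floor(0.20·n) labeled, floor(0.30·n) pool, remainder test — at
n = 146 that is 29 / 43 / 74. The held-out 50% is the evaluation set on
which confusion matrices are computed; it is never touched by training
or querying. The initial labeled draw repeats (new draws from the split
sub-stream, count logged) until it contains at least one healthy and one
non-healthy sample, so the hierarchy is trainable. Each iteration
queries the pool sample with the smallest top-class posterior
probability (least confidence, ties to the smallest index), reveals its
true label instantly, and refits from scratch with a fresh seeded init —
determinism over warm-start convenience. Default stopping rule: pool
exhaustion. Margin and entropy sampling are available behind a config
switch but off by default.

On the shipped cohort both models reach ~95–97% held-out accuracy
(mean ≥ 0.85 over 50 seeds for the two-layer net, verified in the
acceptance suite). These synthetic figures characterise the pipeline
under the generator's assumptions; they are not estimates of real-serum
performance.

## Shapley attributions

Value function: interventional (marginal-replacement) — v(S) is the
model's class probability averaged over background rows with features
in S taken from the explained sample. Background: the labeled training
set, capped at 50 rows by deterministic evenly-spaced subsampling. At
panel scale (p = 7) the values are exact by full 2^p coalition
enumeration (one batched model call over all hybrid points); the
enumeration guard refuses p > 12 and points to the seeded Monte-Carlo
permutation estimator, which is unbiased with error ∝ n_samples^(−1/2).
Explanations target the predicted class by default. Per-class rankings
aggregate mean |φ| across samples, ties broken by panel order.

Known limitation: per-sample top-3 stability. A vote-fraction kNN has a
piecewise-constant probability surface, and the shipped calibration
deliberately gives the rank-2..4 healthy-elevated proteases comparable
effect sizes, so which three features top an individual explanation
fluctuates from sample to sample (most-common top-3 rates of ~0.2–0.5
across seeds — far above the ~3% chance level, but not near-unanimity).
The class-level aggregate ranking is the stable object: MMP3 leads the
healthy class and the aggregate top-3 stays within the healthy-elevated
markers. Real-data panels with a dominant marker gap would show higher
per-sample consistency.

## Reporting conventions

Accuracy = 100 · trace / total, printed to two decimals by truncation
(137/146 → 93.83%, not 93.84%), matching the convention under which the
reference matrices' accuracies are quoted. Sensitivity/specificity are
macro one-vs-rest: per-class recall and true-negative rate, unweighted
mean over the three classes; classes with no true samples are excluded
with a warning. This is a documented convention — other conventions
(micro, weighted) give different numbers, and none is canonical for
3-class panels.

## Problem sizes and determinism

Default analyses run the full n = 146 cohort; seed-averaged properties
use 30–100 seeds for statistical checks and 10–50 active-learning
repetitions, sizes chosen so the whole suite re-runs comfortably on a
single CPU. One root integer seed feeds named deterministic sub-streams
(cohort, plate, split, per-iteration model init, sampling estimator) via
`numpy.random.SeedSequence` spawn keys, so every stage is independently
reproducible and `report.json`, feature tables and query histories are
byte-identical across runs at fixed seed and config.
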