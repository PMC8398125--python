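# Methods

## Problem and model

The package classifies activities of daily living from annotated binary
sensor event logs.  An activity instance is a contiguous run of sensor
events bracketed by `begin`/`end` annotations of one label.  The classifier
input has two parts:

1. **Event sequence.**  Each (sensor, state) pair observed in the corpus
   becomes an integer token (index 0 is reserved for padding; tokens are
   ordered lexicographically so two builds agree).  The instance's event
   sequence is aligned to a fixed length L = 20: shorter sequences are
   front-padded with the pad token, longer ones keep their last 20 events.
   Front-padding (rather than back-padding) keeps the most recent events
   adjacent to the end of the sequence in both reading directions.
2. **External temporal context.**  The one-hot previous-activity vector
   **p** (9 elements; all-zero for the first instance of a stream, so a
   missing context injects no information) and the begin hour scaled as
   hour/23 ∈ [0, 1].  The scaling keeps the hour comparable in range to
   the pooled features and the one-hot entries; unscaled hours (0–23)
   would dominate the concatenated vector.

A bidirectional LSTM (60 nodes per direction by default) consumes the
token sequence; tokens enter as learned rows of the input weight matrix,
which is exactly a one-hot-times-matrix product over the sensor×state
alphabet.  The per-step outputs of the two directions are stacked into the
feature matrix **B** (120 × 20 in the reference configuration).  Temporal
max-pooling takes each feature's maximum over the 20 steps, making the
representation independent of where in the window a pattern occurred.  The
pooled vector, concatenated with the externals, feeds a fully connected
network: a 50-unit ReLU hidden layer and a 9-unit sigmoid output layer.
Prediction is the argmax of the sigmoid outputs (ties break toward the
lower class index).

## Training

The output layer is sigmoid per class, so the default loss is per-class
binary cross-entropy against one-hot targets; a softmax/cross-entropy
variant sits behind `ModelSpec.loss="softmax"`.  Optimization is Adam
(learning rate 1e-3, β₁ 0.9, β₂ 0.999), mini-batches of 32, 60 epochs.
These optimizer settings are this package's choice, made once for stability
at the 540-sample scale of the balanced design.  The whole network —
forward pass, backpropagation through time, the max-pooling subgradient
(gradient routed to the argmax time step of each feature), Adam — is
implemented in NumPy.  Initialization is Glorot-uniform; the forget-gate
bias starts at 1.  Weight initialization and epoch shuffling derive from a
single integer seed, so training histories are bitwise reproducible.

## Evaluation protocol

The balanced design draws 60 instances per class (540 total) uniformly
without replacement; stratified 10-fold CV puts 54/6 instances per class
into each fold's train/test split.  Reported scores accumulate confusion
counts over folds and over repeated draws of the balanced set (5 repeats by
default; each repeat re-draws the sample and re-initializes weights from
fresh derived seeds).  Metrics are one-vs-rest per class — precision,
recall, specificity, F1, accuracy (%) and error = 100 − accuracy — with
unweighted (macro) means; under the balanced design macro and weighted
means coincide.  When a row-normalized confusion matrix is supplied instead
of counts, each class row carries equal weight, which is the same
equal-prevalence convention.  A class never predicted gets precision 0 (and
F1 0) with a warning.

Two further protocols mirror deployment:

* **Held-out evaluation** applies the fold models to the instances not
  drawn into the balanced set.  That remainder is heavily imbalanced, so
  Recall is the headline macro metric.
* **Sequential (real-time) evaluation** feeds each instance the model's
  *previous prediction* as its previous-activity feature.  The stream is
  cut into consecutive ≥7-day windows; each window re-anchors at the first
  Sleeping instance at or after the 7-day boundary and its first instance
  gets the ground-truth predecessor.  This measures how prediction errors
  propagate through the context feature.  Windows with fewer than two
  instances are skipped with a warning.  With a perfect predictor the
  protocol reduces exactly to the ground-truth-context evaluation, which
  the tests exploit as a fixed-point check.

## Synthetic data generator

The generator emulates the statistical structure the method exploits, not
any particular household's numerics:

* a previous→current transition matrix with the structural zeros real
  single-resident data shows (Enter_Home follows only Leave_Home, and
  Leave_Home is always followed by Enter_Home; Bed_to_Toilet follows only
  Sleeping);
* hour-of-day start propensities (Sleeping concentrated 21:00–01:00,
  Bed_to_Toilet 00:00–05:00, meals at meal times);
* per-class categorical sensor emissions over 31 motion + 4 door sensors,
  with Meal_Preparation and Wash_Dishes sharing kitchen sensors — the
  hardest confusion in real data, since both happen in the same location;
* per-class Poisson counts of ON/OFF event pairs (clipped to 1–100 pairs)
  with exponential inter-event and inter-activity gaps.

A schedule loop advances a clock through the simulated days: the next
activity's begin hour is drawn from its hour weights restricted to the
remaining hours of the current day, rolling over to the next day when no
mass remains.  All randomness flows through one generator seeded from
`SimConfig.seed`, and the emitted log is byte-reproducible.

Two presets bracket difficulty for testing: `separable` (disjoint per-class
sensor sets — the sequence alone identifies the class) and
`transition_only` (identical emissions for all classes — only the temporal
context is informative).  What passing tests on these presets show is that
the pipeline learns the signal each preset isolates; they do not show
real-data accuracy, since real logs add sensor noise, annotation errors,
within-class multimodality and long-range routine drift that the generator
deliberately omits.

## Numerical and test-design choices

* **Problem sizes.**  The stochastic end-to-end checks simulate 500 days
  (≈3,000 instances, ≥60 per class including the rare Bed_to_Toilet),
  balance to 60 per class and run 10-fold CV with one repeat; convergence
  checks use ≈1,700 days (≥10,000 instances).  These sizes are the
  package's reproducibility defaults.
* **Transition-frequency convergence.**  At 10,000 instances the rarest
  transition row (Bed_to_Toilet, ~3% of transitions) has a multinomial
  standard error larger than any practical uniform tolerance on the
  conditional probabilities, so the convergence test compares the
  *joint* (previous, current) frequencies against the stationary-weighted
  transition matrix at tolerance 0.02 — a many-sigma bound at that n,
  which genuinely detects generator bias — plus a per-row chi-square
  goodness-of-fit test and exact checks of the structural zeros.
* **Previous-activity bookkeeping.**  Context is attached on the full
  chronological stream *before* class selection and balancing, so
  `prev_label` always records the true temporal predecessor, even one of a
  later-dropped class; the rare-class filter does not re-link context.
* **Degenerate inputs.**  An instance whose events were all removed by
  cleaning encodes to the all-pad sequence; unseen (sensor, state) pairs
  raise by default or map to the pad token under `lenient=True`;
  overlapping annotation spans raise (single-resident logs do not nest
  annotations — nesting would be a labelling error we prefer loud).
* **Dialect.**  Input lines split on arbitrary whitespace runs (real logs
  mix tabs and spaces); output uses a single tab and always six fractional
  digits, making parse∘write the identity on generated logs.  Non-monotone
  timestamps warn and keep file order.

## Known limitations

* Single resident, single annotation track; no "Other" class for events
  outside annotated spans.
* No dropout or other regularization — the reference configuration trains
  on 486 samples where none was needed; larger corpora may want it.
* The NumPy implementation targets clarity and exact reproducibility on
  one CPU, not GPU throughput.
* The simulator's first-order activity chain cannot express longer routine
  dependencies (e.g., weekday/weekend structure).
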