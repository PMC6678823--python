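# Methods

This note records the modelling choices, defaults and numerical conventions
behind `enhsnap`, and what its tests do and do not establish.

## Sequence encoding

A fragment over {A, C, G, T} of length *L* ≥ 2 maps to an *L*×10 matrix.
Columns 0–3 are the one-hot base identity in fixed alphabetical order
A, C, G, T; the order is arbitrary for learning but is part of the on-disk
contract for encoded tensors and checkpoints. Columns 4–9 are the six
normalized dinucleotide physicochemical properties (Rise, Roll, Shift,
Slide, Tilt, Twist) of the base step starting at that position, taken
verbatim from the published normalized lookup table; they are *not*
re-derived from raw biophysical constants, whose provenance and
normalization windows are not part of this package. The table is
reverse-complement symmetric (e.g. AG and CT share one row), which the test
suite asserts for all 16 dinucleotides.

The last row of every encoding carries −1 in the six property channels,
because no dinucleotide starts at the final position. The padding is applied
at encoding time and flows into the network unchanged; −1 is outside the
[0, 1] property range, so the first GRU layer can learn to recognize it.
One-hot channels are never padded.

Ambiguous bases (N, IUPAC codes) have a configurable policy: `reject`
(default — encoding is refused with the offending position named) or
`drop-sequence`. Sequences of any length ≥ 2 encode, but a pipeline run
enforces one fixed length: a model trained at 200 bp refuses other lengths
at prediction time rather than silently trimming or tiling.

## Classifier family

All catalog models are binary classifiers ending in a single sigmoid unit
trained with binary cross-entropy. Building blocks:

* **GRU** — standard two-gate formulation: update gate z, reset gate r,
  candidate h̃ = tanh(W_c x + U_c (r⊙h) + b_c), new state
  h′ = z⊙h + (1−z)⊙h̃. Gate activations are sigmoids, the candidate tanh.
  The final hidden state of the last recurrent layer feeds the dense head;
  earlier recurrent layers pass their full hidden sequence on.
  Bidirectional layers run a second cell over the reversed sequence and
  *concatenate* the two directions (per position for intermediate layers,
  final states for the last one). Concatenation rather than summation keeps
  the two directions' features separate; it doubles the downstream width.
* **Conv1D front end** — 16 channels, kernel 9, stride 1, valid (no)
  padding, ReLU; followed by non-overlapping max-pool of width 2. On 200-bp
  input: 200 → 192 → 96 recurrent steps. Valid padding avoids inventing
  boundary context; the one-position remainder a pool may drop is accepted.
* **Dense** — ReLU, except the linear output unit.
* **Dropout** — inverted dropout applied to the *inputs* of each GRU and
  dense layer at the catalog-specified rate (0.1–0.6); identity in
  evaluation mode.
* **L1+L2 penalties** — 3 × 10⁻⁵ each on weight matrices (not biases) of
  conv/GRU/dense layers in the `_l1l2` variant, folded into the gradient at
  update time.

Initialization is Glorot-uniform for weights and zero for biases, drawn from
a generator seeded per model, so a (spec, seed) pair reproduces a model
bitwise. The compute core is plain numpy with hand-derived reverse-mode
gradients; every layer's backward pass is checked against central finite
differences in the test suite (worst relative error at order 10⁻⁴, the
noise floor set by ReLU kinks and float64 cancellation).

## Optimization and warm restarts

The optimizer is RMSProp with decay 0.9, epsilon 10⁻⁷, and constant default
rate 10⁻³ when no schedule is given. The warm-restart schedule evaluates

γ(t) = γ_min + ½(γ_max − γ_min)(1 + cos(π t / T)),  with t = epoch mod T,

so each cycle starts exactly at γ_max; γ_min is approached but not attained
(epoch T would, but belongs to the next cycle). Defaults follow the
published recipe: γ_min = 10⁻⁴, γ_max = 3 × 10⁻³ for the recurrent-only
model (10⁻³ for the conv/bi-GRU model). A degenerate schedule
(γ_min = γ_max) reproduces constant-rate training exactly, which the suite
uses as an equivalence check. The RMSProp accumulator deliberately persists
across cycle boundaries — only the learning rate resets.

Within each cycle, the parameters at the epoch of highest validation
accuracy are snapshotted ("best-within-cycle" reading: each cycle converges
to a local minimum whose best point is a usable model); a run of E epochs
with cycle length T therefore yields exactly E/T snapshots, and E must be a
multiple of T. Ties in validation accuracy keep the earlier epoch.
Single-model (non-restart) training retains the best-validation epoch of
the whole run, matching how validation results are conventionally reported
at their best epoch.

The validation split is stratified, seeded, and 20% by default (the split
fraction is not part of the published recipe; 0.2 is the common choice).
Batch size defaults to 32 (likewise unstated upstream). Training-history
loss is the plain data BCE, excluding weight penalties.

## Ensembles

Ensemble labels are majority votes over members' 0.5-thresholded
probabilities; the continuous score for ROC/AUC is the mean member
probability (the standard soft-voting companion). Even vote splits — which
cannot occur with the odd member counts selection typically returns, but are
legal — fall back to comparing the mean probability with the threshold.

Member selection scores candidate snapshot subsets of size 1..max_members
(default 5) by voted accuracy on the validation split: exhaustively when at
most 4096 subsets exist, otherwise by greedy forward selection. Ties prefer
the first subset in enumeration order — smaller, then earlier cycles — so
a singleton that matches a larger subset's accuracy wins; on cleanly
separable data the selected "ensemble" is therefore often a single
snapshot, and the Single and Ensemble report rows coincide.

## Evaluation

Sens = TP/(TP+FN), Spec = TN/(TN+FP), Acc = (TP+TN)/N and the Matthews
correlation coefficient with the 0-on-zero-marginal convention. The ROC
curve is a full threshold sweep (no intermediate-point dropping); AUC is the
trapezoidal area, which equals the rank statistic P(score₊ > score₋) with
ties at ½ — the suite verifies the equality to 10⁻⁹ including tied scores.
The decision threshold for converting probabilities to labels is 0.5,
configurable. Cross-validation uses stratified seeded folds; the pooled
summary row aggregates pooled confusion counts and pooled scores, matching
single-value report conventions.

## Synthetic benchmark

The generator emulates the *shape* of the public two-layer enhancer
benchmark: balanced classes of fixed 200-bp fragments, with the layer-2
(strong vs. weak) set drawn from the layer-1 positives at half the size.
Negatives are i.i.d. uniform-background draws. Enhancers carry
non-overlapping planted copies of a 12-bp motif; weak enhancers receive 5
copies and strong enhancers 12, so motif dosage is the only layer-2 signal.
The default motif is an exact consensus 12-mer (each PWM column
concentrated on one base); the `consensus_pwm(weight=...)` knob softens it.

These defaults were calibrated once so that the bundled tasks are *fast but
not trivial* for the catalog's models on a single CPU: the smallest model
(one 8-unit GRU) exceeds 0.9 validation accuracy within 50 epochs on
layer 1, and the two-GRU-layer workhorse reaches high held-out accuracy
within 3 × 20 warm-restart epochs on both layers. A sparser or noisier
signal (one noisy motif copy) is not reliably learnable by these small
recurrent models in tens of epochs — credit assignment across 200 BPTT
steps needs either dense evidence or far longer training.

What passing on this benchmark shows: the encoding, training loop, schedule,
snapshot harvesting, selection, voting and metrics interact correctly and
deterministically, and the models can extract a planted sequence signal.
What it does not show: performance on real enhancer sequences, whose signal
is weaker, compositional, and not motif-dosage-coded; real benchmarks need
full-scale epoch budgets (cycles of 200 epochs, thousands of epochs
total) that the catalog and configuration expose but the bundled defaults
deliberately scale down (3 cycles × 20 epochs, 200 training sequences per
class) to keep runs in CPU-minutes.

## Degenerate inputs and numeric conventions

* Sequences shorter than 2 bp, non-ACGT residues (under `reject`), ragged
  batch lengths, empty datasets, non-binary labels: refused with specific
  errors, before any training starts.
* MCC/Sens/Spec return 0 on empty denominators; metrics on zero total
  counts are refused; AUC on single-class truth is refused.
* All computation is float64; seeded runs are bitwise reproducible
  (verified by byte-comparing rerun metrics tables).
* Checkpoints are `.npz` archives embedding the architecture spec, build
  seed and training length; ensemble manifests are JSON listing member
  checkpoints, selection record and aggregation mode.

## Known limitations

* No GPU path and no framework interop; full-scale epoch budgets are
  CPU-hours with this numpy core.
* The cascade composition (apply layer 2 only to layer-1 positives) is not
  the evaluated protocol; the two layers are independent experiments.
* The generator does not model real genomic background (GC skew, repeats,
  positional preferences), so measured accuracies on it say nothing
  quantitative about real-data performance.
* LSTM variants, attention, bagging/boosting ensembles are out of scope.
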