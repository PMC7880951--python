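# Methods

## Scope and model

`eventkappa` scores agreement between two equal-length streams of
per-sample event labels — typically a hand-coded ground truth and an
algorithm's output for the same gaze recording. The unit of analysis is
the *event*: a maximal run of one label, represented as a half-open
`[onset, offset)` interval of 0-based sample indices. All arithmetic is in
samples; a sampling rate can be attached to a stream but is metadata only,
since the score depends only on the label sequences. Streams of unequal
length are rejected outright rather than truncated — silent truncation
would shift every subsequent boundary and corrupt the matching.

Labels outside the classes under evaluation (e.g. an "undefined" code) are
retained as ordinary classes; under binarization they fall into the
negative class. Excluding such samples before scoring is possible by
preprocessing the streams, but is not the default.

## Matching

Per-event scoring first binarizes both event lists for the class under
evaluation (positive = that class, negative = all others, adjacent
negatives merged), then pairs events one-to-one by temporal overlap:

* ground-truth events are visited in temporal order;
* each takes the not-yet-consumed algorithm event with the largest sample
  overlap; ties break to the earliest onset; zero overlap never pairs;
* a ground-truth event with no free overlapping candidate stays unmatched,
  as does any algorithm event left unconsumed.

The criterion (most overlap) fixes the outcome only up to sweep order and
tie-breaks; ground-truth-major temporal order with earliest-onset
tie-breaking was chosen for determinism and because the comparison is
framed as finding, for each ground-truth event, its counterpart in the
algorithm stream. Matching is label-blind: a positive ground-truth event
may pair with a negative algorithm event, producing an off-diagonal
confusion count. Because event lists tile the stream, the candidates
overlapping a given event form a contiguous block, located by bisection;
`match_events_oracle` re-derives the same rule by brute force (full scan,
overlap counted via explicit sample-set intersection) and exists only as
an independent test reference.

## Confusion matrices and kappa

Matched pairs increment cell `(gt_label, alg_label)`. Unmatched positive
events are errors under every scheme: in the ground truth a false negative
(POS, NEG), in the algorithm stream a false positive (NEG, POS). Unmatched
negative events are governed by the scheme:

* **true-negative** (`tn`): counted in (NEG, NEG), so every input event
  contributes and the per-event score stays procedurally close to the
  overall multi-class score;
* **disregard** (`disregard`, default): omitted, so events not under
  evaluation neither raise nor lower the score; the price is that the
  result is an approximate kappa over the retained events only (the
  omitted share is reported separately as the unmatched-negative
  fraction);
* **error** (`error`): counted off-diagonal, penalizing misclassification
  of the classes not under evaluation; this systematically depresses κ
  and can push it below zero.

For the error scheme the exact cell is genuinely ambiguous. The default
keeps each unmatched negative event on its own stream's margin
(ground-truth stream → (NEG, POS), algorithm stream → (POS, NEG)), which
preserves truthful row/column margins: a negative ground-truth event stays
on the negative ground-truth margin. The opposite reading — literally a
false negative (POS, NEG) for a ground-truth event and a false positive
(NEG, POS) for an algorithm event — is available via
`literal_error_cells=True` (CLI `--literal-error-cells`); both conventions
add the same off-diagonal mass and depress κ similarly.

Kappa itself is evaluated in exact integer arithmetic,
`κ = (N·trace − Σ_k r_k c_k) / (N² − Σ_k r_k c_k)`, so hand-computable
cases are bit-exact. Degenerate input with `p_e = 1` (all mass forced into
one margin pair, so chance agreement is certain) is defined as κ = 1 when
observed agreement is also perfect and 0 otherwise; this avoids 0/0 while
keeping "identical streams score 1.0" an exact invariant. The report
flags these cases in its `warnings` list. An empty matrix raises
`UndefinedScoreError`.

## Overall kappa and event error rate

The overall score matches the *multi-class* event lists and computes κ
over the label pairs of matched events only. Unmatched events are excluded
from that matrix and surfaced instead through the event error rate

    EER = (S + D + I) / N_gt

with S = matched pairs whose labels differ, D = unmatched ground-truth
events (deletions), I = unmatched algorithm events (insertions), and N_gt
the ground-truth event count — the word-error-rate analogue. EER is 0
exactly when the two canonical event lists are identical and is not
bounded above by 1 (insertions can outnumber ground-truth events). This
definition is a package choice: EER is reported here as a conventional,
deterministic discrepancy rate, and readers comparing against other tools
should check which definition those use.

The unmatched-negative fraction — unmatched negative events over all
negative events, both streams pooled — quantifies exactly what the
disregard scheme omits.

## Synthetic streams

The generator emulates the event structure of 500-Hz gaze recordings, not
their waveforms: a grammar walk (fixation → saccade → {PSO | fixation},
PSO → fixation, uniform choice among successors) followed by one uniform
integer duration per event. Defaults: 100 events; fixations 50–250
samples, saccades 10–40, PSOs 5–20 at a nominal 500 samples/s. These
duration scales were chosen once as representative of high-speed
eye-tracking data; they are artifact choices, not measurements. The
perturber degrades a stream the way a disagreeing coder or imperfect
classifier would: per event, in temporal order, independent decisions to
delete (merge into the predecessor; a deleted first event merges into its
successor), relabel (uniform over the other classes), and insert (split an
event of duration ≥ 2 at a uniform point and relabel the second part);
then each internal boundary moves by a rounded Gaussian offset
(`jitter_sd`, default 2 samples), clamped so every event keeps at least
one sample. Perturbation defaults are jitter 2, 5% each for
delete/insert/relabel — mild, realistic disagreement that leaves κ in the
0.5–0.9 range where the three schemes separate visibly.

All randomness flows through one seeded generator with a fixed draw order
(grammar walk, then durations; per-event perturbation decisions drawn
unconditionally in event order, then jitter), so a seed fully determines
the output and seeds are portable across code paths. Stream length is
conserved by construction and all-zero parameters are the exact identity.

What the synthetic regime does *not* model: raw gaze coordinates, noise
waveforms, saccade kinematics, non-constant intersample intervals, or
class-dependent disagreement structure (real classifiers err more on PSOs
than on fixations). Passing tests therefore demonstrate the correctness
and qualitative behaviour of the *scoring machinery* — e.g. that the error
scheme systematically lowers κ, or that agreement degrades monotonically
with relabeling noise — not quantitative performance of any real
classifier on real data.

## Numerical and design notes

* Kappa is exact rational arithmetic in int64; overflow would need
  N > ~3·10⁹ events, far beyond any recording.
* Matching is deterministic; the only tie-break (equal overlap) is
  resolved by onset order.
* The per-event/overall split follows the asymmetry of the problem: the
  binary matrices need an unmatched-negative policy, the multi-class
  matrix does not (unmatched events of any class go to the EER instead).
* The CLI is a thin wrapper over the library and reports byte-identical
  numbers; JSON reports embed the full configuration and tool version.

## Limitations

* Greedy ground-truth-major matching is not globally optimal; an
  assignment-problem or IoU-threshold matcher would occasionally pair
  differently. Those are deliberate non-goals — the implemented rule is
  the one under study.
* The disregard scheme's κ is approximate in the sense that its matrix
  omits the unmatched negatives; no bound on the approximation is
  attempted, but the omitted share is always reported.
* Scores operate on already-labeled streams; event detection from raw
  coordinates, resampling, and proprietary eye-tracker formats are out of
  scope.
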