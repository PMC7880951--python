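"""Synthetic eye-movement label streams and controlled perturbations.

The generator emulates the event structure of high-speed (500 Hz) gaze
recordings: a grammar walk over event classes (by default
fixation -> saccade -> {PSO | fixation}, PSO -> fixation) with per-class
uniform duration ranges.  The perturber then degrades a ground-truth stream
the way a second coder or an imperfect classifier would: Gaussian jitter of
event boundaries, deletion of events (merged into a neighbour), insertion
of spurious events (splitting an existing one), and relabeling.  All
randomness flows through a single seeded generator with a fixed draw order
— grammar walk, then durations, then perturbation decisions in event order,
then boundary jitter — so a seed fully determines the output.

Default regime (configurable): 500 samples/s; fixations 50-250 samples,
saccades 10-40, PSOs 5-20.  These are artifact choices picked to resemble
the duration scales of 500-Hz eye-tracking data, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from eventkappa.streams import LabeledStream

FIXATION = "fixation"
SACCADE = "saccade"
PSO = "pso"

DEFAULT_CLASSES: tuple[str, ...] = (FIXATION, SACCADE, PSO)

#: Per-class (min, max) event durations in samples, inclusive, at 500 Hz.
DEFAULT_DURATION_RANGES: dict[str, tuple[int, int]] = {
    FIXATION: (50, 250),
    SACCADE: (10, 40),
    PSO: (5, 20),
}

#: Allowed successions: saccades follow fixations; a saccade ends in a PSO
#: or directly in a fixation; a PSO always ends in a fixation.
DEFAULT_GRAMMAR: dict[str, tuple[str, ...]] = {
    FIXATION: (SACCADE,),
    SACCADE: (PSO, FIXATION),
    PSO: (FIXATION,),
}


@dataclass
class GeneratorParams:
    """Configuration of the ground-truth stream generator.

    ``n_events`` is the number of events in the generated stream;
    ``duration_ranges`` maps each class to an inclusive (min, max) duration
    in samples; ``grammar`` maps each class to its allowed successors;
    ``sampling_rate`` is metadata attached to the stream.
    """

    sampling_rate: float = 500.0
    n_events: int = 100
    duration_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_RANGES)
    )
    grammar: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_GRAMMAR.items()}
    )
    start_class: str = FIXATION
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        for cls, (lo, hi) in self.duration_ranges.items():
            if lo < 1 or hi < lo:
                raise ValueError(
                    f"invalid duration range for {cls!r}: ({lo}, {hi}); "
                    "minimum must be >= 1 and max >= min"
                )
        if self.start_class not in self.duration_ranges:
            raise ValueError(
                f"start class {self.start_class!r} has no duration range"
            )
        # Every class reachable from the start must be able to continue
        # (nonempty successor list) and must have a duration range.
        seen = {self.start_class}
        frontier = [self.start_class]
        while frontier:
            cls = frontier.pop()
            succs = self.grammar.get(cls, ())
            if not succs:
                raise ValueError(
                    f"grammar dead end: class {cls!r} is reachable but has "
                    "no successors"
                )
            for s in succs:
                if s not in self.duration_ranges:
                    raise ValueError(f"class {s!r} has no duration range")
                if s not in seen:
                    seen.add(s)
                    frontier.append(s)


@dataclass
class PerturbationParams:
    """Configuration of the stream perturber.

    ``jitter_sd`` is the standard deviation (samples) of the Gaussian
    offset applied to each event boundary; ``p_delete``, ``p_insert`` and
    ``p_relabel`` are independent per-event probabilities.  All-zero
    parameters make the perturbation the identity map.
    """

    jitter_sd: float = 2.0
    p_delete: float = 0.05
    p_insert: float = 0.05
    p_relabel: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for name in ("p_delete", "p_insert", "p_relabel"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def generate_gt_stream(params: GeneratorParams | None = None) -> LabeledStream:
    """Generate a ground-truth label stream from a grammar walk.

    The class sequence is drawn first (uniform choice among the successors
    allowed by the grammar), then one duration per event (uniform integer
    within the class range).  Identical parameters and seed give identical
    output.
    """
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    classes = [params.start_class]
    for _ in range(params.n_events - 1):
        succs = params.grammar[classes[-1]]
        classes.append(succs[int(rng.integers(len(succs)))])

    durations = [
        int(rng.integers(params.duration_ranges[c][0], params.duration_ranges[c][1] + 1))
        for c in classes
    ]

    labels: list[str] = []
    for cls, dur in zip(classes, durations):
        labels.extend([cls] * dur)
    class_set = tuple(params.duration_ranges)
    return LabeledStream(
        labels=labels, class_set=class_set, sampling_rate=params.sampling_rate
    )


def _relabel_choice(rng: np.random.Generator, current: str, class_set: tuple[str, ...]) -> str:
    others = [c for c in class_set if c != current]
    return others[int(rng.integers(len(others)))]


def perturb_stream(
    gt: LabeledStream, params: PerturbationParams | None = None
) -> LabeledStream:
    """Produce a degraded copy of a stream, emulating coder/classifier
    disagreement.

    Per original event, in temporal order, three decisions are drawn
    (delete, relabel, insert, each with its auxiliary draws made
    unconditionally so the random state advances identically regardless of
    outcome); a deleted event merges into its predecessor (the first event
    merges into its successor), a relabeled event takes a different class
    uniformly at random, an inserted event splits an event of duration >= 2
    and relabels the second part.  Boundary jitter is applied last: each
    internal boundary moves by a rounded Gaussian offset, clamped so both
    neighbouring events keep duration >= 1.  Stream length is always
    preserved, and all-zero parameters return the input labels unchanged.
    """
    if len(gt) == 0:
        raise ValueError("cannot perturb an empty stream")
    params = params or PerturbationParams()
    params.validate()
    if len(gt.class_set) < 2:
        raise ValueError("perturbation requires at least two classes")
    rng = np.random.default_rng(params.seed)

    # Run-length encode (plain lists; intermediate states need not be
    # canonical, e.g. after a relabel two neighbours may share a class).
    runs: list[list] = []  # [label, duration]
    for lab in gt.labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])

    # Pass 1: per-event decisions, in event order.
    decisions = []
    for lab, dur in runs:
        delete = rng.random() < params.p_delete
        relabel = rng.random() < params.p_relabel
        new_label = _relabel_choice(rng, lab, gt.class_set)
        insert = rng.random() < params.p_insert
        split_frac = rng.random()
        lab_after = new_label if relabel else lab
        insert_label = _relabel_choice(rng, lab_after, gt.class_set)
        decisions.append((delete, relabel, new_label, insert, split_frac, insert_label))

    new_runs: list[list] = []
    carry = 0  # duration of a deleted first event, merged into its successor
    for (lab, dur), (delete, relabel, new_label, insert, split_frac, insert_label) in zip(
        runs, decisions
    ):
        dur += carry
        carry = 0
        label = new_label if relabel else lab
        if delete and len(runs) > 1:
            if new_runs:
                new_runs[-1][1] += dur
            else:
                carry = dur
            continue
        if insert and dur >= 2:
            split = 1 + int(split_frac * (dur - 1))
            new_runs.append([label, split])
            new_runs.append([insert_label, dur - split])
        else:
            new_runs.append([label, dur])
    if carry:  # every event was deleted into the carry; restore the last one
        new_runs.append([runs[-1][0], carry])

    # Pass 2: boundary jitter, left to right on the new event sequence.
    if len(new_runs) > 1:
        durs = [d for _, d in new_runs]
        boundaries = list(np.cumsum(durs))[:-1]
        onset = 0  # onset of the left neighbour, updated as we sweep
        for i, b in enumerate(boundaries):
            d = int(np.rint(rng.normal(0.0, params.jitter_sd)))
            right_end = boundaries[i + 1] if i + 1 < len(boundaries) else len(gt)
            boundaries[i] = int(np.clip(b + d, onset + 1, right_end - 1))
            onset = boundaries[i]
        edges = [0] + boundaries + [len(gt)]
        new_runs = [
            [new_runs[i][0], edges[i + 1] - edges[i]] for i in range(len(new_runs))
        ]

    labels: list[str] = []
    for lab, dur in new_runs:
        labels.extend([lab] * dur)
    assert len(labels) == len(gt), "perturbation must conserve stream length"
    return LabeledStream(
        labels=labels, class_set=gt.class_set, sampling_rate=gt.sampling_rate
    )
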