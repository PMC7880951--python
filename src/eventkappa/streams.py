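"""Sample-level label streams and their event-list representation.

A recording is a sequence of class labels, one per gaze sample.  Scoring
operates on *events*: maximal runs of identical labels, represented as
half-open ``[onset, offset)`` sample intervals.  Time is measured in samples
throughout; a sampling rate may be attached to a stream but is metadata only
and never enters any score.

Binary (per-event-class) scoring reduces a multi-class event list to two
labels, :data:`POSITIVE` (the class under evaluation) and :data:`NEGATIVE`
(everything else, merged), via :func:`binarize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

#: Label of the event class under evaluation in a binarized event list.
POSITIVE = "POS"
#: Label of all other classes, merged, in a binarized event list.
NEGATIVE = "NEG"


@dataclass(frozen=True)
class Event:
    """A contiguous labeled interval ``[onset, offset)`` of samples."""

    onset: int
    offset: int
    label: str

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(
                f"event must span at least one sample: [{self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> int:
        """Event duration in samples."""
        return self.offset - self.onset


@dataclass
class LabeledStream:
    """Per-sample class labels for one recording or coder.

    Parameters
    ----------
    labels
        One class code per gaze sample, in recording order.
    class_set
        The admissible class codes.  Every label must be a member.
    sampling_rate
        Samples per second.  Carried as metadata only; scoring operates on
        sample indices and never uses it.
    """

    labels: list[str]
    class_set: tuple[str, ...]
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.class_set = tuple(self.class_set)
        allowed = set(self.class_set)
        for i, lab in enumerate(self.labels):
            if lab not in allowed:
                raise ValueError(
                    f"label {lab!r} at sample {i} is not in class_set {self.class_set}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)


@dataclass
class EventList:
    """Temporally ordered events tiling ``[0, stream_length)`` exactly.

    Invariants (checked on construction): the first event starts at 0, the
    last ends at ``stream_length``, each onset equals its predecessor's
    offset, and no two adjacent events share a label (canonical form).
    """

    events: list[Event]
    stream_length: int

    def __post_init__(self) -> None:
        self.events = list(self.events)
        if not self.events:
            if self.stream_length != 0:
                raise ValueError("empty event list must have stream_length 0")
            return
        if self.events[0].onset != 0:
            raise ValueError("first event must start at sample 0")
        if self.events[-1].offset != self.stream_length:
            raise ValueError(
                f"last event ends at {self.events[-1].offset}, "
                f"expected stream_length {self.stream_length}"
            )
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.onset != prev.offset:
                raise ValueError(
                    f"events do not tile: gap/overlap at sample {prev.offset}"
                )
            if cur.label == prev.label:
                raise ValueError(
                    f"adjacent events share label {cur.label!r} at sample {cur.onset}; "
                    "event lists are kept in canonical (merged) form"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)


def _runs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run boundaries of an integer code array: (run start indices, run ends)."""
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    return starts, ends


def labels_to_events(stream: LabeledStream | Sequence[str]) -> EventList:
    """Run-length encode a label stream into a canonical event list.

    Concatenating each event's label repeated ``duration`` times reproduces
    the input exactly.  An empty stream yields an empty list.
    """
    labels = list(stream.labels if isinstance(stream, LabeledStream) else stream)
    if not labels:
        return EventList(events=[], stream_length=0)
    arr = np.asarray(labels, dtype=object)
    _, codes = np.unique(arr, return_inverse=True)
    starts, ends = _runs(codes)
    events = [Event(int(a), int(b), labels[int(a)]) for a, b in zip(starts, ends)]
    return EventList(events=events, stream_length=len(labels))


def events_to_labels(
    ev: EventList,
    class_set: Iterable[str] | None = None,
    sampling_rate: float | None = None,
) -> LabeledStream:
    """Expand an event list back to per-sample labels (inverse of
    :func:`labels_to_events`).

    ``class_set`` defaults to the labels present, in order of first
    appearance; pass the original stream's class set to make the round trip
    an exact identity on :class:`LabeledStream`.
    """
    labels: list[str] = []
    for e in ev.events:
        labels.extend([e.label] * e.duration)
    if class_set is None:
        class_set = list(dict.fromkeys(labels))
    return LabeledStream(labels=labels, class_set=tuple(class_set), sampling_rate=sampling_rate)


def binarize(ev: EventList, positive_class: str) -> EventList:
    """Reduce a multi-class event list to POSITIVE/NEGATIVE events.

    Every sample belonging to ``positive_class`` becomes :data:`POSITIVE`;
    all other samples become :data:`NEGATIVE`.  Adjacent events of the same
    (binary) type are merged, so the result is canonical.
    """
    merged: list[Event] = []
    for e in ev.events:
        lab = POSITIVE if e.label == positive_class else NEGATIVE
        if merged and merged[-1].label == lab:
            prev = merged.pop()
            merged.append(Event(prev.onset, e.offset, lab))
        else:
            merged.append(Event(e.onset, e.offset, lab))
    return EventList(events=merged, stream_length=ev.stream_length)


def require_equal_length(gt: LabeledStream | EventList, alg: LabeledStream | EventList) -> None:
    """Raise ``ValueError`` unless the two inputs cover the same number of
    samples.  Unequal lengths are always a hard error; silent truncation
    would corrupt the matching."""
    n_gt = gt.stream_length if isinstance(gt, EventList) else len(gt)
    n_alg = alg.stream_length if isinstance(alg, EventList) else len(alg)
    if n_gt != n_alg:
        raise ValueError(
            f"streams have unequal length ({n_gt} vs {n_alg} samples); "
            "refusing to truncate"
        )
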