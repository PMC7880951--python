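"""Confusion matrices, Cohen's kappa, and the three unmatched-negative schemes.

Per-event (binary) scoring pipeline: binarize both event lists for the class
under evaluation, match one-to-one by maximum overlap, build a 2x2 confusion
matrix from the matched label pairs, and chance-correct with Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = trace / N,   p_e = sum_k row_k * col_k / N**2.

Matched pairs always count toward the cell ``(gt_label, alg_label)`` and
unmatched *positive* events always count as errors (a missed positive is a
false negative, a spurious one a false positive).  Unmatched *negative*
events do not appear in any pair, so a policy — a :class:`Scheme` — decides
how they enter the matrix:

``UNMATCHED_AS_TN``
    count them as true negatives, so every input event contributes;
``DISREGARD_UNMATCHED``
    leave them out, so events not under evaluation neither raise nor lower
    the score (an approximate kappa over the retained events);
``UNMATCHED_AS_ERROR``
    count them as errors, penalising misclassification of the classes not
    under evaluation.  This systematically depresses kappa and can push it
    negative.

Multi-class summaries: an overall kappa over the label pairs of matched
events, and an event error rate (EER) defined as the word-error-rate
analogue ``(S + D + I) / N_gt`` — substitutions (matched pairs with
differing labels) plus deletions (unmatched ground-truth events) plus
insertions (unmatched algorithm events), relative to the number of
ground-truth events.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from eventkappa.matching import MatchResult, match_events
from eventkappa.streams import (
    NEGATIVE,
    POSITIVE,
    EventList,
    LabeledStream,
    binarize,
    labels_to_events,
    require_equal_length,
)


class UndefinedScoreError(ValueError):
    """A score has no defined value for this input (e.g. empty matrix)."""


class Scheme(enum.Enum):
    """Policy for unmatched negative events in the binary confusion matrix."""

    UNMATCHED_AS_TN = "tn"
    DISREGARD_UNMATCHED = "disregard"
    UNMATCHED_AS_ERROR = "error"

    @classmethod
    def from_string(cls, name: str) -> "Scheme":
        for s in cls:
            if name in (s.value, s.name, s.name.lower()):
                return s
        raise ValueError(
            f"unknown scheme {name!r}; expected one of "
            + ", ".join(s.value for s in cls)
        )


@dataclass
class ConfusionMatrix:
    """K x K matched-event counts; rows index the ground-truth class,
    columns the algorithm class."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.class_order = tuple(self.class_order)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} classes {self.class_order}"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def observed_agreement(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def expected_agreement(self) -> float:
        n = self.total
        rows = self.counts.sum(axis=1)
        cols = self.counts.sum(axis=0)
        return float(rows @ cols) / (n * n)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa of a confusion matrix, in [-1, 1].

    Evaluated in exact integer arithmetic as
    ``(N*trace - sum_k row_k*col_k) / (N**2 - sum_k row_k*col_k)`` so that
    hand-computable cases come out exactly.

    Raises :class:`UndefinedScoreError` on an empty matrix.  In the
    degenerate case ``p_e == 1`` (all mass concentrated so that chance
    agreement is certain) the value is defined as 1.0 when observed
    agreement is also perfect and 0.0 otherwise, preserving the
    perfect-agreement invariant without a 0/0.
    """
    n = cm.total
    if n == 0:
        raise UndefinedScoreError("kappa is undefined for an empty confusion matrix")
    trace = int(np.trace(cm.counts))
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    pe_num = int(rows @ cols)  # p_e * N**2
    denom = n * n - pe_num
    if denom == 0:  # p_e == 1
        return 1.0 if trace == n else 0.0
    return (n * trace - pe_num) / denom


def _is_binary(ev: Iterable) -> bool:
    return all(e.label in (POSITIVE, NEGATIVE) for e in ev)


def confusion_from_matches(
    match: MatchResult,
    scheme: Scheme,
    literal_error_cells: bool = False,
) -> ConfusionMatrix:
    """2x2 confusion matrix (classes POS, NEG) from a binary match result.

    Matched pairs increment cell ``(gt_label, alg_label)``.  Unmatched
    positive events are scheme-independent errors: a ground-truth one is a
    false negative, cell (POS, NEG); an algorithm one a false positive,
    cell (NEG, POS).  Unmatched negative events follow ``scheme``.

    Under ``UNMATCHED_AS_ERROR`` the default cell assignment keeps each
    unmatched negative event on its own stream's margin — ground-truth
    stream into (NEG, POS), algorithm stream into (POS, NEG) — preserving
    marginal truthfulness.  ``literal_error_cells=True`` selects the
    opposite convention (ground-truth unmatched negatives as false
    negatives, algorithm ones as false positives); both drive kappa lower.
    """
    order = (POSITIVE, NEGATIVE)
    idx = {POSITIVE: 0, NEGATIVE: 1}
    counts = np.zeros((2, 2), dtype=np.int64)

    all_events = (
        [g for g, _, _ in match.pairs]
        + [a for _, a, _ in match.pairs]
        + match.unmatched_gt
        + match.unmatched_alg
    )
    if not _is_binary(all_events):
        raise ValueError(
            "confusion_from_matches requires a match built from binarized "
            "(POS/NEG) event lists"
        )

    for g, a, _ in match.pairs:
        counts[idx[g.label], idx[a.label]] += 1

    for e in match.unmatched_gt:
        if e.label == POSITIVE:
            counts[0, 1] += 1  # false negative
        elif scheme is Scheme.UNMATCHED_AS_TN:
            counts[1, 1] += 1
        elif scheme is Scheme.UNMATCHED_AS_ERROR:
            if literal_error_cells:
                counts[0, 1] += 1
            else:
                counts[1, 0] += 1
        # DISREGARD_UNMATCHED: not counted

    for e in match.unmatched_alg:
        if e.label == POSITIVE:
            counts[1, 0] += 1  # false positive
        elif scheme is Scheme.UNMATCHED_AS_TN:
            counts[1, 1] += 1
        elif scheme is Scheme.UNMATCHED_AS_ERROR:
            if literal_error_cells:
                counts[1, 0] += 1
            else:
                counts[0, 1] += 1

    return ConfusionMatrix(counts=counts, class_order=order)


def per_event_agreement(
    gt: EventList,
    alg: EventList,
    target_class: str,
    scheme: Scheme,
    literal_error_cells: bool = False,
) -> float:
    """Binary event-level kappa for one class under one scheme.

    Composition of binarize -> match -> confusion -> kappa; deterministic.
    """
    require_equal_length(gt, alg)
    match = match_events(binarize(gt, target_class), binarize(alg, target_class))
    cm = confusion_from_matches(match, scheme, literal_error_cells=literal_error_cells)
    return cohen_kappa(cm)


def confusion_from_multiclass_matches(
    match: MatchResult, class_order: Sequence[str]
) -> ConfusionMatrix:
    """K x K matrix over the label pairs of matched events only."""
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order),) * 2, dtype=np.int64)
    for g, a, _ in match.pairs:
        counts[idx[g.label], idx[a.label]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def overall_agreement(
    gt: EventList,
    alg: EventList,
    class_order: Sequence[str] | None = None,
) -> float:
    """Multi-class kappa over matched event pairs.

    Unmatched events (either side) are excluded from the matrix; their
    contribution is surfaced separately through :func:`event_error_rate`.
    Raises :class:`UndefinedScoreError` if no events could be matched.
    """
    require_equal_length(gt, alg)
    match = match_events(gt, alg)
    if class_order is None:
        seen = [e.label for e in gt.events] + [e.label for e in alg.events]
        class_order = list(dict.fromkeys(seen))
    cm = confusion_from_multiclass_matches(match, class_order)
    if cm.total == 0:
        raise UndefinedScoreError("no matched event pairs; overall kappa undefined")
    return cohen_kappa(cm)


def event_error_rate(match: MatchResult) -> float:
    """Event error rate ``(S + D + I) / N_gt``.

    S: matched pairs whose labels differ; D: unmatched ground-truth events
    (deletions); I: unmatched algorithm events (insertions); N_gt: number of
    ground-truth events.  Zero exactly when the two streams have identical
    canonical event lists.  Not bounded above by 1 (insertions can exceed
    the ground-truth event count).
    """
    n_gt = len(match.pairs) + len(match.unmatched_gt)
    if n_gt == 0:
        raise UndefinedScoreError("EER undefined: no ground-truth events")
    s = sum(1 for g, a, _ in match.pairs if g.label != a.label)
    return (s + len(match.unmatched_gt) + len(match.unmatched_alg)) / n_gt


def unmatched_negative_fraction(match: MatchResult) -> float:
    """Share of negative events (both streams pooled) left unmatched.

    Requires a match built from binarized lists; raises
    :class:`UndefinedScoreError` when neither stream contains a negative
    event.
    """
    matched_neg = sum(1 for g, _, _ in match.pairs if g.label == NEGATIVE)
    matched_neg += sum(1 for _, a, _ in match.pairs if a.label == NEGATIVE)
    unmatched_neg = sum(1 for e in match.unmatched_gt if e.label == NEGATIVE)
    unmatched_neg += sum(1 for e in match.unmatched_alg if e.label == NEGATIVE)
    total_neg = matched_neg + unmatched_neg
    if total_neg == 0:
        raise UndefinedScoreError(
            "unmatched-negative fraction undefined: no negative events"
        )
    return unmatched_neg / total_neg


@dataclass
class AgreementReport:
    """Full scoring output for one ground-truth/algorithm stream pair."""

    per_event_kappa: dict[tuple[str, Scheme], float]
    overall_kappa: float
    eer: float
    unmatched_negative_fraction: dict[str, float]
    confusion_matrices: dict[tuple[str, Scheme], ConfusionMatrix]
    overall_confusion: ConfusionMatrix
    stream_length: int
    class_set: tuple[str, ...]
    positive_classes: tuple[str, ...]
    schemes: tuple[Scheme, ...]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serializable form (kappas at full precision)."""
        per_event: dict[str, dict[str, float]] = {}
        matrices: dict[str, dict[str, list[list[int]]]] = {}
        for (cls, scheme), k in self.per_event_kappa.items():
            per_event.setdefault(cls, {})[scheme.value] = k
        for (cls, scheme), cm in self.confusion_matrices.items():
            matrices.setdefault(cls, {})[scheme.value] = cm.counts.tolist()
        return {
            "per_event_kappa": per_event,
            "overall_kappa": self.overall_kappa,
            "eer": self.eer,
            "unmatched_negative_fraction": dict(self.unmatched_negative_fraction),
            "confusion_matrices": matrices,
            "overall_confusion": {
                "class_order": list(self.overall_confusion.class_order),
                "counts": self.overall_confusion.counts.tolist(),
            },
            "stream_length": self.stream_length,
            "class_set": list(self.class_set),
            "positive_classes": list(self.positive_classes),
            "schemes": [s.value for s in self.schemes],
            "warnings": list(self.warnings),
        }


def evaluate(
    gt: LabeledStream,
    alg: LabeledStream,
    positive_classes: Sequence[str] | None = None,
    schemes: Sequence[Scheme] = (Scheme.DISREGARD_UNMATCHED,),
    literal_error_cells: bool = False,
) -> AgreementReport:
    """Score an algorithm stream against a ground-truth stream.

    Computes the per-event binary kappa for every requested class under
    every requested scheme, the unmatched-negative fraction per class, and
    the multi-class overall kappa and event error rate.  Both streams must
    have equal length and (for well-defined results) be non-empty.
    """
    require_equal_length(gt, alg)
    if len(gt) == 0:
        raise UndefinedScoreError("cannot score empty streams")
    if positive_classes is None:
        positive_classes = gt.class_set
    unknown = [c for c in positive_classes if c not in gt.class_set]
    if unknown:
        raise ValueError(f"positive classes {unknown} not in class_set {gt.class_set}")
    if not schemes:
        raise ValueError("at least one scheme is required")

    gt_ev = labels_to_events(gt)
    alg_ev = labels_to_events(alg)

    warnings: list[str] = []
    per_event: dict[tuple[str, Scheme], float] = {}
    matrices: dict[tuple[str, Scheme], ConfusionMatrix] = {}
    unf: dict[str, float] = {}

    for cls in positive_classes:
        gt_bin = binarize(gt_ev, cls)
        alg_bin = binarize(alg_ev, cls)
        match = match_events(gt_bin, alg_bin)
        try:
            unf[cls] = unmatched_negative_fraction(match)
        except UndefinedScoreError:
            unf[cls] = 0.0
            warnings.append(f"{cls}: no negative events; unmatched fraction set to 0")
        for scheme in schemes:
            cm = confusion_from_matches(
                match, scheme, literal_error_cells=literal_error_cells
            )
            n = cm.total
            if n > 0 and n * n == int(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)):
                warnings.append(
                    f"{cls}/{scheme.value}: degenerate matrix (chance agreement "
                    "certain); kappa defined by the perfect-agreement rule"
                )
            per_event[(cls, scheme)] = cohen_kappa(cm)
            matrices[(cls, scheme)] = cm

    multi_match = match_events(gt_ev, alg_ev)
    class_order = tuple(gt.class_set)
    overall_cm = confusion_from_multiclass_matches(multi_match, class_order)
    if overall_cm.total == 0:
        raise UndefinedScoreError("no matched event pairs; overall kappa undefined")
    overall_kappa = cohen_kappa(overall_cm)
    eer = event_error_rate(multi_match)

    return AgreementReport(
        per_event_kappa=per_event,
        overall_kappa=overall_kappa,
        eer=eer,
        unmatched_negative_fraction=unf,
        confusion_matrices=matrices,
        overall_confusion=overall_cm,
        stream_length=len(gt),
        class_set=tuple(gt.class_set),
        positive_classes=tuple(positive_classes),
        schemes=tuple(schemes),
        warnings=warnings,
    )
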