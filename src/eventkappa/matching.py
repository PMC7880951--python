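"""One-to-one maximum-overlap matching of ground-truth and algorithm events.

Ground-truth events are visited in temporal order; each is paired with the
not-yet-consumed algorithm event sharing the most samples with it.  Ties are
broken toward the algorithm event with the earliest onset, and events with
zero overlap are never paired, so a ground-truth event with no overlapping
free candidate stays unmatched.  Matching is label-blind: a positive
ground-truth event may be paired with a negative algorithm event, and the
resulting label pair feeds the confusion matrix.

:func:`match_events_oracle` re-derives the same rule by brute force
(explicit scan of every remaining candidate, overlap counted sample by
sample) and exists purely as an independent reference for testing.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from eventkappa.streams import Event, EventList, require_equal_length


@dataclass
class MatchResult:
    """Outcome of matching two event lists.

    ``pairs`` holds ``(gt_event, alg_event, overlap_samples)`` triples; each
    event from either side appears in at most one pair, and every pair
    overlaps by at least one sample.  Events without a partner are listed in
    ``unmatched_gt`` / ``unmatched_alg``; together with the pairs they cover
    each side exactly once.
    """

    pairs: list[tuple[Event, Event, int]] = field(default_factory=list)
    unmatched_gt: list[Event] = field(default_factory=list)
    unmatched_alg: list[Event] = field(default_factory=list)


def overlap_samples(a: Event, b: Event) -> int:
    """Number of samples shared by two half-open intervals (0 if disjoint)."""
    return max(0, min(a.offset, b.offset) - max(a.onset, b.onset))


def match_events(gt: EventList, alg: EventList) -> MatchResult:
    """Greedy one-to-one max-overlap matching (ground-truth-major order).

    Both lists must cover the same number of samples.  Deterministic for
    fixed inputs.  Because event lists tile the stream, the algorithm events
    overlapping a ground-truth event form a contiguous block, located here
    by bisection; candidates are scanned in onset order so that a strict
    ``>`` keeps the earliest-onset event among equal overlaps.
    """
    require_equal_length(gt, alg)
    alg_events = alg.events
    onsets = [e.onset for e in alg_events]
    consumed = [False] * len(alg_events)
    result = MatchResult()

    for g in gt.events:
        lo = max(bisect_right(onsets, g.onset) - 1, 0)
        hi = bisect_left(onsets, g.offset)
        best_j = -1
        best_ov = 0
        for j in range(lo, hi):
            if consumed[j]:
                continue
            ov = overlap_samples(g, alg_events[j])
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0:
            consumed[best_j] = True
            result.pairs.append((g, alg_events[best_j], best_ov))
        else:
            result.unmatched_gt.append(g)

    result.unmatched_alg = [e for e, c in zip(alg_events, consumed) if not c]
    return result


def match_events_oracle(gt: EventList, alg: EventList) -> MatchResult:
    """Brute-force reference trace of the matching rule, for testing only.

    Same contract as :func:`match_events`, but every remaining algorithm
    event is examined for every ground-truth event and overlap is counted by
    intersecting explicit sample-index sets.  Intended for small instances
    (roughly <= 8 events per side).
    """
    require_equal_length(gt, alg)
    remaining = list(alg.events)  # stays sorted by onset
    result = MatchResult()

    for g in gt.events:
        g_samples = set(range(g.onset, g.offset))
        best = None
        best_ov = 0
        for cand in remaining:
            ov = len(g_samples & set(range(cand.onset, cand.offset)))
            if ov > best_ov:  # ties keep the earlier onset (scan order)
                best, best_ov = cand, ov
        if best is not None:
            remaining.remove(best)
            result.pairs.append((g, best, best_ov))
        else:
            result.unmatched_gt.append(g)

    result.unmatched_alg = remaining
    return result
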