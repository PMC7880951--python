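"""Confusion building, kappa, schemes, EER, unmatched-negative fraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eventkappa import (
    NEGATIVE,
    POSITIVE,
    ConfusionMatrix,
    Event,
    LabeledStream,
    MatchResult,
    Scheme,
    UndefinedScoreError,
    cohen_kappa,
    confusion_from_matches,
    evaluate,
    event_error_rate,
    labels_to_events,
    match_events,
    overall_agreement,
    per_event_agreement,
    unmatched_negative_fraction,
)
from eventkappa.agreement import confusion_from_multiclass_matches


def cm2(counts):
    return ConfusionMatrix(np.array(counts), (POSITIVE, NEGATIVE))


def pos(a, b):
    return Event(a, b, POSITIVE)


def neg(a, b):
    return Event(a, b, NEGATIVE)


class TestCohenKappa:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[45, 5], [5, 45]], 0.80),
            ([[10, 0], [0, 7]], 1.0),
            ([[1, 1], [1, 1]], 0.0),
            ([[0, 2], [2, 0]], -1.0),
        ],
    )
    def test_hand_values(self, counts, expected):
        assert cohen_kappa(cm2(counts)) == expected

    def test_empty_matrix_undefined(self):
        with pytest.raises(UndefinedScoreError):
            cohen_kappa(cm2([[0, 0], [0, 0]]))

    def test_degenerate_single_cell(self):
        # all mass in one diagonal cell: chance agreement is certain but so
        # is observed agreement -> 1.0 by the degeneracy rule
        assert cohen_kappa(cm2([[7, 0], [0, 0]])) == 1.0

    @given(
        st.lists(st.integers(0, 50), min_size=4, max_size=4).filter(lambda c: sum(c) > 0)
    )
    def test_range_invariant(self, cells):
        counts = [[cells[0], cells[1]], [cells[2], cells[3]]]
        k = cohen_kappa(cm2(counts))
        assert -1.0 <= k <= 1.0

    def test_sklearn_cross_check(self):
        """1000 random matrices agree with scikit-learn to 1e-12."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            counts = rng.integers(0, 20, size=(k, k)) + np.eye(k, dtype=np.int64)
            cm = ConfusionMatrix(counts, tuple(str(i) for i in range(k)))
            y1 = np.repeat(np.arange(k), counts.sum(axis=1))
            y2 = np.concatenate([np.repeat(np.arange(k), row) for row in counts])
            assert cohen_kappa(cm) == pytest.approx(
                cohen_kappa_score(y1, y2), abs=1e-12
            )


class TestConfusionFromMatches:
    def test_no_unmatched_schemes_coincide(self):
        pairs = [(pos(i * 2, i * 2 + 1), pos(i * 2, i * 2 + 1), 1) for i in range(10)]
        pairs += [(neg(20 + i, 21 + i), neg(20 + i, 21 + i), 1) for i in range(10)]
        m = MatchResult(pairs=pairs)
        for scheme in Scheme:
            cm = confusion_from_matches(m, scheme)
            assert cm.counts.tolist() == [[10, 0], [0, 10]]

    def test_unmatched_negatives_per_scheme(self):
        pairs = [(pos(i * 2, i * 2 + 1), pos(i * 2, i * 2 + 1), 1) for i in range(8)]
        m = MatchResult(pairs=pairs, unmatched_gt=[neg(30, 31), neg(32, 33)])
        assert confusion_from_matches(m, Scheme.UNMATCHED_AS_TN).counts.tolist() == [[8, 0], [0, 2]]
        assert confusion_from_matches(m, Scheme.DISREGARD_UNMATCHED).counts.tolist() == [[8, 0], [0, 0]]
        assert confusion_from_matches(m, Scheme.UNMATCHED_AS_ERROR).counts.tolist() == [[8, 0], [2, 0]]

    def test_literal_error_cells_swap_margins(self):
        # the two conventions transpose each other's off-diagonal assignment
        m2 = MatchResult(unmatched_gt=[neg(0, 1)])
        assert confusion_from_matches(m2, Scheme.UNMATCHED_AS_ERROR).counts.tolist() == [[0, 0], [1, 0]]
        assert confusion_from_matches(
            m2, Scheme.UNMATCHED_AS_ERROR, literal_error_cells=True
        ).counts.tolist() == [[0, 1], [0, 0]]

    def test_unmatched_positives_scheme_independent(self):
        m = MatchResult(unmatched_gt=[pos(0, 1)], unmatched_alg=[pos(2, 3)])
        for scheme in Scheme:
            assert confusion_from_matches(m, scheme).counts.tolist() == [[0, 1], [1, 0]]

    def test_non_binary_labels_rejected(self):
        m = MatchResult(unmatched_gt=[Event(0, 1, "fixation")])
        with pytest.raises(ValueError, match="binarized"):
            confusion_from_matches(m, Scheme.UNMATCHED_AS_TN)

    @pytest.mark.parametrize("k", [0, 1, 5, 100])
    def test_scheme_algebra_under_added_negatives(self, k):
        """Adding k unmatched NEG events: disregard invariant, TN adds to
        (NEG,NEG), error adds k off-diagonal counts."""
        base = MatchResult(
            pairs=[(pos(0, 5), pos(0, 5), 5), (neg(5, 9), neg(5, 9), 4)],
            unmatched_gt=[pos(9, 10)],
        )
        extra = [neg(20 + 2 * i, 21 + 2 * i) for i in range(k)]
        grown = MatchResult(
            pairs=list(base.pairs),
            unmatched_gt=list(base.unmatched_gt) + extra[: k // 2],
            unmatched_alg=extra[k // 2 :],
        )
        dis0 = confusion_from_matches(base, Scheme.DISREGARD_UNMATCHED).counts
        disk = confusion_from_matches(grown, Scheme.DISREGARD_UNMATCHED).counts
        assert (dis0 == disk).all()

        tn0 = confusion_from_matches(base, Scheme.UNMATCHED_AS_TN).counts
        tnk = confusion_from_matches(grown, Scheme.UNMATCHED_AS_TN).counts
        assert tnk[1, 1] - tn0[1, 1] == k
        assert (np.delete(tnk.ravel(), 3) == np.delete(tn0.ravel(), 3)).all()

        er0 = confusion_from_matches(base, Scheme.UNMATCHED_AS_ERROR).counts
        erk = confusion_from_matches(grown, Scheme.UNMATCHED_AS_ERROR).counts
        off = (erk[0, 1] + erk[1, 0]) - (er0[0, 1] + er0[1, 0])
        assert off == k
        assert erk[0, 0] == er0[0, 0] and erk[1, 1] == er0[1, 1]


class TestPerEventAgreement:
    def test_self_agreement_is_one(self, three_class_stream):
        ev = labels_to_events(three_class_stream)
        for cls in three_class_stream.class_set:
            for scheme in Scheme:
                assert per_event_agreement(ev, ev, cls, scheme) == 1.0

    def test_hand_traced_scheme_ordering(self):
        # 6-event pair in which one negative event on each side goes
        # unmatched; matrices enumerated by hand.
        gt = labels_to_events(["F"] * 4 + ["S"] * 2 + ["F"] * 4 + ["S"] * 2 + ["F"] * 4)
        alg = labels_to_events(["F"] * 4 + ["S"] * 2 + ["F"] * 10)
        ks = {
            s: per_event_agreement(gt, alg, "F", s)
            for s in Scheme
        }
        assert ks[Scheme.UNMATCHED_AS_ERROR] <= ks[Scheme.DISREGARD_UNMATCHED]
        assert ks[Scheme.DISREGARD_UNMATCHED] <= ks[Scheme.UNMATCHED_AS_TN]


class TestOverallAgreement:
    def test_identity_three_classes(self, three_class_stream):
        ev = labels_to_events(three_class_stream)
        assert overall_agreement(ev, ev) == 1.0

    def test_fixed_matrix_cross_check(self):
        """Multi-class kappa on a fixed matched-pair matrix matches an
        independent implementation."""
        from sklearn.metrics import cohen_kappa_score

        counts = np.array([[5, 1, 0], [1, 5, 0], [0, 0, 4]])
        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        y1 = np.repeat(np.arange(3), counts.sum(axis=1))
        y2 = np.concatenate([np.repeat(np.arange(3), row) for row in counts])
        assert cohen_kappa(cm) == pytest.approx(cohen_kappa_score(y1, y2), abs=1e-12)

    def test_total_disagreement_negative(self):
        assert cohen_kappa(ConfusionMatrix(np.array([[0, 2], [2, 0]]), ("a", "b"))) < 0


class TestEventErrorRate:
    def test_identity_zero(self, three_class_stream):
        ev = labels_to_events(three_class_stream)
        assert event_error_rate(match_events(ev, ev)) == 0.0

    def test_substitution_rate(self):
        pairs = [(Event(i, i + 1, "a"), Event(i, i + 1, "a"), 1) for i in range(9)]
        pairs.append((Event(9, 10, "a"), Event(9, 10, "b"), 1))
        assert event_error_rate(MatchResult(pairs=pairs)) == pytest.approx(0.1)

    def test_insertion_rate(self):
        pairs = [(Event(i, i + 1, "a"), Event(i, i + 1, "a"), 1) for i in range(10)]
        ins = [Event(20, 21, "b"), Event(22, 23, "b")]
        assert event_error_rate(MatchResult(pairs=pairs, unmatched_alg=ins)) == pytest.approx(0.2)

    def test_no_gt_events_undefined(self):
        with pytest.raises(UndefinedScoreError):
            event_error_rate(MatchResult())


class TestUnmatchedNegativeFraction:
    def test_no_unmatched(self):
        m = MatchResult(pairs=[(neg(0, 2), neg(0, 2), 2)])
        assert unmatched_negative_fraction(m) == 0.0

    def test_ratio(self):
        pairs = [(neg(i * 2, i * 2 + 1), neg(i * 2, i * 2 + 1), 1) for i in range(9)]
        m = MatchResult(pairs=pairs, unmatched_gt=[neg(30, 31)], unmatched_alg=[neg(32, 33)])
        # 2 unmatched NEG out of 20 NEG events pooled over both streams
        assert unmatched_negative_fraction(m) == pytest.approx(0.10)

    def test_all_unmatched_boundary(self):
        m = MatchResult(unmatched_gt=[neg(0, 1)], unmatched_alg=[neg(2, 3)])
        assert unmatched_negative_fraction(m) == 1.0

    def test_no_negatives_undefined(self):
        m = MatchResult(pairs=[(pos(0, 1), pos(0, 1), 1)])
        with pytest.raises(UndefinedScoreError):
            unmatched_negative_fraction(m)


class TestEvaluate:
    def test_report_shape_and_identity(self, three_class_stream):
        rep = evaluate(three_class_stream, three_class_stream, schemes=tuple(Scheme))
        assert set(rep.per_event_kappa.values()) == {1.0}
        assert len(rep.per_event_kappa) == 3 * len(three_class_stream.class_set)
        assert rep.overall_kappa == 1.0 and rep.eer == 0.0
        assert set(rep.unmatched_negative_fraction.values()) == {0.0}
        d = rep.to_dict()
        assert d["per_event_kappa"]["fixation"]["disregard"] == 1.0

    def test_unequal_length_rejected(self, three_class_stream):
        short = LabeledStream(
            three_class_stream.labels[:-1], three_class_stream.class_set
        )
        with pytest.raises(ValueError, match="unequal length"):
            evaluate(three_class_stream, short)

    def test_unknown_positive_class_rejected(self, three_class_stream):
        with pytest.raises(ValueError, match="positive classes"):
            evaluate(three_class_stream, three_class_stream, positive_classes=["blink"])
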