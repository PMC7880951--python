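"""Readers and writers for label streams, event lists, and match results.

Label streams travel as plain text, one label per line, or as two-column
CSV (``sample_index,label`` or ``sample,label``) with a header.  Event
lists serialize to ``onset,offset,label`` CSV; match results to a CSV in
which unmatched events carry empty counterpart fields.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from eventkappa.matching import MatchResult
from eventkappa.streams import EventList, LabeledStream


class LabelFileError(ValueError):
    """A label file could not be parsed or failed validation."""


def read_label_file(
    path: str | Path,
    class_set: Sequence[str] | None = None,
    sampling_rate: float | None = None,
) -> LabeledStream:
    """Read a label stream from disk.

    A file whose first line contains a comma is treated as CSV with a
    header; the label is taken from a ``label`` column if the header names
    one, else from the second column.  Otherwise the file is read as one
    label per line.  Blank lines are ignored.  If ``class_set`` is given,
    an unknown label raises :class:`LabelFileError` naming the offending
    line; otherwise the class set is inferred (order of first appearance).
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    labels: list[str] = []
    lines: list[int] = []  # 1-based source line of each label, for errors

    if raw and "," in raw[0]:
        header = [h.strip().lower() for h in raw[0].split(",")]
        col = header.index("label") if "label" in header else 1
        for lineno, line in enumerate(raw[1:], start=2):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) <= col:
                raise LabelFileError(f"{path}:{lineno}: missing label column")
            labels.append(fields[col])
            lines.append(lineno)
    else:
        for lineno, line in enumerate(raw, start=1):
            token = line.strip()
            if token:
                labels.append(token)
                lines.append(lineno)

    if class_set is None:
        class_set = list(dict.fromkeys(labels))
    else:
        allowed = set(class_set)
        for lab, lineno in zip(labels, lines):
            if lab not in allowed:
                raise LabelFileError(
                    f"{path}:{lineno}: unknown label {lab!r} "
                    f"(class set: {', '.join(class_set)})"
                )
    return LabeledStream(
        labels=labels, class_set=tuple(class_set), sampling_rate=sampling_rate
    )


def write_label_file(stream: LabeledStream, path: str | Path) -> None:
    """Write a stream as plain text, one label per line."""
    Path(path).write_text("".join(f"{lab}\n" for lab in stream.labels))


def write_events_csv(ev: EventList, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset", "offset", "label"])
        for e in ev.events:
            w.writerow([e.onset, e.offset, e.label])


def write_match_csv(match: MatchResult, path: str | Path) -> None:
    """Serialize a match result; unmatched rows have empty partner fields."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "gt_onset",
                "gt_offset",
                "gt_label",
                "alg_onset",
                "alg_offset",
                "alg_label",
                "overlap",
            ]
        )
        for g, a, ov in match.pairs:
            w.writerow([g.onset, g.offset, g.label, a.onset, a.offset, a.label, ov])
        for g in match.unmatched_gt:
            w.writerow([g.onset, g.offset, g.label, "", "", "", ""])
        for a in match.unmatched_alg:
            w.writerow(["", "", "", a.onset, a.offset, a.label, ""])
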