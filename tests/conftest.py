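from hypothesis import HealthCheck, settings
import pytest

from eventkappa import EventList, Event, LabeledStream

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def three_class_stream() -> LabeledStream:
    """Small hand-built fixation/saccade/PSO stream."""
    labels = (
        ["fixation"] * 6 + ["saccade"] * 3 + ["pso"] * 2 + ["fixation"] * 5
        + ["saccade"] * 2 + ["fixation"] * 4
    )
    return LabeledStream(labels, ("fixation", "saccade", "pso"))


def make_events(spec: list[tuple[int, int, str]]) -> EventList:
    """Build an EventList from (onset, offset, label) triples."""
    events = [Event(a, b, lab) for a, b, lab in spec]
    return EventList(events, events[-1].offset if events else 0)


@pytest.fixture
def events_factory():
    return make_events
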