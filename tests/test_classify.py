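"""PIRA / RAW / undefined classification under the four interval definitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirabias import (
    AnalysisConfig,
    DetectedEvent,
    classify_events,
    classify_pira,
    classify_raw,
    classify_raw_subtype,
    detect_events,
)
from pirabias.classify import definition_intervals
from pirabias.model import INTERVAL_DEFINITIONS, ValidationError
from conftest import make_traj

EVENT = DetectedEvent("worsening", 84, 3.0, 0, 2.0, 168, 3.0)


@pytest.mark.parametrize(
    "relapses, expected",
    [([80], True), ([84], True), ([0], True), ([85], False), ([], False)],
)
def test_raw_window_is_closed_90_days(config, relapses, expected):
    # onset 84: RAW iff a relapse precedes or coincides within 90 days,
    # so day 0 (gap 84) counts and day 85 (relapse after onset) does not
    ev = DetectedEvent("worsening", 84, 3.0, 0, 2.0, 168, 3.0)
    assert classify_raw(ev, relapses, config) is expected


def test_raw_gap_above_90_not_raw(config):
    ev = DetectedEvent("worsening", 200, 3.0, 0, 2.0, 284, 3.0)
    assert classify_raw(ev, [80], config) is False  # gap 120
    assert classify_raw(ev, [110], config) is True  # gap 90, closed


def test_definition_interval_anchors(config):
    assert definition_intervals(EVENT, "standard1", config) == [(0, 168)]
    assert definition_intervals(EVENT, "standard2", config) == [(0, 114), (138, 198)]
    assert definition_intervals(EVENT, "standard3", config) == [(-6, 114), (78, 198)]
    assert definition_intervals(EVENT, "non_raw", config) == [(-6, 84)]
    with pytest.raises(ValidationError):
        definition_intervals(EVENT, "standard9", config)


def test_spec_handtrace_relapse_after_event(config):
    # relapse on day 100: inside Standard2's [0, 114] but after the event,
    # so not RAW -> undefined; Non-RAW interval [-6, 84] is clean -> PIRA
    assert classify_pira(EVENT, [100], "standard2", config) == "undefined"
    assert classify_pira(EVENT, [100], "non_raw", config) == "PIRA"


def test_no_relapses_pira_under_all_definitions(config):
    for d in INTERVAL_DEFINITIONS:
        assert classify_pira(EVENT, [], d, config) == "PIRA"


def test_relapse_just_before_event_raw_everywhere(config):
    for d in INTERVAL_DEFINITIONS:
        assert classify_pira(EVENT, [80], d, config) == "RAW"


def test_standard2_relapse_exactly_30_days_after_event_violates(config):
    # endpoint inclusion: a relapse exactly at event + 30 breaks Standard2
    assert classify_pira(EVENT, [114], "standard2", config) != "PIRA"
    assert classify_pira(EVENT, [115], "standard2", config) == "PIRA"


def test_raw_subtype_transient_vs_sustained(config):
    ev = DetectedEvent("worsening", 84, 3.5, 0, 2.0, 168, 3.5, "RAW")
    recovering = make_traj([(0, 2.0), (84, 3.5), (168, 3.5), (252, 2.0)], relapses=[50])
    persisting = make_traj([(0, 2.0), (84, 3.5), (168, 3.5), (252, 3.0)], relapses=[50])
    assert classify_raw_subtype(ev, recovering) == "transient"
    assert classify_raw_subtype(ev, persisting) == "sustained"
    # no later visits after the confirmed peak -> sustained by definition
    terminal = make_traj([(0, 2.0), (84, 3.5), (168, 3.5)], relapses=[50])
    ev2 = DetectedEvent("worsening", 168, 3.5, 0, 2.0, 168, 3.5, "RAW")
    assert classify_raw_subtype(ev2, terminal) == "sustained"


@st.composite
def classified_cases(draw):
    onset = draw(st.integers(84, 400))
    conf = onset + draw(st.integers(84, 200))
    ref_day = draw(st.integers(0, max(0, onset - 84)))
    ev = DetectedEvent("worsening", onset, 3.0, ref_day, 2.0, conf, 3.0)
    relapses = sorted(
        draw(st.lists(st.integers(0, conf + 60), min_size=0, max_size=4))
    )
    return ev, relapses


@settings(max_examples=300, deadline=None, derandomize=True)
@given(classified_cases())
def test_nonraw_is_exact_complement_of_raw(case):
    """Under non_raw, PIRA <=> not RAW; no event is ever undefined."""
    config = AnalysisConfig()
    ev, relapses = case
    cls = classify_pira(ev, relapses, "non_raw", config)
    assert cls != "undefined"
    assert (cls == "RAW") == classify_raw(ev, relapses, config)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(classified_cases(), st.integers(0, 500))
def test_adding_relapse_never_creates_pira(case, extra):
    config = AnalysisConfig()
    ev, relapses = case
    for d in INTERVAL_DEFINITIONS:
        before = classify_pira(ev, relapses, d, config)
        after = classify_pira(ev, sorted(relapses + [extra]), d, config)
        if before != "PIRA":
            assert after != "PIRA"


def test_classify_events_fills_worsenings_only(config):
    traj = make_traj(
        [(0, 4.0), (84, 3.0), (168, 3.0), (252, 4.0), (336, 4.0), (420, 4.0)],
        relapses=[250],
    )
    events = detect_events(traj, config)
    classified = classify_events(traj, events, "non_raw", config)
    kinds = {e.kind: e for e in classified}
    assert kinds["improvement"].classification == "n/a"
    assert kinds["worsening"].classification == "RAW"
    assert kinds["worsening"].raw_subtype in ("transient", "sustained")
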