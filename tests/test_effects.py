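"""Effect estimation: survival records, Cox HR vs an Efron partial-likelihood
oracle, risk ratios, and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pirabias import (
    DetectedEvent,
    EstimationError,
    aggregate_replicates,
    estimate_hr,
    estimate_rr,
    paired_bias,
    time_to_first_pira,
)
from pirabias.effects import SurvivalRecord, survival_table
from conftest import oracle_loghr


def _ev(onset, cls):
    return DetectedEvent("worsening", onset, 3.0, 0, 2.0, onset + 84, 3.0, cls)


def test_time_to_first_pira_takes_first_event():
    events = [_ev(84, "PIRA"), _ev(252, "PIRA")]
    rec = time_to_first_pira("p", "control", events, 672)
    assert (rec.time_days, rec.event) == (84, True)


def test_raw_only_patient_censored():
    rec = time_to_first_pira("p", "control", [_ev(84, "RAW")], 672)
    assert (rec.time_days, rec.event) == (672, False)
    rec2 = time_to_first_pira("p", "control", [], 672)
    assert (rec2.time_days, rec2.event) == (672, False)


def test_hr_two_group_exponential():
    """Exponential survival with a true rate ratio of 0.5 at n = 2000/arm
    recovers the hazard ratio within |log bias| < 0.05."""
    rng = np.random.default_rng(42)
    n = 2000
    t0 = rng.exponential(1.0, n)
    t1 = rng.exponential(2.0, n)  # half the hazard
    cens = 3.0
    df = pd.DataFrame(
        {
            "time": np.concatenate([np.minimum(t0, cens), np.minimum(t1, cens)]),
            "event": np.concatenate([t0 < cens, t1 < cens]),
            "arm": np.repeat([0, 1], n),
        }
    )
    est = estimate_hr(df)
    assert abs(np.log(est.point) - np.log(0.5)) < 0.05


def test_hr_mirrored_arms_is_one():
    times = [50, 100, 150, 200, 250, 300]
    recs = [SurvivalRecord(f"c{i}", "control", t, True) for i, t in enumerate(times)]
    recs += [SurvivalRecord(f"t{i}", "treated", t, True) for i, t in enumerate(times)]
    est = estimate_hr(recs)
    assert est.point == pytest.approx(1.0, abs=1e-6)


def test_hr_monotone_likelihood_flagged():
    recs = [
        SurvivalRecord("c1", "control", 10, True),
        SurvivalRecord("c2", "control", 20, True),
        SurvivalRecord("t1", "treated", 30, False),
        SurvivalRecord("t2", "treated", 40, False),
    ]
    with pytest.raises(EstimationError):
        estimate_hr(recs)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_hr_matches_efron_oracle(data):
    """lifelines' Cox fit agrees with a direct Efron partial-likelihood
    maximisation within 1e-4 on the log hazard ratio (<=20 records)."""
    n = data.draw(st.integers(6, 20))
    times = data.draw(
        st.lists(st.integers(1, 8), min_size=n, max_size=n)
    )
    events = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    arms = [i % 2 for i in range(n)]
    if sum(e and a for e, a in zip(events, arms)) == 0:
        return
    if sum(e and not a for e, a in zip(events, arms)) == 0:
        return
    df = pd.DataFrame({"time": times, "event": events, "arm": arms})
    try:
        est = estimate_hr(df)
    except EstimationError:
        return
    expected = oracle_loghr(times, events, arms)
    if abs(expected) > 5:  # effectively monotone; oracle at boundary
        return
    assert np.log(est.point) == pytest.approx(expected, abs=1e-4)


def test_hr_label_swap_inverts():
    rng = np.random.default_rng(1)
    recs = []
    for i in range(200):
        t = rng.integers(10, 500)
        recs.append(SurvivalRecord(f"c{i}", "control", int(t), bool(rng.random() < 0.6)))
        t = rng.integers(10, 500)
        recs.append(SurvivalRecord(f"t{i}", "treated", int(t), bool(rng.random() < 0.4)))
    fwd = estimate_hr(recs).point
    swapped = [
        SurvivalRecord(r.patient_id, "treated" if r.arm == "control" else "control", r.time_days, r.event)
        for r in recs
    ]
    rev = estimate_hr(swapped).point
    assert fwd * rev == pytest.approx(1.0, rel=1e-4)


def test_rr_examples():
    assert estimate_rr(40, 100, 50, 100).point == pytest.approx(0.80)
    assert estimate_rr(50, 100, 50, 100).point == pytest.approx(1.00)
    assert estimate_rr(0, 100, 50, 100).point == 0.0
    with pytest.raises(EstimationError):
        estimate_rr(10, 100, 0, 100)


def test_aggregate_constant_replicates():
    est = aggregate_replicates([0.75] * 10, n_boot=200, seed=0)
    assert est.point == pytest.approx(0.75)
    assert est.ci_low == pytest.approx(0.75)
    assert est.ci_high == pytest.approx(0.75)


def test_aggregate_geometric_mean():
    est = aggregate_replicates([0.5, 2.0], n_boot=100, seed=0)
    assert est.point == pytest.approx(1.0)
    arith = aggregate_replicates([0.5, 2.0], n_boot=100, seed=0, scale="natural")
    assert arith.point == pytest.approx(1.25)


def test_aggregate_lln_lognormal():
    rng = np.random.default_rng(3)
    vals = np.exp(rng.normal(np.log(0.75), 0.1, size=200))
    est = aggregate_replicates(vals, n_boot=500, seed=1)
    mc_se = 0.1 / np.sqrt(200)
    assert abs(np.log(est.point) - np.log(0.75)) < 2 * mc_se * 1.5
    assert est.ci_low <= est.point <= est.ci_high


def test_aggregate_excludes_nonfinite():
    est = aggregate_replicates([0.75, np.nan, 0.75, np.inf], n_boot=100, seed=0)
    assert est.n_replicates == 2
    assert est.point == pytest.approx(0.75)


def test_paired_bias_antisymmetric():
    rng = np.random.default_rng(2)
    a = np.exp(rng.normal(0.0, 0.1, 50))
    b = np.exp(rng.normal(-0.2, 0.1, 50))
    fwd, *_ = paired_bias(a, b, n_boot=100, seed=0)
    rev, *_ = paired_bias(b, a, n_boot=100, seed=0)
    assert fwd == pytest.approx(-rev)
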