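"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from pirabias import AnalysisConfig, PatientTrajectory, threshold


def make_traj(visits, relapses=(), arm="control", pid="p"):
    return PatientTrajectory.from_visits(pid, visits, relapses, arm=arm)


# ---------------------------------------------------------------------------
# Brute-force confirmation oracle: enumerates (onset, confirmation) visit
# pairs and checks the sustained-change predicate by explicit enumeration.
# Kept deliberately naive and independent of pirabias.events internals.
# ---------------------------------------------------------------------------

def oracle_detect(traj, config: AnalysisConfig | None = None):
    if config is None:
        config = AnalysisConfig()
    days = [int(d) for d in traj.days]
    scores = [float(s) for s in traj.scores]
    rel = [int(r) for r in traj.relapse_days]
    n = len(days)

    def eligible(j):
        return not any(0 <= days[j] - r <= config.confirmation_relapse_exclusion_days for r in rel)

    out = []
    ref_d, ref_v = days[0], scores[0]
    lo = 1
    while lo < n:
        found = None
        for i in range(lo, n):
            thr = threshold(ref_v)
            for kind, sign in (("worsening", 1.0), ("improvement", -1.0)):
                if sign * (scores[i] - ref_v) < thr:
                    continue
                for j in range(i + 1, n):
                    if days[j] - days[i] < config.confirmation_days or not eligible(j):
                        continue
                    if all(sign * (scores[k] - ref_v) >= thr for k in range(i + 1, j + 1)):
                        found = (i, j, kind)
                        break
                if found:
                    break
            if found:
                break
        if not found:
            break
        i, j, kind = found
        out.append(
            dict(kind=kind, onset_day=days[i], reference_day=ref_d,
                 reference_value=ref_v, confirmation_day=days[j])
        )
        ref_d, ref_v = days[j], scores[j]
        lo = j + 1
    return out


# ---------------------------------------------------------------------------
# Efron partial-likelihood oracle for a single binary covariate.
# ---------------------------------------------------------------------------

def efron_loglik(beta: float, time, event, arm) -> float:
    time = np.asarray(time)
    event = np.asarray(event, dtype=bool)
    arm = np.asarray(arm, dtype=float)
    ll = 0.0
    for t in np.unique(time[event]):
        d_idx = event & (time == t)
        r_idx = time >= t
        m = int(d_idx.sum())
        ll += beta * arm[d_idx].sum()
        sum_r = np.exp(beta * arm[r_idx]).sum()
        sum_d = np.exp(beta * arm[d_idx]).sum()
        for ell in range(m):
            ll -= np.log(sum_r - ell / m * sum_d)
    return ll


def oracle_loghr(time, event, arm) -> float:
    res = minimize_scalar(
        lambda b: -efron_loglik(b, time, event, arm),
        bounds=(-8.0, 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


@pytest.fixture
def config():
    return AnalysisConfig()
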