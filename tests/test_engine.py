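"""Simulation engine: piecewise integration, continuous progression
detection, and the worst-case offset evaluation."""

import math

import numpy as np
import pytest

from atopt import (
    LVParams,
    NOT_PROGRESSED,
    ProgressionRule,
    ProtocolSpec,
    Trajectory,
    TumorState,
    lv_optimal_threshold,
    lv_tau_star,
    min_ttp_over_offsets,
    simulate_treatment,
    time_to_progression,
)

LV = LVParams(r_S=0.027, r_R=0.0135, K=0.75, d=0.0, d_D=1.5)


def test_strong_kill_never_progresses():
    """With (1 - d_D) < 0 the treated sensitive population only decays, and
    without resistant cells the tumor cannot progress."""
    rule = ProgressionRule.total_size(0.5)
    spec = ProtocolSpec(kind="CT", tau=30.0)
    res = simulate_treatment("lv", LV, spec, rule, TumorState(0.5, 0.0), horizon=1000.0)
    assert not res.progressed
    assert res.ttp == NOT_PROGRESSED
    assert np.all(np.diff(res.trajectory.pop1) <= 1e-12)


def test_at50_beats_continuous_therapy():
    rule = ProgressionRule.total_size(0.5625)
    init = TumorState(0.556875, 0.005625)
    ct = simulate_treatment("lv", LV, ProtocolSpec(kind="CT", tau=30.0), rule, init)
    at = simulate_treatment("lv", LV, ProtocolSpec(kind="AT50", tau=30.0), rule, init)
    assert ct.progressed and at.progressed
    assert at.ttp > ct.ttp


@pytest.mark.parametrize("n_star", [0.45, 0.55, 0.65])
def test_drug_free_regrowth_hits_limit_at_tau_star(n_star):
    """The simulated drug-free crossing time from N* equals the closed-form
    tau* within integration tolerance (well under 0.1 day)."""
    N0 = 0.5625
    rule = ProgressionRule.total_size(N0)
    never_treat = ProtocolSpec(kind="ATN_fixed", tau=30.0, N_star=10.0)
    res = simulate_treatment("lv", LV, never_treat, rule, TumorState(n_star, 0.0), horizon=3000.0)
    expected = lv_tau_star(n_star, LV.r_S, LV.d, LV.K, N0)
    assert res.premature  # off-drug crossing by construction
    assert res.ttp == pytest.approx(expected, abs=1e-3)


def test_dose_constant_between_appointments():
    rule = ProgressionRule.total_size(0.5625)
    spec = ProtocolSpec(kind="AT50", tau=30.0)
    res = simulate_treatment("lv", LV, spec, rule, TumorState(0.556875, 0.005625))
    tr = res.trajectory
    switches = np.nonzero(np.diff(tr.dose) != 0)[0]
    for i in switches:
        # every dose change coincides with an appointment time
        assert np.isclose(tr.times[i + 1] % spec.tau, 0.0, atol=1e-9) or np.isclose(
            tr.times[i + 1] % spec.tau, spec.tau, atol=1e-9
        )


def test_near_continuous_monitoring_caps_overshoot():
    """As tau -> 0 the threshold protocol pins the tumor at N* (early in
    the course, before resistant escape)."""
    N0 = 0.5625
    rule = ProgressionRule.total_size(N0)
    spec = ProtocolSpec(kind="ATN_fixed", tau=0.5, N_star=0.6)
    res = simulate_treatment("lv", LV, spec, rule, TumorState(0.556875, 0.005625), horizon=300.0)
    tr = res.trajectory
    assert tr.total[tr.times <= 300.0].max() <= 0.6 + 0.005


def test_initial_offset_forces_treatment_first():
    spec = ProtocolSpec(kind="ATN_fixed", tau=30.0, N_star=0.2, offset=15.0)
    rule = ProgressionRule.total_size(0.5625)
    res = simulate_treatment("lv", LV, spec, rule, TumorState(0.5, 0.05), horizon=100.0)
    tr = res.trajectory
    assert np.all(tr.dose[tr.times < 15.0] == 1)
    assert tr.appointments[0] == 15.0


def test_progression_at_start_is_degenerate_zero():
    rule = ProgressionRule.total_size(0.3)  # limit 0.36 < N(0)
    spec = ProtocolSpec(kind="CT", tau=30.0)
    res = simulate_treatment("lv", LV, spec, rule, TumorState(0.4, 0.0))
    assert res.progressed and res.ttp == 0.0


def test_tolerance_refinement_stable():
    """Refining rtol/atol tenfold moves the reported TTP by < 0.1 day."""
    rule = ProgressionRule.total_size(0.5625)
    init = TumorState(0.556875, 0.005625)
    spec = ProtocolSpec(kind="ATN_fixed", tau=30.0, N_star=0.5625)
    a = simulate_treatment("lv", LV, spec, rule, init, rtol=1e-8, atol=1e-10)
    b = simulate_treatment("lv", LV, spec, rule, init, rtol=1e-9, atol=1e-11)
    assert abs(a.ttp - b.ttp) < 0.1


def test_populations_stay_nonnegative():
    rule = ProgressionRule.total_size(0.5625)
    res = simulate_treatment(
        "lv", LV, ProtocolSpec(kind="CT", tau=30.0), rule, TumorState(0.556875, 0.005625)
    )
    assert res.trajectory.pop1.min() >= 0.0
    assert res.trajectory.pop2.min() >= 0.0


# --- time_to_progression on fabricated trajectories -----------------------


def _linear_traj(n0, slope, t_end=100.0, n=201):
    t = np.linspace(0.0, t_end, n)
    total = n0 + slope * t
    return Trajectory(t, total, np.zeros_like(t), np.ones(n, dtype=int), np.array([]))


def test_ttp_of_linear_crossing_is_analytic():
    rule = ProgressionRule.total_size(0.5)  # limit 0.6
    traj = _linear_traj(0.5, 0.002)  # crosses 0.6 at t = 50
    assert time_to_progression(traj, rule) == pytest.approx(50.0, abs=1e-9)


def test_ttp_sentinel_and_zero():
    rule = ProgressionRule.total_size(0.5)
    assert time_to_progression(_linear_traj(0.5, -0.001), rule) == NOT_PROGRESSED
    assert time_to_progression(_linear_traj(0.6, 0.001), rule) == 0.0


def test_ttp_resistant_rule_takes_first_crossing():
    t = np.linspace(0.0, 100.0, 101)
    pop1 = np.full_like(t, 0.4)
    pop2 = 0.05 + 0.001 * t  # hits 0.1 at t = 50
    traj = Trajectory(t, pop1, pop2, np.ones_like(t, dtype=int), np.array([]))
    rule = ProgressionRule.resistant_fraction(0.5, K_R=1.0)  # R-limit 0.1, cap 0.6
    assert time_to_progression(traj, rule) == pytest.approx(50.0, abs=1e-9)


# --- worst-case offsets ----------------------------------------------------


def test_ct_is_offset_invariant():
    rule = ProgressionRule.total_size(0.5625)
    init = TumorState(0.556875, 0.005625)
    wc = min_ttp_over_offsets("lv", LV, ProtocolSpec(kind="CT", tau=30.0), rule, init, n_offsets=5)
    ttps = [r.ttp for r in wc.results]
    # identical up to event-location jitter across segment layouts
    assert np.ptp(ttps) < 1e-3


def test_single_offset_equals_plain_simulation():
    rule = ProgressionRule.total_size(0.5625)
    init = TumorState(0.556875, 0.005625)
    spec = ProtocolSpec(kind="ATN_fixed", tau=30.0, N_star=0.5625)
    wc = min_ttp_over_offsets("lv", LV, spec, rule, init, n_offsets=1)
    plain = simulate_treatment("lv", LV, spec, rule, init)
    assert wc.worst_ttp == plain.ttp
    assert wc.worst_offset == 0.0


def test_threshold_sharpness_around_optimal():
    """Slightly above the analytic threshold the worst-case offset run
    progresses prematurely; slightly below it never does."""
    N0 = 0.5625
    rule = ProgressionRule.total_size(N0)
    init = TumorState(0.556875, 0.005625)
    tau = 30.0
    ns = lv_optimal_threshold(tau, LV.r_S, LV.d, LV.K, N0)
    hi = min_ttp_over_offsets(
        "lv", LV, ProtocolSpec(kind="ATN_fixed", tau=tau, N_star=1.02 * ns), rule, init
    )
    lo = min_ttp_over_offsets(
        "lv", LV, ProtocolSpec(kind="ATN_fixed", tau=tau, N_star=0.98 * ns), rule, init
    )
    assert hi.premature
    assert not lo.premature
    assert not any(r.premature for r in lo.results)
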