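import numpy as np
import pytest

from latedose import (
    RuleConfig,
    ScenarioSpec,
    TrialConfig,
    builtin_scenario,
    correct_outcome,
    default_design,
    load_default_weights,
    observable_dataset,
    patient_streams,
    run_trial,
    simulate_ocs,
)
from latedose.designs import SUSPEND, Design
from latedose.isotonic import isotonic_mtd
from latedose.boin import BetaPrior

DOSES = (1.5, 2.5, 3.5, 4.5, 6.0, 7.0)


class StayDesign(Design):
    """Stub that always proposes the current dose."""

    name = "stay"

    def propose(self, ctx):
        return ctx.current_dose

    def final_select(self, data, admissible, tau):
        return isotonic_mtd(data.treated_per_dose(), data.dlt_per_dose(),
                            BetaPrior(1, 1), tau, admissible)


class RoundRobinDesign(Design):
    """Stub cycling through doses so no dose accumulates 9 patients."""

    name = "round-robin"

    def propose(self, ctx):
        return (ctx.current_dose + 1) % 4  # cycles doses 1-4 (k-fold safe)

    def final_select(self, data, admissible, tau):
        return 0


def _safe_scenario(p1=0.0):
    eps = 1e-9 if p1 == 0.0 else 0.0
    return ScenarioSpec(dose_values=DOSES, p1=tuple([max(p1, eps)] * 6), truth=1)


def test_observable_follow_up_pattern():
    sc = _safe_scenario()
    w = load_default_weights()
    lat, aux = patient_streams(1, 0, 9, 3)
    doses = [0, 0, 0, 1, 1, 1, 2, 2, 2]
    enroll = [0, 0, 0, 1, 1, 1, 2, 2, 2]
    # at week 6 (boundary 1) only cohort 1 is observed, with one cycle
    ds = observable_dataset(sc, doses, enroll, 1, lat, aux, w)
    assert ds.n_patients == 3
    assert all(r.cycles_observed == 1 for r in ds.records)
    # at week 18 (boundary 3): cohort 1 complete, cohort 2 two cycles,
    # cohort 3 one cycle
    ds = observable_dataset(sc, doses, enroll, 3, lat, aux, w)
    u_by_cohort = [ds.records[i].cycles_observed for i in (0, 3, 6)]
    assert u_by_cohort == [3, 2, 1]
    # no future leakage: observation never exceeds elapsed cycles
    for b in range(1, 7):
        ds = observable_dataset(sc, doses, enroll, b, lat, aux, w)
        for r in ds.records:
            assert r.cycles_observed <= b - enroll[r.patient]


def test_dlt_patient_contributes_fixed_cycles():
    # a patient with a cycle-1 DLT contributes exactly one cycle forever
    sc = ScenarioSpec(dose_values=DOSES, p1=(0.999,) * 6, truth="all_unsafe")
    w = load_default_weights()
    lat, aux = patient_streams(1, 0, 3, 3)
    ds = observable_dataset(sc, [0, 0, 0], [0, 0, 0], 5, lat, aux, w)
    assert all(r.dlt_cycle == 1 and r.cycles_observed == 1 for r in ds.records)


def test_stay_design_sufficient_information_trace():
    # p1 = 0, always-stay at dose 1, setting 1: cohorts enter at weeks
    # 0/6/12; at week 18 the proposed dose already carries 9 patients,
    # so the trial stops with 9 enrolled; the last cohort (week 12)
    # completes follow-up at week 30
    res = run_trial(StayDesign(), _safe_scenario(), TrialConfig(), 1, 0)
    assert res.n_patients == 9
    assert res.stop_reasons == ("sufficient_information",)
    assert res.duration_weeks == 30.0
    assert res.allocation.tolist() == [9, 0, 0, 0, 0, 0]
    assert res.recommendation == 0


def test_all_dlt_first_cohort_hard_safety_stop():
    # setting 2: a first cohort of cycle-1 DLTs at dose 1 excludes every
    # dose and stops the trial with 3 patients and no recommendation
    sc = ScenarioSpec(dose_values=DOSES, p1=(0.999,) * 6, truth="all_unsafe")
    cfg = TrialConfig(rules=RuleConfig(setting=2))
    res = run_trial(StayDesign(), sc, cfg, 1, 0)
    assert res.n_patients == 3
    assert res.recommendation is None
    assert "hard_safety" in res.stop_reasons
    assert correct_outcome(res, sc)


def test_max_patients_path():
    # a stub that never parks 9 patients on one dose runs to 30
    res = run_trial(RoundRobinDesign(), _safe_scenario(), TrialConfig(), 1, 0)
    assert res.n_patients == 30
    assert "maximum_patients" in res.stop_reasons
    assert res.allocation.sum() == 30


def test_trial_result_invariants_across_designs(scenario_d, config_s1):
    for name in ("tite-boin", "tite-mtpi2", "r-mtpi2", "tite-crm"):
        design = default_design(name, 1)
        for rep in range(8):
            res = run_trial(design, scenario_d, config_s1, 3, rep)
            assert res.n_patients <= 30
            assert res.allocation.sum() == res.n_patients
            assert res.n_patients % 3 == 0
            assert res.duration_weeks >= res.n_interims * 0  # non-negative
            # duration is the completion week of the last patient
            assert res.duration_weeks % 6 == 0


def test_determinism_and_shared_latents(scenario_d, config_s1):
    a = run_trial(default_design("tite-boin", 1), scenario_d, config_s1, 5, 2)
    b = run_trial(default_design("tite-boin", 1), scenario_d, config_s1, 5, 2)
    assert a.n_patients == b.n_patients
    assert np.array_equal(a.patient_latents, b.patient_latents)
    assert a.stop_reasons == b.stop_reasons
    # a different design sees the same latent patient sequence
    c = run_trial(default_design("tite-crm", 1), scenario_d, config_s1, 5, 2)
    n = min(c.n_patients, a.n_patients)
    assert np.array_equal(a.patient_latents[:n], c.patient_latents[:n])


def test_excluded_doses_never_assigned():
    # setting 2 on a scenario with a very toxic top half of the grid
    sc = ScenarioSpec(dose_values=DOSES, p1=(0.05, 0.05, 0.9, 0.9, 0.9, 0.9),
                      truth=2)
    cfg = TrialConfig(rules=RuleConfig(setting=2))
    design = default_design("tite-boin", 2)
    for rep in range(10):
        res = run_trial(design, sc, cfg, 11, rep)
        # once dose 3 shows 3/3 cycle-1 DLTs it is excluded; the trial
        # may still have treated it before exclusion, but dose 4+ never
        assert res.allocation[3:].sum() == 0


def test_correct_outcome_conventions(scenario_d):
    from latedose.engine import TrialResult

    def mk(rec, reasons):
        return TrialResult(rec, 3, 6.0, np.array([3, 0, 0, 0, 0, 0]),
                           tuple(reasons), np.zeros(3, int), np.zeros(3), 1)

    assert correct_outcome(mk(2, ["sufficient_information"]), scenario_d)
    assert not correct_outcome(mk(3, ["sufficient_information"]), scenario_d)
    unsafe = builtin_scenario("P.S.5")
    assert correct_outcome(mk(None, ["lowest_unsafe"]), unsafe)
    assert correct_outcome(mk(None, ["hard_safety"]), unsafe)
    assert not correct_outcome(mk(0, ["sufficient_information"]), unsafe)
    safe = builtin_scenario("P.S.6")
    assert correct_outcome(mk(None, ["highest_safe"]), safe)
    assert not correct_outcome(mk(None, ["lowest_unsafe"]), safe)


def test_simulate_ocs_aggregation(scenario_d, config_s1):
    oc = simulate_ocs(default_design("tite-boin", 1), scenario_d, 20, 2, config_s1)
    assert oc.n_sims == 20
    assert oc.recommendation_pct.sum() == pytest.approx(100.0)
    assert 0 <= oc.pcs <= 100
    # byte-identical reproducibility for a fixed seed
    oc2 = simulate_ocs(default_design("tite-boin", 1), scenario_d, 20, 2, config_s1)
    assert oc.to_frame().equals(oc2.to_frame())


def test_single_replicate_oc_equals_trial(scenario_d, config_s1):
    design = default_design("tite-boin", 1)
    oc = simulate_ocs(design, scenario_d, 1, 9, config_s1)
    res = run_trial(design, scenario_d, config_s1, 9, 0)
    assert oc.mean_patients == res.n_patients
    assert oc.mean_duration == res.duration_weeks
    assert oc.mean_allocation.tolist() == res.allocation.tolist()
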