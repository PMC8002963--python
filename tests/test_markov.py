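"""Transition-matrix construction and the cohort engine."""

import copy

import numpy as np
import pytest

from ipmncea import (
    InitialAllocation,
    LifeTable,
    build_transition_matrix,
    run_cohort,
    run_strategy,
)
from ipmncea.structure import internal_states
from ipmncea.synthetic import generate_parameters


def _toy_table(q):
    ages = np.arange(60, 101)
    return LifeTable(ages=ages, qx=np.full(ages.size, q))


def _alloc_all_in(state, p, upfront=0.0):
    states = internal_states(p.structure)
    occ = np.zeros(len(states))
    occ[states.index(state)] = 1.0
    return InitialAllocation(states=tuple(states), occupancy=occ, upfront_cost=upfront)


def test_rows_sum_to_one_across_ages(base_params, life_table):
    for age in (60, 64.3, 70.5, 85, 95):
        for strategy in ("pet", "ctmri"):
            tm = build_transition_matrix(age, base_params, strategy, life_table)
            np.testing.assert_allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(tm.probs >= 0)


def test_death_row_is_absorbing(base_params, life_table):
    tm = build_transition_matrix(64.3, base_params, "pet", life_table)
    d = tm.states.index("D")
    expected = np.zeros(len(tm.states))
    expected[d] = 1.0
    np.testing.assert_array_equal(tm.probs[d], expected)


def test_recurrence_death_competing_risk(base_params):
    # stay-alive = (1 - q_age)(1 - 0.283); with q_age = 0.02 -> P(death) = 0.29734
    tm = build_transition_matrix(64, base_params, "ctmri", _toy_table(0.02))
    i, d = tm.states.index("REC"), tm.states.index("D")
    assert tm.probs[i, d] == pytest.approx(1 - 0.98 * (1 - 0.283), abs=1e-12)
    assert tm.probs[i, d] == pytest.approx(0.29734)


def test_pet_recurrence_risk_reduction(base_params):
    # 16.7%/yr scaled by (1 - 10%) in the PET strategy, no background mortality
    tm = build_transition_matrix(64, base_params, "pet", _toy_table(0.0))
    src, rec = tm.states.index("PRM"), tm.states.index("REC")
    assert tm.probs[src, rec] == pytest.approx(0.167 * 0.9, abs=1e-12)
    tm_ct = build_transition_matrix(64, base_params, "ctmri", _toy_table(0.0))
    assert tm_ct.probs[src, rec] == pytest.approx(0.167, abs=1e-12)


def test_no_event_limit_is_identity(base_params):
    p = base_params.copy()
    t = p.transitions
    t.malignant_transformation = t.death_malignant_ipmn = 0.0
    t.death_recurrence = t.perioperative_mortality = t.recurrence_probability = 0.0
    p.ctmri.sensitivity = 0.0  # no detection flow either
    tm = build_transition_matrix(64, p, "ctmri", _toy_table(0.0))
    # every state maps to its natural successor with probability 1; resection
    # -year states roll over into their long-term states
    stay = np.diag(tm.probs)
    for s in ("SB", "UM", "PRB", "PRM", "REC", "D"):
        assert stay[tm.states.index(s)] == pytest.approx(1.0)
    assert tm.probs[tm.states.index("PRB1"), tm.states.index("PRB")] == 1.0


def test_delayed_surgery_charged_to_perioperative_deaths(base_params):
    tm = build_transition_matrix(64, base_params, "ctmri", _toy_table(0.0))
    um, prm1, d = (tm.states.index(s) for s in ("UM", "PRM1", "D"))
    assert tm.event_costs[um, prm1] == pytest.approx(base_params.costs.surgery_event_cost)
    # expected event cost on UM->Death equals the perioperative share
    se, pm = base_params.ctmri.sensitivity, base_params.transitions.perioperative_mortality
    alive = 1 - base_params.transitions.death_malignant_ipmn
    p_death = tm.probs[um, d]
    expected = alive * se * pm * base_params.costs.surgery_event_cost / p_death
    assert tm.event_costs[um, d] == pytest.approx(expected)


def test_fifteen_qaly_limit_no_mortality_no_discount(base_params, zero_mortality_table):
    p = base_params.copy()
    t = p.transitions
    t.malignant_transformation = t.death_malignant_ipmn = 0.0
    t.death_recurrence = t.perioperative_mortality = t.recurrence_probability = 0.0
    u = p.utilities
    u.healthy_ipmn = u.resection_year = u.post_resection_longterm = u.recurrence = 1.0
    p.economics.discount_rate = 0.0
    alloc = _alloc_all_in("SB", p)
    trace = run_cohort(alloc, p, "ctmri", zero_mortality_table)
    assert trace.total_qaly == pytest.approx(15.0, abs=1e-12)


def test_two_state_toy_geometric_series(base_params, zero_mortality_table):
    # Alive -> Death at 10%/yr, utility 1, no discounting, start-of-cycle
    # rewards: sum_{t=0}^{14} 0.9^t = (1 - 0.9^15)/0.1
    p = base_params.copy()
    p.transitions.death_recurrence = 0.10
    p.utilities.recurrence = 1.0
    p.economics.discount_rate = 0.0
    alloc = _alloc_all_in("REC", p)
    trace = run_cohort(alloc, p, "ctmri", zero_mortality_table)
    assert trace.total_qaly == pytest.approx((1 - 0.9**15) / 0.1, abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_mass_conserved_and_death_monotone(seed, life_table):
    p = generate_parameters(seed, scale=0.2)
    for strategy in ("pet", "ctmri"):
        _, trace = run_strategy(p, life_table, strategy)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        dead = trace.occupancy[:, trace.states.index("D")]
        assert np.all(np.diff(dead) >= -1e-15)


def test_discounting_reduces_totals(base_params, life_table):
    p0 = base_params.copy()
    p0.economics.discount_rate = 0.0
    _, undisc = run_strategy(p0, life_table, "pet")
    _, disc = run_strategy(base_params, life_table, "pet")
    assert disc.total_cost < undisc.total_cost
    assert disc.total_qaly < undisc.total_qaly
    # discounted QALYs bounded by the discounted-annuity ceiling
    r = base_params.economics.discount_rate
    ceiling = sum((1 + r) ** -t for t in range(15))
    assert disc.total_qaly <= ceiling


def test_equal_accuracy_zero_pet_extras_makes_strategies_identical(base_params, life_table):
    p = base_params.copy()
    p.pet = copy.deepcopy(p.ctmri)
    p.costs.pet_exam = 0.0
    p.transitions.pet_recurrence_risk_reduction = 0.0
    _, tr_pet = run_strategy(p, life_table, "pet")
    _, tr_ct = run_strategy(p, life_table, "ctmri")
    np.testing.assert_allclose(tr_pet.occupancy, tr_ct.occupancy, atol=1e-15)
    np.testing.assert_allclose(tr_pet.discounted_cost, tr_ct.discounted_cost, atol=1e-9)
    np.testing.assert_allclose(tr_pet.discounted_qaly, tr_ct.discounted_qaly, atol=1e-12)


def test_trace_export_shape(base_params, life_table):
    _, trace = run_strategy(base_params, life_table, "pet")
    df = trace.to_dataframe()
    assert len(df) == 15
    assert {"cycle", "age", "Death", "discounted_cost", "cumulative_discounted_qaly"} <= set(
        df.columns
    )
    occ_cols = ["SurveillanceBenign", "UndetectedMalignant", "PostResectionBenign",
                "PostResectionMalignant", "Recurrence", "Death"]
    np.testing.assert_allclose(df[occ_cols].sum(axis=1), 1.0, atol=1e-12)
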