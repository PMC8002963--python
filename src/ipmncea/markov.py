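"""Annual-cycle Markov cohort engine.

The engine propagates state-occupancy fractions through age-dependent
transition matrices over a 15-year horizon (annual cycles), accumulating
costs and QALYs discounted at the annual rate.  Cycle ``t`` rewards use state
membership at the start of cycle ``t`` (no half-cycle correction by default),
and the discount factor ``(1 + r)^-t`` applies to both costs and utilities,
so cycle-0 events are undiscounted.

Cause-specific annual risks (malignant transformation, death from untreated
malignancy, recurrence, death from recurrence) are combined with background
mortality ``q(age)`` as independent competing risks within a cycle: the
probability of staying alive is the product of the cause-specific survival
probabilities, and residual probability remains in the current state.

Event costs (delayed surgery when an undetected malignancy is found during
surveillance; the recurrence cost on entry to Recurrence) are attached to
transitions as *expected cost conditional on making the transition*, so the
cohort engine and the individual-level microsimulation oracle charge exactly
the same expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import InitialAllocation, STRATEGIES
from .lifetables import LifeTable, lookup_mortality
from .parameters import ModelParameters
from .structure import (
    PUBLIC_STATE_OF,
    PUBLIC_STATES,
    StructureVariant,
    internal_states,
    recurrence_risk_states,
)

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "build_transition_matrix",
    "reward_vectors",
    "run_cohort",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """One cycle's transition probabilities and attached event costs.

    ``probs[i, j]`` is the probability of moving from state ``i`` to ``j``
    within the cycle; ``event_costs[i, j]`` is the expected event cost (US-$)
    conditional on that transition.
    """

    states: tuple[str, ...]
    probs: np.ndarray
    event_costs: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, dtype=float)
        rows = P.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise AssertionError(
                f"transition row {self.states[bad]!r} sums to {rows[bad]!r}"
            )
        if np.any((P < -_ROW_TOL) | (P > 1 + _ROW_TOL)):
            raise AssertionError("transition probabilities outside [0, 1]")


def build_transition_matrix(
    age: float,
    p: ModelParameters,
    strategy: str,
    life_table: LifeTable,
    variant: StructureVariant | None = None,
) -> TransitionMatrix:
    """Per-cycle transition matrix at a given age for one strategy.

    Annual flows: surveillance-benign patients transform to undetected
    malignancy; undetected malignancy carries an annual disease-specific
    death risk and is found during surveillance (with the strategy's own
    sensitivity under the default variant), triggering delayed surgery with
    its cost and one-time perioperative mortality; resected malignancy recurs
    at the annual recurrence probability (reduced by the early-detection
    factor in the PET strategy); recurrence carries its own annual death
    risk.  Every alive flow competes independently with background mortality
    at the current age.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    variant = variant or p.structure
    states = internal_states(variant)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    P = np.zeros((n, n))
    C = np.zeros((n, n))

    q = lookup_mortality(life_table, age)
    # In disease states whose exit rates come from clinical cohorts, the
    # life-table risk is optionally not stacked on top (those cohort rates
    # already include all-cause death).
    q_dis = q if variant.background_mortality == "all_states" else 0.0
    t = p.transitions
    se = p.pet.sensitivity if strategy == "pet" else p.ctmri.sensitivity
    detect = 1.0 if variant.fn_detection == "one_year_delay" else se
    rr = t.recurrence_probability
    if strategy == "pet":
        rr *= 1.0 - t.pet_recurrence_risk_reduction
    risk_states = recurrence_risk_states(variant)
    surgery = p.costs.surgery_event_cost

    # SurveillanceBenign: background death vs. malignant transformation
    alive = 1.0 - q
    P[idx["SB"], idx["UM"]] = alive * t.malignant_transformation
    P[idx["SB"], idx["SB"]] = alive * (1.0 - t.malignant_transformation)
    P[idx["SB"], idx["D"]] = q

    # UndetectedMalignant: background + disease death compete; survivors are
    # re-tested, detection leads to surgery (cost + perioperative mortality)
    alive = (1.0 - q_dis) * (1.0 - t.death_malignant_ipmn)
    to_surgery = alive * detect
    P[idx["UM"], idx["PRM1"]] = to_surgery * (1.0 - t.perioperative_mortality)
    P[idx["UM"], idx["UM"]] = alive * (1.0 - detect)
    p_death = (1.0 - alive) + to_surgery * t.perioperative_mortality
    P[idx["UM"], idx["D"]] = p_death
    C[idx["UM"], idx["PRM1"]] = surgery
    if p_death > 0:
        # perioperative deaths still incurred the surgery cost
        C[idx["UM"], idx["D"]] = to_surgery * t.perioperative_mortality * surgery / p_death

    # Post-resection benign: resection year then long-term follow-up
    alive = 1.0 - q
    P[idx["PRB1"], idx["PRB"]] = alive
    P[idx["PRB1"], idx["D"]] = q
    P[idx["PRB"], idx["PRB"]] = alive
    P[idx["PRB"], idx["D"]] = q

    # Post-resection malignant tunnel: recurrence risk per variant
    prm_chain = [s for s in states if s.startswith("PRM")]
    successor = {s: prm_chain[i + 1] if i + 1 < len(prm_chain) else "PRM"
                 for i, s in enumerate(prm_chain)}
    successor["PRM"] = "PRM"
    for s in prm_chain:
        risk = rr if s in risk_states else 0.0
        alive = 1.0 - q_dis
        P[idx[s], idx["REC"]] = alive * risk
        P[idx[s], idx[successor[s]]] += alive * (1.0 - risk)
        P[idx[s], idx["D"]] = q_dis
        if variant.recurrence_cost == "on_entry":
            C[idx[s], idx["REC"]] = p.costs.recurrence_cost

    # Recurrence: background + recurrence-specific death compete
    alive = (1.0 - q_dis) * (1.0 - t.death_recurrence)
    P[idx["REC"], idx["REC"]] = alive
    P[idx["REC"], idx["D"]] = 1.0 - alive

    P[idx["D"], idx["D"]] = 1.0
    return TransitionMatrix(states=tuple(states), probs=P, event_costs=C)


def reward_vectors(
    p: ModelParameters, variant: StructureVariant | None = None
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Per-cycle state cost and utility vectors ``(states, costs, utilities)``.

    Surveillance states are charged the annual imaging cost; post-resection
    states likewise unless the variant disables post-resection imaging.
    Recurrence carries its cost per cycle only under the ``per_cycle``
    variant (otherwise it is an entry event).
    """
    variant = variant or p.structure
    states = internal_states(variant)
    u = p.utilities
    cost = np.zeros(len(states))
    util = np.zeros(len(states))
    for i, s in enumerate(states):
        if s in ("SB", "UM"):
            cost[i] = p.costs.mri_exam
            util[i] = u.healthy_ipmn
        elif s in ("PRB1", "PRM1"):
            cost[i] = p.costs.mri_exam if variant.post_resection_imaging else 0.0
            util[i] = u.resection_year
        elif s.startswith("PR"):
            cost[i] = p.costs.mri_exam if variant.post_resection_imaging else 0.0
            util[i] = u.post_resection_longterm
        elif s == "REC":
            cost[i] = p.costs.recurrence_cost if variant.recurrence_cost == "per_cycle" else 0.0
            util[i] = u.recurrence
        else:  # Death
            util[i] = u.death
    return tuple(states), cost, util


@dataclass
class CohortTrace:
    """Per-cycle record of the cohort simulation.

    ``occupancy[t]`` is state membership at the start of cycle ``t``;
    row ``horizon`` is the terminal distribution.  Costs and QALYs are per
    cycle, with discounted counterparts and cumulative discounted totals.
    """

    states: tuple[str, ...]
    cycles: np.ndarray
    ages: np.ndarray
    occupancy: np.ndarray
    cost: np.ndarray
    qaly: np.ndarray
    discounted_cost: np.ndarray
    discounted_qaly: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.discounted_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.discounted_qaly.sum())

    @property
    def cumulative_cost(self) -> np.ndarray:
        return np.cumsum(self.discounted_cost)

    @property
    def cumulative_qaly(self) -> np.ndarray:
        return np.cumsum(self.discounted_qaly)

    def public_occupancy(self) -> pd.DataFrame:
        """Occupancy aggregated onto the six reportable health states."""
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        out = pd.DataFrame(
            {ps: 0.0 for ps in PUBLIC_STATES}, index=df.index
        )
        for s in self.states:
            out[PUBLIC_STATE_OF[s].value] += df[s]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """One row per cycle: cycle, age, public occupancies, rewards."""
        occ = self.public_occupancy().iloc[: len(self.cycles)].reset_index(drop=True)
        head = pd.DataFrame({"cycle": self.cycles, "age": self.ages})
        tail = pd.DataFrame(
            {
                "cost": self.cost,
                "discounted_cost": self.discounted_cost,
                "qaly": self.qaly,
                "discounted_qaly": self.discounted_qaly,
                "cumulative_discounted_cost": self.cumulative_cost,
                "cumulative_discounted_qaly": self.cumulative_qaly,
            }
        )
        return pd.concat([head, occ, tail], axis=1)


def run_cohort(
    alloc: InitialAllocation,
    p: ModelParameters,
    strategy: str,
    life_table: LifeTable,
    variant: StructureVariant | None = None,
) -> CohortTrace:
    """Propagate the cohort over the horizon, accumulating discounted rewards.

    The upfront diagnostic and surgery costs from the decision tree are
    charged in cycle 0 (undiscounted).  Event costs attached to transitions
    during cycle ``t`` are discounted with cycle ``t``'s factor.
    """
    variant = variant or p.structure
    econ = p.economics
    h = econ.horizon
    if h < 1:
        raise ValueError("horizon must be >= 1")
    states, state_cost, state_util = reward_vectors(p, variant)
    if states != tuple(alloc.states):
        raise ValueError("allocation states do not match the structural variant")
    n = len(states)

    occupancy = np.zeros((h + 1, n))
    occupancy[0] = alloc.occupancy
    cost = np.zeros(h)
    qaly = np.zeros(h)
    disc = (1.0 + econ.discount_rate) ** -np.arange(h)
    ages = econ.starting_age + econ.cycle_length * np.arange(h)

    for t in range(h):
        x = occupancy[t]
        tm = build_transition_matrix(ages[t], p, strategy, life_table, variant)
        x_next = x @ tm.probs
        mass = x.sum()
        if abs(x_next.sum() - mass) > 1e-12:
            raise AssertionError("cohort mass not conserved")
        occupancy[t + 1] = x_next
        reward_occ = 0.5 * (x + x_next) if variant.half_cycle_correction else x
        event_cost = float(x @ (tm.probs * tm.event_costs).sum(axis=1))
        cost[t] = float(reward_occ @ state_cost) + event_cost
        qaly[t] = float(reward_occ @ state_util)
    cost[0] += alloc.upfront_cost

    return CohortTrace(
        states=states,
        cycles=np.arange(h),
        ages=ages,
        occupancy=occupancy,
        cost=cost,
        qaly=qaly,
        discounted_cost=cost * disc,
        discounted_qaly=qaly * disc,
    )
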