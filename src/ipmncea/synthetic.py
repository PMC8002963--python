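"""Random parameter sets and the individual-level microsimulation oracle.

``generate_parameters`` perturbs every cost, utility, accuracy and
transition probability around its base value, clamped to validity, for
property tests over a family of valid models.

``microsimulate`` pushes ``n`` individuals through the identical decision
tree and per-cycle state transitions by random draws from the *same*
transition matrices, costs, utilities, and discounting as the cohort engine.
Its sample mean must agree with the cohort engine's expectation within
sampling error, which makes it an independent oracle for the engine's
accumulation and discounting logic (the matrices themselves are checked by
hand-arithmetic unit tests).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .lifetables import LifeTable
from .markov import build_transition_matrix, reward_vectors
from .parameters import (
    CostInputs,
    ModelParameters,
    TransitionInputs,
    UtilityInputs,
    validate_parameters,
)
from .structure import StructureVariant, internal_states

__all__ = ["MicrosimResult", "generate_parameters", "microsimulate"]


@dataclass(frozen=True)
class MicrosimResult:
    """Sample moments of discounted cost and QALYs over ``n`` individuals."""

    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _perturb(rng: np.random.Generator, value: float, scale: float,
             lo: float | None = None, hi: float | None = None) -> float:
    v = value * (1.0 + scale * rng.uniform(-1.0, 1.0))
    if lo is not None:
        v = max(v, lo)
    if hi is not None:
        v = min(v, hi)
    return v


def generate_parameters(
    seed: int, scale: float = 0.2, base: ModelParameters | None = None
) -> ModelParameters:
    """A valid random parameter set around the base case.

    Each accuracy, cost, utility and transition probability (and the
    pre-test probability) is independently multiplied by ``1 + scale*U`` with
    ``U ~ Uniform(-1, 1)`` and clamped to its validity range; economic
    settings other than the pre-test probability are left at base.  With
    ``scale=0`` the base case is returned unchanged.  Deterministic given
    ``seed``.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    p = (base or ModelParameters()).copy()
    rng = np.random.default_rng(seed)

    for acc in (p.ctmri, p.pet):
        acc.sensitivity = _perturb(rng, acc.sensitivity, scale, 0.0, 1.0)
        acc.specificity = _perturb(rng, acc.specificity, scale, 0.0, 1.0)
    for f in dataclasses.fields(CostInputs):
        hi = 1.0 if f.name.endswith("_fraction") else None
        setattr(p.costs, f.name, _perturb(rng, getattr(p.costs, f.name), scale, 0.0, hi))
    for f in dataclasses.fields(UtilityInputs):
        if f.name == "death":
            continue  # death stays at utility 0
        setattr(
            p.utilities, f.name,
            _perturb(rng, getattr(p.utilities, f.name), scale, 0.0, 1.0),
        )
    for f in dataclasses.fields(TransitionInputs):
        setattr(
            p.transitions, f.name,
            _perturb(rng, getattr(p.transitions, f.name), scale, 0.0, 1.0),
        )
    p.economics.pretest_probability = _perturb(
        rng, p.economics.pretest_probability, scale, 0.0, 1.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return validate_parameters(p)


def microsimulate(
    p: ModelParameters,
    strategy: str,
    n: int,
    seed: int,
    life_table: LifeTable,
    variant: StructureVariant | None = None,
) -> MicrosimResult:
    """Monte-Carlo estimate of per-patient discounted cost and QALYs.

    Individuals are drawn through the decision tree (disease status, test
    result, surgery, perioperative death) and then stepped cycle-by-cycle
    with categorical draws from the cohort engine's transition matrices.
    Rewards follow the same timing conventions as the engine, including the
    half-cycle-correction variant.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    variant = variant or p.structure
    rng = np.random.default_rng(seed)
    states = internal_states(variant)
    idx = {s: i for i, s in enumerate(states)}
    _, state_cost, state_util = reward_vectors(p, variant)

    econ = p.economics
    acc = p.pet if strategy == "pet" else p.ctmri
    prev = econ.pretest_probability
    pm = p.transitions.perioperative_mortality

    cost = np.zeros(n)
    qaly = np.zeros(n)

    # decision tree at cycle 0
    diseased = rng.random(n) < prev
    positive = np.where(
        diseased, rng.random(n) < acc.sensitivity, rng.random(n) < 1.0 - acc.specificity
    )
    imaging = p.costs.mri_exam + (p.costs.pet_exam if strategy == "pet" else 0.0)
    cost += imaging
    cost[positive] += p.costs.surgery_event_cost
    periop_dead = positive & (rng.random(n) < pm)

    state = np.full(n, idx["SB"], dtype=np.int64)
    state[diseased & ~positive] = idx["UM"]
    state[diseased & positive] = idx["PRM1"]
    state[~diseased & positive] = idx["PRB1"]
    state[periop_dead] = idx["D"]

    h = econ.horizon
    disc = (1.0 + econ.discount_rate) ** -np.arange(h)
    cum = None  # per-state cumulative transition probabilities for the cycle
    for t in range(h):
        age = econ.starting_age + econ.cycle_length * t
        tm = build_transition_matrix(age, p, strategy, life_table, variant)
        cum = np.cumsum(tm.probs, axis=1)
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int64)
        for s in np.unique(state):
            mask = state == s
            nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        np.minimum(nxt, len(states) - 1, out=nxt)
        if variant.half_cycle_correction:
            cost += disc[t] * 0.5 * (state_cost[state] + state_cost[nxt])
            qaly += disc[t] * 0.5 * (state_util[state] + state_util[nxt])
        else:
            cost += disc[t] * state_cost[state]
            qaly += disc[t] * state_util[state]
        cost += disc[t] * tm.event_costs[state, nxt]
        state = nxt

    se_cost = float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    se_qaly = float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return MicrosimResult(
        n=n,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=se_cost,
        se_qaly=se_qaly,
        seed=seed,
    )
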