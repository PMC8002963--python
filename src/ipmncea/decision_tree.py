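"""Diagnostic decision tree: cohort classification and initial allocation.

A cohort of patients with IPMN under evaluation for malignancy enters one of
two strategies: conventional CT/MRI imaging alone, or CT/MRI with a single
supplemental FDG-PET/CT.  Given the pre-test probability of malignancy and
the strategy's sensitivity/specificity, the cohort splits into true/false
positives and negatives.  Test-positive patients undergo pancreatic resection
immediately (with its cost, readmission cost, and one-time perioperative
mortality); test-negative patients enter guideline surveillance, false
negatives carrying an as-yet-undetected malignancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DiagnosticAccuracy, ModelParameters
from .structure import StructureVariant, internal_states

__all__ = ["CohortSplit", "InitialAllocation", "classify_cohort", "initial_allocation"]

STRATEGIES = ("ctmri", "pet")


@dataclass(frozen=True)
class CohortSplit:
    """Cohort fractions by diagnostic outcome; sums to 1."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.tp + self.fp + self.tn + self.fn - 1.0) > 1e-12:
            raise ValueError("cohort fractions must sum to 1")

    @property
    def test_positive(self) -> float:
        return self.tp + self.fp


@dataclass(frozen=True)
class InitialAllocation:
    """Cycle-0 state occupancy and the upfront (undiscounted) cost per patient.

    ``occupancy`` is indexed by the internal state labels in ``states``.  The
    first post-operative year's reduced utility is carried by the resection
    -year tunnel states, so no separate upfront utility term is needed.
    """

    states: tuple[str, ...]
    occupancy: np.ndarray
    upfront_cost: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.shape != (len(self.states),):
            raise ValueError("occupancy must have one entry per state")
        if abs(occ.sum() - 1.0) > 1e-12 or np.any(occ < -1e-15):
            raise ValueError("occupancy must be a distribution over states")
        if self.upfront_cost < 0:
            raise ValueError("upfront cost must be non-negative")


def classify_cohort(prevalence: float, acc: DiagnosticAccuracy) -> CohortSplit:
    """Split the cohort by true disease status and test result."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    se, sp = acc.sensitivity, acc.specificity
    return CohortSplit(
        tp=prevalence * se,
        fn=prevalence * (1.0 - se),
        tn=(1.0 - prevalence) * sp,
        fp=(1.0 - prevalence) * (1.0 - sp),
    )


def initial_allocation(
    split: CohortSplit,
    p: ModelParameters,
    strategy: str,
    variant: StructureVariant | None = None,
) -> InitialAllocation:
    """Assign diagnostic outcomes to Markov states and charge upfront costs.

    Test positives are resected at cycle 0: the weighted surgery cost plus
    readmission is charged, perioperative mortality moves that fraction to
    Death, and survivors start the first post-operative year (malignant for
    TP, benign for FP).  Test negatives enter surveillance (benign for TN,
    undetected-malignant for FN).  Both strategies are charged one CT/MRI
    exam; the PET strategy additionally charges one PET exam (the PET scan is
    supplemental to, not a replacement for, conventional imaging).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    variant = variant or p.structure
    states = internal_states(variant)
    idx = {s: i for i, s in enumerate(states)}

    pm = p.transitions.perioperative_mortality
    occ = np.zeros(len(states))
    occ[idx["SB"]] = split.tn
    occ[idx["UM"]] = split.fn
    occ[idx["PRM1"]] = split.tp * (1.0 - pm)
    occ[idx["PRB1"]] = split.fp * (1.0 - pm)
    occ[idx["D"]] = split.test_positive * pm

    upfront = p.costs.mri_exam
    if strategy == "pet":
        upfront += p.costs.pet_exam
    upfront += split.test_positive * p.costs.surgery_event_cost

    return InitialAllocation(states=tuple(states), occupancy=occ, upfront_cost=upfront)
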