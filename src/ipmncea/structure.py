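"""Health-state machinery and structural model variants.

The published model diagram names four health states (follow-up, resection,
recurrence, death).  To let every input parameter act on a distinct flow, the
cohort engine refines these into six reportable states:

* ``SurveillanceBenign``     — IPMN under surveillance, no malignancy.
* ``UndetectedMalignant``    — malignant transformation present but not (yet)
  detected, i.e. false negatives and new transformations awaiting detection.
* ``PostResectionBenign``    — resected on a false-positive finding.
* ``PostResectionMalignant`` — resected malignant IPMN, at risk of recurrence.
* ``Recurrence``             — recurrent malignant disease.
* ``Death``                  — absorbing.

Internally the engine expands the two post-resection states into small tunnel
chains so that the first post-operative year (with its reduced utility) and,
under some variants, a time-limited recurrence risk are expressible as a plain
Markov chain.  Internal states aggregate back onto the six reportable states
via :data:`PUBLIC_STATE_OF`.

Where the source publication under-specifies the model wiring, the alternatives
are enumerated explicitly as a :class:`StructureVariant`; the shipped default
is the combination selected by the calibration harness (see
:mod:`ipmncea.calibration` and ``docs/methods.md``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields


class HealthState(str, enum.Enum):
    """Reportable health states of the cohort model."""

    SURVEILLANCE_BENIGN = "SurveillanceBenign"
    UNDETECTED_MALIGNANT = "UndetectedMalignant"
    POST_RESECTION_BENIGN = "PostResectionBenign"
    POST_RESECTION_MALIGNANT = "PostResectionMalignant"
    RECURRENCE = "Recurrence"
    DEATH = "Death"


PUBLIC_STATES: tuple[str, ...] = tuple(s.value for s in HealthState)

_FN_DETECTION = ("annual_retest", "one_year_delay")
_RECURRENCE_RISK = ("every_cycle", "from_second_year", "first_five_years", "one_time")
_RECURRENCE_COST = ("on_entry", "per_cycle")
_BACKGROUND_MORTALITY = ("all_states", "disease_rates_only")


@dataclass(frozen=True)
class StructureVariant:
    """One combination of the structural choices the model leaves open.

    Parameters
    ----------
    fn_detection:
        How an undetected malignancy is found during surveillance.
        ``"annual_retest"`` re-applies the strategy's own sensitivity every
        cycle; ``"one_year_delay"`` detects deterministically one cycle later.
    recurrence_risk:
        Which post-resection cycles carry the annual recurrence probability:
        every cycle (exponential), every cycle after the resection year
        (``"from_second_year"``), only the first five post-operative years,
        or only the first post-operative year (``"one_time"``).
    recurrence_cost:
        Whether the cost of recurrent disease is charged once on entry to the
        Recurrence state or in every cycle spent in it.
    background_mortality:
        ``"all_states"`` combines the age-specific background death
        probability with every disease-specific risk as independent competing
        risks.  ``"disease_rates_only"`` applies the life-table risk only in
        states whose mortality is not already described by a cohort-derived
        rate (surveillance and post-resection-benign); rates estimated from
        clinical cohorts (death from untreated malignancy, death in
        recurrence) embed all-cause mortality, so stacking the life table on
        top of them double-counts background deaths.
    post_resection_imaging:
        Whether annual surveillance imaging continues after resection.
    half_cycle_correction:
        Average state membership across cycle boundaries when accruing
        rewards, instead of start-of-cycle membership.
    """

    fn_detection: str = "annual_retest"
    recurrence_risk: str = "every_cycle"
    recurrence_cost: str = "on_entry"
    background_mortality: str = "all_states"
    post_resection_imaging: bool = True
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.fn_detection not in _FN_DETECTION:
            raise ValueError(f"unknown fn_detection {self.fn_detection!r}")
        if self.recurrence_risk not in _RECURRENCE_RISK:
            raise ValueError(f"unknown recurrence_risk {self.recurrence_risk!r}")
        if self.recurrence_cost not in _RECURRENCE_COST:
            raise ValueError(f"unknown recurrence_cost {self.recurrence_cost!r}")
        if self.background_mortality not in _BACKGROUND_MORTALITY:
            raise ValueError(
                f"unknown background_mortality {self.background_mortality!r}"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "StructureVariant":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown structure keys: {sorted(unknown)}")
        return cls(**d)


def internal_states(variant: StructureVariant) -> list[str]:
    """Internal Markov state labels for a given structural variant.

    ``PRB1``/``PRM1`` are the first post-operative year (resection-year
    utility); ``PRM2``..``PRM5`` appear only under the ``first_five_years``
    recurrence-risk variant.
    """
    states = ["SB", "UM", "PRB1", "PRB", "PRM1"]
    if variant.recurrence_risk == "first_five_years":
        states += ["PRM2", "PRM3", "PRM4", "PRM5"]
    states += ["PRM", "REC", "D"]
    return states


def recurrence_risk_states(variant: StructureVariant) -> set[str]:
    """Internal states from which the annual recurrence probability applies."""
    if variant.recurrence_risk == "every_cycle":
        return {"PRM1", "PRM"}
    if variant.recurrence_risk == "from_second_year":
        return {"PRM"}
    if variant.recurrence_risk == "first_five_years":
        return {"PRM1", "PRM2", "PRM3", "PRM4", "PRM5"}
    return {"PRM1"}  # one_time


PUBLIC_STATE_OF: dict[str, HealthState] = {
    "SB": HealthState.SURVEILLANCE_BENIGN,
    "UM": HealthState.UNDETECTED_MALIGNANT,
    "PRB1": HealthState.POST_RESECTION_BENIGN,
    "PRB": HealthState.POST_RESECTION_BENIGN,
    "PRM1": HealthState.POST_RESECTION_MALIGNANT,
    "PRM2": HealthState.POST_RESECTION_MALIGNANT,
    "PRM3": HealthState.POST_RESECTION_MALIGNANT,
    "PRM4": HealthState.POST_RESECTION_MALIGNANT,
    "PRM5": HealthState.POST_RESECTION_MALIGNANT,
    "PRM": HealthState.POST_RESECTION_MALIGNANT,
    "REC": HealthState.RECURRENCE,
    "D": HealthState.DEATH,
}

# Shipped default: the variant combination that best reproduces the published
# base-case results, selected by ipmncea.calibration.calibrate (methods note).
DEFAULT_VARIANT = StructureVariant(
    fn_detection="annual_retest",
    recurrence_risk="from_second_year",
    recurrence_cost="per_cycle",
    background_mortality="all_states",
    post_resection_imaging=False,
    half_cycle_correction=False,
)
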