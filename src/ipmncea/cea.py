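"""Cost-effectiveness metrics: NMB, incremental analysis, dominance.

The net monetary benefit (NMB) of a strategy is ``WTP × E − C`` where ``E``
is cumulative discounted effectiveness in QALYs, ``C`` cumulative discounted
cost, and WTP the willingness-to-pay threshold per QALY.  Incremental values
are reported relative to the PET strategy (matching the sign convention of
the published results table); a strategy that is both cheaper and more
effective dominates, and no ICER is reported under dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .decision_tree import classify_cohort, initial_allocation
from .lifetables import LifeTable
from .markov import CohortTrace, run_cohort
from .parameters import ModelParameters
from .structure import StructureVariant

__all__ = [
    "StrategyResult",
    "CEAResult",
    "net_monetary_benefit",
    "incremental_analysis",
    "run_strategy",
    "run_base_case",
    "compare_to_reference",
]


def net_monetary_benefit(cost: float, effectiveness: float, wtp: float) -> float:
    """``wtp * effectiveness - cost`` (US-$); higher is better."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * effectiveness - cost


@dataclass(frozen=True)
class StrategyResult:
    """Cumulative discounted outcomes of one diagnostic strategy."""

    label: str
    cost: float
    effectiveness: float
    nmb: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of two strategies (reference first)."""

    reference: StrategyResult
    comparator: StrategyResult
    incremental_cost: float
    incremental_effectiveness: float
    icer: float | None
    dominance: str  # of the reference strategy: dominant / dominated / tradeoff

    def to_frame(self) -> pd.DataFrame:
        """Two-row table mirroring the published base-case layout."""
        rows = [
            {
                "strategy": self.reference.label,
                "cumulative_discounted_cost": self.reference.cost,
                "incremental_cost": math.nan,
                "cumulative_discounted_effectiveness": self.reference.effectiveness,
                "incremental_effectiveness": math.nan,
                "net_monetary_benefit": self.reference.nmb,
            },
            {
                "strategy": self.comparator.label,
                "cumulative_discounted_cost": self.comparator.cost,
                "incremental_cost": self.incremental_cost,
                "cumulative_discounted_effectiveness": self.comparator.effectiveness,
                "incremental_effectiveness": self.incremental_effectiveness,
                "net_monetary_benefit": self.comparator.nmb,
            },
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "strategies": {
                r.label: {
                    "cost": r.cost,
                    "effectiveness": r.effectiveness,
                    "nmb": r.nmb,
                }
                for r in (self.reference, self.comparator)
            },
            "incremental_cost": self.incremental_cost,
            "incremental_effectiveness": self.incremental_effectiveness,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def incremental_analysis(
    a: StrategyResult, b: StrategyResult, wtp: float
) -> CEAResult:
    """Incremental comparison of ``b`` against reference ``a``.

    ``incremental_cost = cost_b - cost_a`` and likewise for effectiveness.
    ``dominance`` classifies the *reference*: "dominant" if it is no more
    costly and no less effective (strictly better on at least one axis),
    "dominated" for the mirror case, else "tradeoff".  The ICER is reported
    only in the tradeoff case with nonzero incremental effectiveness.
    """
    d_cost = b.cost - a.cost
    d_eff = b.effectiveness - a.effectiveness
    if (d_cost >= 0 and d_eff <= 0) and (d_cost > 0 or d_eff < 0):
        dominance = "dominant"
    elif (d_cost <= 0 and d_eff >= 0) and (d_cost < 0 or d_eff > 0):
        dominance = "dominated"
    else:
        dominance = "tradeoff"
    icer = None
    if dominance == "tradeoff" and d_eff != 0.0:
        icer = d_cost / d_eff
    return CEAResult(
        reference=a,
        comparator=b,
        incremental_cost=d_cost,
        incremental_effectiveness=d_eff,
        icer=icer,
        dominance=dominance,
    )


_LABELS = {"pet": "Add. FDG-PET/CT", "ctmri": "CT/MRI"}


def run_strategy(
    p: ModelParameters,
    life_table: LifeTable,
    strategy: str,
    variant: StructureVariant | None = None,
) -> tuple[StrategyResult, CohortTrace]:
    """Full pipeline for one strategy: classify, allocate, run, summarize."""
    acc = p.pet if strategy == "pet" else p.ctmri
    split = classify_cohort(p.economics.pretest_probability, acc)
    alloc = initial_allocation(split, p, strategy, variant)
    trace = run_cohort(alloc, p, strategy, life_table, variant)
    cost, eff = trace.total_cost, trace.total_qaly
    result = StrategyResult(
        label=_LABELS[strategy],
        cost=cost,
        effectiveness=eff,
        nmb=net_monetary_benefit(cost, eff, p.economics.wtp),
    )
    return result, trace


def run_base_case(
    p: ModelParameters,
    life_table: LifeTable,
    variant: StructureVariant | None = None,
) -> tuple[CEAResult, dict[str, CohortTrace]]:
    """Run both strategies and the incremental analysis (PET as reference)."""
    pet, pet_trace = run_strategy(p, life_table, "pet", variant)
    ctmri, ct_trace = run_strategy(p, life_table, "ctmri", variant)
    result = incremental_analysis(pet, ctmri, p.economics.wtp)
    return result, {"pet": pet_trace, "ctmri": ct_trace}


def compare_to_reference(
    result: CEAResult,
    reference: dict[str, float],
    tolerances: dict[str, tuple[str, float]],
) -> pd.DataFrame:
    """Deviation report of computed quantities against reference values.

    ``reference`` maps quantity names (keys of the flattened result dict,
    e.g. ``"pet_cost"``) to reference values; ``tolerances`` maps the same
    names to ``("rel", x)`` or ``("abs", x)`` bounds.  Returns one row per
    quantity with absolute/relative deviation and a pass flag.
    """
    computed = {
        "pet_cost": result.reference.cost,
        "pet_effectiveness": result.reference.effectiveness,
        "pet_nmb": result.reference.nmb,
        "ctmri_cost": result.comparator.cost,
        "ctmri_effectiveness": result.comparator.effectiveness,
        "ctmri_nmb": result.comparator.nmb,
        "incremental_cost": result.incremental_cost,
        "incremental_effectiveness": result.incremental_effectiveness,
    }
    rows = []
    for name, ref in reference.items():
        if name not in computed:
            raise KeyError(f"unknown reference quantity {name!r}")
        value = computed[name]
        abs_dev = abs(value - ref)
        rel_dev = abs_dev / abs(ref) if ref != 0 else math.inf
        ok = True
        kind, tol = tolerances.get(name, (None, None))
        if kind == "rel":
            ok = rel_dev <= tol
        elif kind == "abs":
            ok = abs_dev <= tol
        elif kind is not None:
            raise ValueError(f"unknown tolerance kind {kind!r}")
        rows.append(
            {
                "quantity": name,
                "value": value,
                "reference": ref,
                "abs_deviation": abs_dev,
                "rel_deviation": rel_dev,
                "tolerance_kind": kind,
                "tolerance": tol,
                "pass": ok,
            }
        )
    return pd.DataFrame(rows)
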