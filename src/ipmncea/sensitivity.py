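"""Deterministic sensitivity analysis and threshold analysis.

One-way DSA re-runs both strategies end-to-end with a single parameter at
its low/high bound (all others at base) and records the incremental cost and
effectiveness (PET minus CT/MRI), for display as tornado diagrams.

The threshold analysis finds the parameter value at which the two
strategies' net monetary benefits cross, by bisection after verifying by
dense pre-sampling that the NMB difference is monotone over the search
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .cea import run_base_case
from .lifetables import LifeTable
from .parameters import ModelParameters, get_param, with_param
from .structure import StructureVariant

__all__ = [
    "ParameterRange",
    "TornadoEntry",
    "ThresholdResult",
    "default_ranges",
    "one_way_dsa",
    "threshold_analysis",
    "find_root_bisect",
    "specificity_sweep",
]


@dataclass(frozen=True)
class ParameterRange:
    """Low/base/high values for one dotted parameter path."""

    path: str
    low: float
    base: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.path}: require low <= base <= high")


@dataclass(frozen=True)
class TornadoEntry:
    """Incremental outcomes (PET − CT/MRI) with one parameter at its bounds."""

    parameter: str
    low: float
    high: float
    incremental_cost_low: float
    incremental_cost_high: float
    incremental_effectiveness_low: float
    incremental_effectiveness_high: float

    @property
    def cost_bar_width(self) -> float:
        return abs(self.incremental_cost_high - self.incremental_cost_low)

    @property
    def effectiveness_bar_width(self) -> float:
        return abs(
            self.incremental_effectiveness_high - self.incremental_effectiveness_low
        )


# Parameters varied in the published tornado diagrams; bounds are +/-20% of
# base (clamped to validity) unless overridden in a config.
_DSA_PATHS = [
    "ctmri.sensitivity",
    "ctmri.specificity",
    "pet.sensitivity",
    "pet.specificity",
    "costs.mri_exam",
    "costs.pet_exam",
    "costs.pancreatoduodenectomy",
    "costs.distal_resection",
    "costs.recurrence_cost",
    "economics.pretest_probability",
    "transitions.recurrence_probability",
    "transitions.perioperative_mortality",
]

_PROB_PATHS = {
    "ctmri.sensitivity",
    "ctmri.specificity",
    "pet.sensitivity",
    "pet.specificity",
    "economics.pretest_probability",
    "transitions.recurrence_probability",
    "transitions.perioperative_mortality",
}


def default_ranges(
    p: ModelParameters, rel: float = 0.2, paths: list[str] | None = None
) -> list[ParameterRange]:
    """±``rel`` ranges around base for the standard DSA parameter set."""
    ranges = []
    for path in paths or _DSA_PATHS:
        base = get_param(p, path)
        lo, hi = base * (1 - rel), base * (1 + rel)
        if path in _PROB_PATHS:
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        else:
            lo = max(lo, 0.0)
        ranges.append(ParameterRange(path, lo, base, hi))
    return ranges


def one_way_dsa(
    p: ModelParameters,
    life_table: LifeTable,
    ranges: list[ParameterRange] | None = None,
    variant: StructureVariant | None = None,
) -> list[TornadoEntry]:
    """One-way DSA over the given ranges, sorted by cost-bar width (widest first).

    Each range is validated (via the parameter set's own validation) before
    any model run.
    """
    ranges = ranges if ranges is not None else default_ranges(p)
    # validate all bounds up front so a bad range fails before any run
    varied = [
        (r, with_param(p, r.path, r.low), with_param(p, r.path, r.high))
        for r in ranges
    ]
    entries = []
    for r, p_lo, p_hi in varied:
        res_lo, _ = run_base_case(p_lo, life_table, variant)
        res_hi, _ = run_base_case(p_hi, life_table, variant)
        # incremental_* in CEAResult is CT/MRI minus PET; tornado reports PET - CT/MRI
        entries.append(
            TornadoEntry(
                parameter=r.path,
                low=r.low,
                high=r.high,
                incremental_cost_low=-res_lo.incremental_cost,
                incremental_cost_high=-res_hi.incremental_cost,
                incremental_effectiveness_low=-res_lo.incremental_effectiveness,
                incremental_effectiveness_high=-res_hi.incremental_effectiveness,
            )
        )
    return sorted(entries, key=lambda e: e.cost_bar_width, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "incremental_cost_low": [e.incremental_cost_low for e in entries],
            "incremental_cost_high": [e.incremental_cost_high for e in entries],
            "incremental_effectiveness_low": [
                e.incremental_effectiveness_low for e in entries
            ],
            "incremental_effectiveness_high": [
                e.incremental_effectiveness_high for e in entries
            ],
        }
    )


def find_root_bisect(
    f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-4
) -> float:
    """Bisection root of ``f`` on ``[lo, hi]`` to interval width < ``tol``.

    Requires a sign change across the interval.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    return float(bisect(f, lo, hi, xtol=tol))


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold search on one parameter."""

    parameter: str
    value: float | None  # None when the NMB difference never changes sign
    crossed: bool


def threshold_analysis(
    p: ModelParameters,
    life_table: LifeTable,
    path: str = "pet.specificity",
    interval: tuple[float, float] = (0.50, 0.99),
    tol: float = 1e-4,
    presample: int = 50,
    variant: StructureVariant | None = None,
) -> ThresholdResult:
    """Parameter value at which PET and CT/MRI net monetary benefits are equal.

    ``f(x) = NMB_PET(x) − NMB_CTMRI(x)`` is pre-sampled at ``presample``
    points to verify monotonicity (a non-monotone profile raises, reporting
    the sampled sign pattern); a constant sign returns ``crossed=False``,
    otherwise the root is found by bisection to interval width < ``tol``.
    """
    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")

    def f(x: float) -> float:
        result, _ = run_base_case(with_param(p, path, x), life_table, variant)
        return result.reference.nmb - result.comparator.nmb

    xs = np.linspace(lo, hi, presample)
    fs = np.array([f(x) for x in xs])
    diffs = np.diff(fs)
    slack = 1e-9 * max(1.0, float(np.abs(fs).max()))
    if not (np.all(diffs >= -slack) or np.all(diffs <= slack)):
        signs = "".join("+" if v > 0 else ("-" if v < 0 else "0") for v in fs)
        raise ValueError(
            f"NMB difference is not monotone over {interval}: sign pattern {signs}"
        )
    if np.all(fs > 0) or np.all(fs < 0):
        return ThresholdResult(parameter=path, value=None, crossed=False)
    # bracket the sign change from the pre-sample to keep bisection robust
    change = int(np.nonzero(np.sign(fs[:-1]) != np.sign(fs[1:]))[0][0])
    root = find_root_bisect(f, float(xs[change]), float(xs[change + 1]), tol)
    return ThresholdResult(parameter=path, value=root, crossed=True)


def specificity_sweep(
    p: ModelParameters,
    life_table: LifeTable,
    path: str = "pet.specificity",
    grid: np.ndarray | None = None,
    variant: StructureVariant | None = None,
) -> pd.DataFrame:
    """NMB of both strategies over a parameter grid (threshold-plot data)."""
    if grid is None:
        grid = np.linspace(0.50, 0.99, 50)
    rows = []
    for x in grid:
        result, _ = run_base_case(with_param(p, path, float(x)), life_table, variant)
        rows.append(
            {
                "value": float(x),
                "nmb_pet": result.reference.nmb,
                "nmb_ctmri": result.comparator.nmb,
            }
        )
    return pd.DataFrame(rows)
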