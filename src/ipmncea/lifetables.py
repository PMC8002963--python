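"""Age-adjusted background mortality.

A :class:`LifeTable` maps integer age to the annual probability of death
``qx``.  The cohort model starts at a fractional age (64.3 years in the base
case) and advances one year per cycle, so lookups linearly interpolate ``qx``
between the bracketing integer ages; ages beyond the table clamp to the last
tabulated value.

Two sources are provided: a bundled CSV covering ages 60-85 for the base case,
and a deterministic Gompertz generator for synthetic tables in tests and
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "lookup_mortality",
    "synthesize_life_table",
    "load_life_table",
    "bundled_us_2017",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` on a contiguous integer age grid."""

    ages: np.ndarray  # integer years, strictly increasing by 1
    qx: np.ndarray    # annual death probability per age

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.size == 0 or qx.shape != ages.shape:
            raise ValueError("ages and qx must be equal-length 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous integers")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("every qx must be in [0, 1]")

    def annual_mortality(self, age: float) -> float:
        return lookup_mortality(self, age)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def lookup_mortality(lt: LifeTable, age: float) -> float:
    """Annual death probability at a (possibly fractional) age.

    Linear interpolation between bracketing integer ages; ages above the
    table's maximum return the last ``qx``.  Ages below the table raise.
    """
    if age < lt.ages[0]:
        raise ValueError(
            f"age {age} below the tabulated range [{lt.ages[0]}, {lt.ages[-1]}]"
        )
    return float(np.interp(age, lt.ages, lt.qx))


def synthesize_life_table(
    a: float = 2.0e-5,
    b: float = 0.095,
    age_range: tuple[int, int] = (0, 110),
) -> LifeTable:
    """Deterministic Gompertz life table: ``qx = 1 - exp(-a * exp(b * age))``.

    ``a`` sets the overall mortality level and ``b`` the exponential slope
    with age; both must be positive.  Values are clamped to [0, 1].
    """
    if a <= 0 or b <= 0:
        raise ValueError("Gompertz parameters a and b must be positive")
    lo, hi = age_range
    ages = np.arange(int(lo), int(hi) + 1)
    qx = 1.0 - np.exp(-a * np.exp(b * ages))
    return LifeTable(ages=ages, qx=np.clip(qx, 0.0, 1.0))


def load_life_table(path: str | Path) -> LifeTable:
    """Read a two-column CSV (``age``, ``qx``) with a header row."""
    df = pd.read_csv(path)
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise ValueError(f"life-table CSV missing columns: {sorted(missing)}")
    df = df.sort_values("age")
    return LifeTable(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def bundled_us_2017() -> LifeTable:
    """The packaged background-mortality table for ages 60-85.

    A Gompertz-smoothed synthetic stand-in anchored to representative 2017 US
    all-population mortality levels (about 1.3% at 65 rising to 4.8% at 80),
    not a verbatim copy of the official life table; see ``docs/methods.md``.
    """
    ref = resources.files("ipmncea.data").joinpath("us2017_smoothed_qx.csv")
    with resources.as_file(ref) as path:
        return load_life_table(path)
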