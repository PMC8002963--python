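"""Model input parameters: definition, loading, validation.

All inputs of the cost-effectiveness model are literature-derived constants
grouped into small typed blocks (diagnostic accuracy, costs, utilities,
transition probabilities, economic settings).  Config files are YAML (JSON is
valid YAML) with keys mirroring the published input table in snake_case.

Because published tables mix percentages and fractions, any scalar key may be
suffixed ``_percent`` in a config file; the loader divides such values by 100
and strips the suffix, so ``specificity_percent: 91.1`` and
``specificity: 0.911`` are equivalent.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import yaml

from .structure import DEFAULT_VARIANT, StructureVariant

__all__ = [
    "DiagnosticAccuracy",
    "CostInputs",
    "UtilityInputs",
    "TransitionInputs",
    "EconomicSettings",
    "ModelParameters",
    "ParameterError",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "base_case_parameters",
    "get_param",
    "with_param",
]


class ParameterError(ValueError):
    """Invalid or unparseable model input."""


@dataclass
class DiagnosticAccuracy:
    """Sensitivity/specificity of an imaging strategy for malignant IPMN."""

    sensitivity: float
    specificity: float


@dataclass
class CostInputs:
    """Per-event costs in US-$ and the resection-type mix.

    ``head_resection_fraction``/``distal_resection_fraction`` give the mix of
    pancreatoduodenectomy vs. distal resection among operated patients.  The
    published proportions (78%/21%) sum to 0.99; the weighted surgery cost
    renormalizes over their sum rather than assigning the residual to an
    unpriced third procedure.
    """

    mri_exam: float = 492.0
    pet_exam: float = 1551.0
    pancreatoduodenectomy: float = 28623.0
    distal_resection: float = 13900.0
    head_resection_fraction: float = 0.78
    distal_resection_fraction: float = 0.21
    recurrence_cost: float = 78630.0
    readmission_cost: float = 1930.0

    @property
    def weighted_resection_cost(self) -> float:
        """Mean surgery cost over the (renormalized) resection-type mix."""
        total = self.head_resection_fraction + self.distal_resection_fraction
        if total <= 0:
            raise ParameterError("resection-type fractions sum to zero")
        return (
            self.head_resection_fraction * self.pancreatoduodenectomy
            + self.distal_resection_fraction * self.distal_resection
        ) / total

    @property
    def surgery_event_cost(self) -> float:
        """Weighted resection cost plus the per-surgery readmission cost."""
        return self.weighted_resection_cost + self.readmission_cost


@dataclass
class UtilityInputs:
    """Health-state utilities (QALY weights per year)."""

    healthy_ipmn: float = 1.0
    resection_year: float = 0.818
    post_resection_longterm: float = 0.896
    recurrence: float = 0.65
    death: float = 0.0


@dataclass
class TransitionInputs:
    """Annual transition probabilities and per-surgery mortality."""

    malignant_transformation: float = 0.0223
    death_malignant_ipmn: float = 0.027
    death_recurrence: float = 0.283
    perioperative_mortality: float = 0.046
    recurrence_probability: float = 0.167
    pet_recurrence_risk_reduction: float = 0.10


@dataclass
class EconomicSettings:
    """Economic evaluation settings (US healthcare perspective)."""

    wtp: float = 100000.0
    discount_rate: float = 0.03
    horizon: int = 15
    cycle_length: float = 1.0
    starting_age: float = 64.3
    pretest_probability: float = 0.52


@dataclass
class ModelParameters:
    """Complete, validated input set of the cost-effectiveness model."""

    ctmri: DiagnosticAccuracy = field(
        default_factory=lambda: DiagnosticAccuracy(0.809, 0.762)
    )
    pet: DiagnosticAccuracy = field(
        default_factory=lambda: DiagnosticAccuracy(0.968, 0.911)
    )
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    transitions: TransitionInputs = field(default_factory=TransitionInputs)
    economics: EconomicSettings = field(default_factory=EconomicSettings)
    structure: StructureVariant = DEFAULT_VARIANT

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["structure"] = self.structure.to_dict()
        return d

    @classmethod
    def from_dict(cls, data: dict, use_defaults: bool = False) -> "ModelParameters":
        return _params_from_dict(data, use_defaults=use_defaults)


_BLOCK_TYPES: dict[str, type] = {
    "ctmri": DiagnosticAccuracy,
    "pet": DiagnosticAccuracy,
    "costs": CostInputs,
    "utilities": UtilityInputs,
    "transitions": TransitionInputs,
    "economics": EconomicSettings,
}

# (block, field) -> validity class; "probability"/"utility" in [0,1], "cost" >= 0
_PROBABILITY_FIELDS = {
    ("ctmri", "sensitivity"),
    ("ctmri", "specificity"),
    ("pet", "sensitivity"),
    ("pet", "specificity"),
    ("costs", "head_resection_fraction"),
    ("costs", "distal_resection_fraction"),
    ("transitions", "malignant_transformation"),
    ("transitions", "death_malignant_ipmn"),
    ("transitions", "death_recurrence"),
    ("transitions", "perioperative_mortality"),
    ("transitions", "recurrence_probability"),
    ("transitions", "pet_recurrence_risk_reduction"),
    ("economics", "pretest_probability"),
}
_UTILITY_FIELDS = {("utilities", f.name) for f in dataclasses.fields(UtilityInputs)}
_COST_FIELDS = {
    ("costs", f.name)
    for f in dataclasses.fields(CostInputs)
    if not f.name.endswith("_fraction")
} | {("economics", "wtp")}


def _normalize_percent_keys(block: dict, context: str) -> dict:
    out: dict[str, Any] = {}
    for key, value in block.items():
        if key.endswith("_percent"):
            base = key[: -len("_percent")]
            if base in block:
                raise ParameterError(
                    f"{context}: both {base!r} and {key!r} given"
                )
            out[base] = float(value) / 100.0
        else:
            out[key] = value
    return out


def _params_from_dict(data: dict, use_defaults: bool) -> ModelParameters:
    if not isinstance(data, dict):
        raise ParameterError("config root must be a mapping")
    data = dict(data)
    structure_raw = data.pop("structure", None)
    unknown = set(data) - set(_BLOCK_TYPES)
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")

    defaults = ModelParameters()  # packaged base-case values
    blocks: dict[str, Any] = {}
    for name, typ in _BLOCK_TYPES.items():
        raw = data.get(name)
        if raw is None:
            if not use_defaults:
                raise ParameterError(f"missing config section {name!r}")
            blocks[name] = copy.deepcopy(getattr(defaults, name))
            continue
        if not isinstance(raw, dict):
            raise ParameterError(f"section {name!r} must be a mapping")
        raw = _normalize_percent_keys(raw, name)
        known = {f.name for f in dataclasses.fields(typ)}
        unknown_keys = set(raw) - known
        if unknown_keys:
            raise ParameterError(
                f"unknown keys in section {name!r}: {sorted(unknown_keys)}"
            )
        missing = known - set(raw)
        if missing and not use_defaults:
            raise ParameterError(
                f"missing keys in section {name!r}: {sorted(missing)}"
            )
        kwargs = {k: _coerce(name, k, v) for k, v in raw.items()}
        for k in missing:
            kwargs[k] = getattr(getattr(defaults, name), k)
        blocks[name] = typ(**kwargs)

    if isinstance(structure_raw, dict):
        structure = StructureVariant.from_dict(structure_raw)
    elif structure_raw is None:
        structure = DEFAULT_VARIANT
    else:
        raise ParameterError("structure must be a mapping of variant options")

    p = ModelParameters(structure=structure, **blocks)
    return validate_parameters(p)


def _coerce(block: str, key: str, value: Any) -> Any:
    if block == "economics" and key == "horizon":
        h = int(value)
        if h != value:
            raise ParameterError("economics.horizon must be an integer")
        return h
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ParameterError(f"{block}.{key} must be a number, got {value!r}")
    return float(value)


def _iter_scalar_fields(p: ModelParameters) -> Iterator[tuple[str, str, float]]:
    for block in _BLOCK_TYPES:
        obj = getattr(p, block)
        for f in dataclasses.fields(obj):
            yield block, f.name, getattr(obj, f.name)


def validate_parameters(p: ModelParameters) -> ModelParameters:
    """Validate ranges field-by-field; returns the (unchanged) parameter set.

    Raises :class:`ParameterError` naming the offending field on any range
    violation.  A resection-type mix not summing to 1 is only warned about:
    the published proportions themselves sum to 0.99.
    """
    for block, name, value in _iter_scalar_fields(p):
        path = f"{block}.{name}"
        if (block, name) in _PROBABILITY_FIELDS:
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{path} must be a probability in [0, 1], got {value}")
        elif (block, name) in _UTILITY_FIELDS:
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{path} must be a utility in [0, 1], got {value}")
        elif (block, name) in _COST_FIELDS:
            if value < 0:
                raise ParameterError(f"{path} must be non-negative, got {value}")
    if p.utilities.death != 0.0:
        raise ParameterError("utilities.death must be 0")
    if not 0.0 <= p.economics.discount_rate < 1.0:
        raise ParameterError("economics.discount_rate must be in [0, 1)")
    if p.economics.horizon < 1:
        raise ParameterError("economics.horizon must be >= 1")
    if p.economics.cycle_length != 1.0:
        raise ParameterError("economics.cycle_length must be 1 (annual cycles)")
    mix = p.costs.head_resection_fraction + p.costs.distal_resection_fraction
    if abs(mix - 1.0) > 1e-9:
        warnings.warn(
            f"resection-type fractions sum to {mix:.4g}, not 1; the weighted "
            "surgery cost renormalizes over their sum",
            UserWarning,
            stacklevel=2,
        )
    return p


def load_parameters(path: str | Path, use_defaults: bool = False) -> ModelParameters:
    """Load and validate a YAML/JSON parameter config.

    With ``use_defaults=True``, keys absent from the file are filled from the
    packaged base-case values; otherwise every key is required.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParameterError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParameterError(f"cannot parse config {path}: {exc}") from exc
    return _params_from_dict(data or {}, use_defaults=use_defaults)


def save_parameters(p: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to YAML (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    d = p.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def base_case_parameters() -> ModelParameters:
    """The packaged base-case parameter set (the published input table)."""
    ref = resources.files("ipmncea.data").joinpath("base_case.yaml")
    data = yaml.safe_load(ref.read_text())
    return _params_from_dict(data, use_defaults=False)


# -- dotted-path access (used by the sensitivity module) ---------------------

def get_param(p: ModelParameters, path: str) -> float:
    """Read a scalar by dotted path, e.g. ``"pet.specificity"``."""
    obj: Any = p
    for part in path.split("."):
        try:
            obj = getattr(obj, part)
        except AttributeError as exc:
            raise ParameterError(f"unknown parameter path {path!r}") from exc
    if not isinstance(obj, (int, float)):
        raise ParameterError(f"parameter path {path!r} is not a scalar")
    return float(obj)


def with_param(p: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a validated deep copy with the field at ``path`` set to ``value``."""
    q = p.copy()
    *head, last = path.split(".")
    obj: Any = q
    for part in head:
        try:
            obj = getattr(obj, part)
        except AttributeError as exc:
            raise ParameterError(f"unknown parameter path {path!r}") from exc
    if not hasattr(obj, last):
        raise ParameterError(f"unknown parameter path {path!r}")
    setattr(obj, last, float(value))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return validate_parameters(q)
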