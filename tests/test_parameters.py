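"""Parameter loading, validation, and round-trip behaviour."""

import warnings

import pytest
import yaml

from ipmncea import (
    ModelParameters,
    ParameterError,
    get_param,
    load_parameters,
    save_parameters,
    validate_parameters,
    with_param,
)


def test_packaged_base_case_values(base_params):
    p = base_params
    assert p.pet.sensitivity == pytest.approx(0.968)
    assert p.pet.specificity == pytest.approx(0.911)
    assert p.ctmri.sensitivity == pytest.approx(0.809)
    assert p.ctmri.specificity == pytest.approx(0.762)
    assert p.costs.pet_exam == 1551
    assert p.economics.wtp == 100000
    assert p.economics.discount_rate == pytest.approx(0.03)
    assert p.economics.starting_age == pytest.approx(64.3)
    assert p.economics.pretest_probability == pytest.approx(0.52)


def test_weighted_resection_cost_renormalizes(base_params):
    # (0.78*28623 + 0.21*13900) / 0.99
    assert base_params.costs.weighted_resection_cost == pytest.approx(25499.939393939)


def test_percent_suffix_equivalent_to_fraction(tmp_path, base_params):
    cfg = tmp_path / "p.yaml"
    cfg.write_text(yaml.safe_dump({"pet": {"sensitivity_percent": 96.8, "specificity": 0.911}}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        p = load_parameters(cfg, use_defaults=True)
    assert p.pet.sensitivity == pytest.approx(0.968)


def test_missing_section_requires_use_defaults(tmp_path):
    cfg = tmp_path / "p.yaml"
    cfg.write_text(yaml.safe_dump({"pet": {"sensitivity": 0.9, "specificity": 0.9}}))
    with pytest.raises(ParameterError, match="missing"):
        load_parameters(cfg)


@pytest.mark.parametrize(
    "section, key, value, match",
    [
        ("pet", "sensitivity", 1.2, "probability"),
        ("costs", "recurrence_cost", -5.0, "recurrence_cost"),
        ("utilities", "recurrence", 1.5, "utility"),
    ],
)
def test_out_of_range_values_rejected(tmp_path, section, key, value, match):
    cfg = tmp_path / "p.yaml"
    cfg.write_text(yaml.safe_dump({section: {key: value}}))
    with pytest.raises(ParameterError, match=match):
        load_parameters(cfg, use_defaults=True)


def test_unknown_keys_rejected(tmp_path):
    cfg = tmp_path / "p.yaml"
    cfg.write_text(yaml.safe_dump({"pet": {"sensibility": 0.9}}))
    with pytest.raises(ParameterError, match="unknown"):
        load_parameters(cfg, use_defaults=True)


def test_resection_mix_warning(base_params):
    with pytest.warns(UserWarning, match="0.99"):
        validate_parameters(base_params)


def test_all_zero_costs_pass():
    p = ModelParameters()
    for f in ("mri_exam", "pet_exam", "pancreatoduodenectomy", "distal_resection",
              "recurrence_cost", "readmission_cost"):
        setattr(p.costs, f, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        validate_parameters(p)


def test_round_trip_identity(tmp_path, base_params):
    out = tmp_path / "roundtrip.yaml"
    save_parameters(base_params, out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        again = load_parameters(out)
    assert again == base_params


def test_validate_idempotent(base_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        once = validate_parameters(base_params)
        twice = validate_parameters(once)
    assert twice == once


def test_dotted_path_get_and_set(base_params):
    assert get_param(base_params, "pet.specificity") == pytest.approx(0.911)
    q = with_param(base_params, "pet.specificity", 0.7)
    assert q.pet.specificity == 0.7
    assert base_params.pet.specificity == pytest.approx(0.911)  # original untouched
    with pytest.raises(ParameterError):
        get_param(base_params, "pet.does_not_exist")
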