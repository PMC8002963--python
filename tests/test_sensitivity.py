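"""One-way DSA and threshold/bisection behaviour."""

import numpy as np
import pytest

from ipmncea import (
    ParameterRange,
    default_ranges,
    one_way_dsa,
    run_base_case,
    specificity_sweep,
    threshold_analysis,
)
from ipmncea.parameters import ParameterError
from ipmncea.sensitivity import find_root_bisect


def test_bisection_recovers_closed_form_root():
    root = find_root_bisect(lambda x: x - 0.7, 0.0, 1.0, tol=1e-4)
    assert root == pytest.approx(0.7, abs=1e-4)


def test_degenerate_range_gives_zero_width_bar(base_params, life_table):
    base = base_params.pet.specificity
    r = ParameterRange("pet.specificity", base, base, base)
    (entry,) = one_way_dsa(base_params, life_table, [r])
    assert entry.cost_bar_width == pytest.approx(0.0, abs=1e-9)
    assert entry.effectiveness_bar_width == pytest.approx(0.0, abs=1e-12)


def test_dsa_at_base_reproduces_base_case(base_params, life_table):
    base = base_params.pet.specificity
    r = ParameterRange("pet.specificity", base, base, base)
    (entry,) = one_way_dsa(base_params, life_table, [r])
    result, _ = run_base_case(base_params, life_table)
    assert entry.incremental_cost_low == pytest.approx(-result.incremental_cost)
    assert entry.incremental_effectiveness_low == pytest.approx(
        -result.incremental_effectiveness
    )


def test_invalid_range_fails_before_any_run(base_params, life_table):
    bad = ParameterRange("pet.specificity", 0.5, 0.9, 1.4)
    with pytest.raises(ParameterError):
        one_way_dsa(base_params, life_table, [bad])


def test_range_ordering_enforced():
    with pytest.raises(ValueError):
        ParameterRange("pet.specificity", 0.9, 0.8, 0.95)


def test_default_ranges_respect_validity(base_params):
    for r in default_ranges(base_params, rel=0.5):
        assert 0.0 <= r.low <= r.base <= r.high


def test_entries_sorted_by_cost_bar_width(base_params, life_table):
    ranges = default_ranges(base_params, rel=0.2)[:4]
    entries = one_way_dsa(base_params, life_table, ranges)
    widths = [e.cost_bar_width for e in entries]
    assert widths == sorted(widths, reverse=True)


def test_threshold_exists_for_pet_specificity(base_params, life_table):
    res = threshold_analysis(base_params, life_table, tol=1e-4, presample=20)
    assert res.crossed
    # below the root CT/MRI wins, above it PET wins
    lo = specificity_sweep(base_params, life_table, grid=np.array([res.value - 0.02]))
    hi = specificity_sweep(base_params, life_table, grid=np.array([res.value + 0.02]))
    assert lo["nmb_pet"][0] < lo["nmb_ctmri"][0]
    assert hi["nmb_pet"][0] > hi["nmb_ctmri"][0]


def test_no_crossing_when_pet_dominates_throughout(base_params, life_table):
    res = threshold_analysis(
        base_params, life_table, interval=(0.90, 0.99), presample=10
    )
    assert not res.crossed and res.value is None


def test_nmb_monotone_in_pet_specificity(base_params, life_table):
    sweep = specificity_sweep(
        base_params, life_table, grid=np.linspace(0.55, 0.95, 9)
    )
    assert np.all(np.diff(sweep["nmb_pet"]) > 0)
    # CT/MRI outcomes do not depend on PET accuracy
    assert np.allclose(np.diff(sweep["nmb_ctmri"]), 0.0, atol=1e-9)


def test_non_monotone_profile_reported(base_params, life_table, monkeypatch):
    import types

    import ipmncea.sensitivity as sens

    def fake_run_base_case(q, lt, variant=None):
        x = q.pet.specificity
        fake = types.SimpleNamespace(
            reference=types.SimpleNamespace(nmb=np.sin(20 * x)),
            comparator=types.SimpleNamespace(nmb=0.0),
        )
        return fake, None

    monkeypatch.setattr(sens, "run_base_case", fake_run_base_case)
    with pytest.raises(ValueError, match="monotone"):
        sens.threshold_analysis(base_params, life_table, presample=40)
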