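"""Published reference results for the base case.

These are the base-case outcomes reported by the source cost-effectiveness
study this package re-implements (15-year horizon, 3% discounting, WTP
$100,000/QALY).  They are used by the calibration harness to select the
default structural variant and by the deviation-report utility; they are
never used in the computation itself.
"""

from __future__ import annotations

REFERENCE_BASE_CASE: dict[str, float] = {
    "pet_cost": 104842.0,
    "ctmri_cost": 106424.0,
    "pet_effectiveness": 8.48,
    "ctmri_effectiveness": 8.37,
    "pet_nmb": 742697.0,
    "ctmri_nmb": 730272.0,
    "incremental_cost": 1581.0,
    "incremental_effectiveness": -0.11,
}

# Reported sensitivity/threshold results
REFERENCE_PET_SPECIFICITY_THRESHOLD = 0.715
REFERENCE_QALY_ADVANTAGE_AT_CTMRI_SP = {0.65: 0.18, 0.85: 0.06}

DEFAULT_TOLERANCES: dict[str, tuple[str, float]] = {
    "pet_cost": ("rel", 0.05),
    "ctmri_cost": ("rel", 0.05),
    "pet_effectiveness": ("abs", 0.15),
    "ctmri_effectiveness": ("abs", 0.15),
    "pet_nmb": ("rel", 0.05),
    "ctmri_nmb": ("rel", 0.05),
    "incremental_cost": ("abs", 1500.0),
    "incremental_effectiveness": ("abs", 0.05),
}
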