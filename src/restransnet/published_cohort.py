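"""Published cohort characteristics of the 93-patient HCC study.

The study's demographics table gives patient counts by cohort, PD-1 status,
and categorical characteristics; this module reconstructs a patient-level
roster from those counts so cohort arithmetic (positive fractions, sex
distributions) can be recomputed rather than quoted.
"""

from __future__ import annotations

import pandas as pd

# cohort -> PD-1 status -> (n patients, n male)
_COHORT_COUNTS = {
    "train": {1: {"n": 16, "male": 13}, 0: {"n": 59, "male": 54}},
    "test": {1: {"n": 9, "male": 8}, 0: {"n": 9, "male": 8}},
}


def patient_roster() -> pd.DataFrame:
    """Patient-level DataFrame with columns cohort, patient_id, label, sex."""
    rows = []
    k = 0
    for cohort, by_status in _COHORT_COUNTS.items():
        for label, info in by_status.items():
            for i in range(info["n"]):
                rows.append({
                    "cohort": cohort,
                    "patient_id": f"H{k:03d}",
                    "label": label,
                    "sex": "M" if i < info["male"] else "F",
                })
                k += 1
    return pd.DataFrame(rows)


def male_percentage(cohort: str, label: int) -> float:
    """Male percentage within a cohort/PD-1 stratum, from the roster."""
    roster = patient_roster()
    grp = roster[(roster.cohort == cohort) & (roster.label == label)]
    return round(100.0 * (grp.sex == "M").mean(), 2)
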