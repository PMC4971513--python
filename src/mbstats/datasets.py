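"""Built-in example datasets.

``breast_cohort_tables`` carries the printed patient-characteristics
contingency tables of a 28-subject aseptic breast-surgery cohort (15
invasive cancers vs 13 benign non-atypia lesions).  These are the worked
examples for the cohort statistics: chi-square for nominal variables,
Cochran-Armitage trend for ordinal ones.  Columns are ordered
(invasive cancer, benign).
"""

from __future__ import annotations

from .cohort import ContingencyTable

__all__ = ["breast_cohort_tables", "BREAST_COHORT_VARIABLE_KINDS"]

#: Which test each variable calls for.
BREAST_COHORT_VARIABLE_KINDS = {
    "menopausal_status": "nominal",
    "bmi_category": "ordinal",
    "smoking_status": "nominal",
    "diabetes": "nominal",
    "parity": "ordinal",
    "breastfed": "nominal",
    "family_history": "nominal",
    "nipple_distance": "ordinal",
}

_COLS = ("invasive_cancer", "benign_non_atypia")


def breast_cohort_tables() -> dict[str, ContingencyTable]:
    """Category x disease-state count tables for the example cohort."""
    t = {}
    t["menopausal_status"] = ContingencyTable.from_lists(
        ("pre", "peri", "post"), _COLS, [[2, 6], [0, 2], [13, 5]]
    )
    t["bmi_category"] = ContingencyTable.from_lists(
        ("18.5-24.9", "25-29.9", ">=30"), _COLS, [[4, 2], [8, 5], [3, 6]]
    )
    t["smoking_status"] = ContingencyTable.from_lists(
        ("former", "never"), _COLS, [[4, 6], [11, 7]]
    )
    t["diabetes"] = ContingencyTable.from_lists(
        ("no", "yes"), _COLS, [[13, 12], [2, 1]]
    )
    t["parity"] = ContingencyTable.from_lists(
        ("0", "1-3", ">3"), _COLS, [[2, 2], [10, 9], [3, 2]]
    )
    t["breastfed"] = ContingencyTable.from_lists(
        ("no", "yes"), _COLS, [[8, 4], [6, 3]]
    )
    t["family_history"] = ContingencyTable.from_lists(
        ("no", "yes"), _COLS, [[10, 7], [5, 6]]
    )
    t["nipple_distance"] = ContingencyTable.from_lists(
        ("<=2cm", "2-5cm", ">5cm"), _COLS, [[2, 2], [5, 6], [8, 5]]
    )
    return t
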