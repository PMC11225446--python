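"""Cohort schema: canonical column names, categorical code sets, codings.

The unit of analysis is one patient-visit row ("cohort record") of an HIV
cohort under antiretroviral therapy, carrying two outcomes — a CD4
T-lymphocyte count (cells/mm^3) and a binary tuberculosis screening result —
plus socio-demographic and clinical covariates.

Internal conventions
--------------------
* ``tb_status`` is stored as 0 = negative, 1 = positive, so that the logistic
  channel models Pr(TB positive).  Source files commonly code it 1 = negative,
  2 = positive; the schema map's ``tb_coding`` handles the recode on read.
* ``oi_status`` (opportunistic infection, i.e. an infectious disease other
  than HIV/TB) is stored as 0 = no, 1 = yes.  Source files use either a 0/1
  or a 1 = yes / 2 = no coding; ``oi_coding`` selects which.
* Missing values are empty CSV cells and ``NaN`` in memory.
"""

from __future__ import annotations

from typing import Mapping

#: canonical column order for the long-format cohort table
CANONICAL_COLUMNS = [
    "patient_id",
    "visit",
    "cd4_count",
    "tb_status",
    "gender",
    "age",
    "marital_status",
    "weight",
    "adherence",
    "who_stage",
    "functional_status",
    "hemoglobin",
    "baseline_cd4",
    "religion",
    "education",
    "occupation",
    "oi_status",
    "regimen",
]

#: admissible codes per categorical column (internal representation)
CATEGORICAL_LEVELS: Mapping[str, tuple[int, ...]] = {
    "gender": (0, 1),                      # 0=female, 1=male
    "marital_status": (1, 2, 3, 4),        # single/married/divorced/widowed
    "adherence": (1, 2, 3),                # good/fair/poor
    "who_stage": (1, 2, 3, 4),             # WHO clinical stage I-IV
    "functional_status": (1, 2, 3),        # working/ambulatory/bedridden
    "religion": (1, 2, 3, 4),
    "education": (0, 1, 2, 3),             # none/primary/secondary/tertiary
    "occupation": (0, 1, 2, 3, 4, 5, 6),
    "oi_status": (1, 0),                   # internal: 0=no, 1=yes; listed yes-first
                                           # so "no" is the (last) reference level
    "regimen": (0, 1, 2, 3, 4, 5),
    "tb_status": (0, 1),                   # internal: 0=negative, 1=positive
}

#: continuous (or count-valued) columns
CONTINUOUS_COLUMNS = ["age", "weight", "hemoglobin", "baseline_cd4", "cd4_count"]

OUTCOME_COLUMNS = ("cd4_count", "tb_status")

#: columns that are neither outcomes nor identifiers
COVARIATE_COLUMNS = [
    c for c in CANONICAL_COLUMNS if c not in ("patient_id", "visit") + OUTCOME_COLUMNS
]

MAX_VISITS = 10


def default_schema() -> dict:
    """Schema map for reading/writing CSV files.

    ``columns`` maps canonical names to CSV header names (identity by
    default). ``tb_coding`` is ``"12"`` (1=negative, 2=positive, the common
    chart coding) or ``"01"``.  ``oi_coding`` is ``"01"`` (0=no, 1=yes) or
    ``"12"`` (1=yes, 2=no).
    """
    return {
        "columns": {c: c for c in CANONICAL_COLUMNS},
        "tb_coding": "12",
        "oi_coding": "01",
    }
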