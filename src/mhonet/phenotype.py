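"""Metabolically-healthy-obesity (MHO) phenotype classification.

Obese subjects (BMI >= 30 kg/m^2) are split into metabolically healthy
(MHO) and metabolically abnormal (MAO) using one of three published
criterion sets of increasing stringency:

* Definition 1 — no hypertension (SBP <= 130 and DBP <= 85 mmHg, no
  blood-pressure medication), no diabetes (fasting glucose <= 126 mg/dl),
  HDL-C >= 40 mg/dl (men) / >= 50 mg/dl (women).
* Definition 2 — no hypertension, no pre-diabetes (glucose <= 100 mg/dl),
  HOMA-IR <= 5.1, TG/HDL <= 1.65 (men) / <= 1.32 (women).
* Definition 3 — Definition 2 plus an inflammation criterion,
  hsCRP <= 0.3 mg/dl.  This is the pipeline default.

All comparisons are inclusive and every criterion of the chosen
definition must be met.  Non-obese subjects are labelled NOT_OBESE and
never MHO/MAO.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MHO",
    "MAO",
    "NOT_OBESE",
    "REFERENCE_COHORT_SUMMARY",
    "PhenotypeLabel",
    "classify_mho",
    "classify_cohort",
    "tg_hdl_ratio",
    "group_summary",
]

MHO = "MHO"
MAO = "MAO"
NOT_OBESE = "NOT_OBESE"

#: Per-group clinical summary (arithmetic mean, SD) of the 29-subject
#: reference cohort (8 MHO vs 21 MAO African-American adults) that the
#: synthetic generator is calibrated to.  Fractions are counts/n.
REFERENCE_COHORT_SUMMARY: dict[str, dict] = {
    "MHO": {
        "n": 8,
        "bmi": (34.0, 6.0),
        "glucose": (87.0, 6.57),
        "hscrp": (0.13, 0.09),
        "homa_ir": (1.99, 1.49),
        "tg_hdl": (0.98, 0.27),
        "age": (41.88, 6.08),
        "female_frac": 3 / 8,
        "smoker_frac": 4 / 8,
        "drinker_frac": 3 / 8,
        "hypertensive_frac": 0 / 8,
    },
    "MAO": {
        "n": 21,
        "bmi": (37.0, 5.0),
        "glucose": (92.62, 9.59),
        "hscrp": (0.36, 0.21),
        "homa_ir": (4.21, 2.97),
        "tg_hdl": (2.25, 1.21),
        "age": (42.33, 5.97),
        "female_frac": 14 / 21,
        "smoker_frac": 10 / 21,
        "drinker_frac": 5 / 21,
        "hypertensive_frac": 13 / 21,
    },
}

_REQUIRED_FIELDS = {
    1: ["bmi", "sbp", "dbp", "bp_medication", "glucose", "hdl", "sex"],
    2: ["bmi", "sbp", "dbp", "bp_medication", "glucose", "homa_ir", "sex"],
    3: ["bmi", "sbp", "dbp", "bp_medication", "glucose", "homa_ir", "sex", "hscrp"],
}


@dataclass
class PhenotypeLabel:
    """Classification outcome with a per-criterion audit trail."""

    label: str
    definition: int
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def is_mho(self) -> bool:
        return self.label == MHO


def tg_hdl_ratio(tg: float, hdl: float) -> float:
    """Triglycerides / HDL-cholesterol ratio (insulin-resistance index)."""
    if hdl <= 0:
        raise ValueError(f"HDL must be positive, got {hdl!r}")
    return tg / hdl


def _get(record: Mapping, name: str):
    try:
        value = record[name]
    except (KeyError, IndexError) as exc:
        raise ValueError(f"clinical record is missing required field {name!r}") from exc
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"clinical record is missing required field {name!r}")
    return value


def _ratio_from_record(record: Mapping) -> float:
    # tg_hdl may be given directly or derived from tg and hdl
    try:
        ratio = record["tg_hdl"]
        if ratio is not None and not (isinstance(ratio, float) and math.isnan(ratio)):
            return float(ratio)
    except (KeyError, IndexError):
        pass
    return tg_hdl_ratio(float(_get(record, "tg")), float(_get(record, "hdl")))


def _is_female(record: Mapping) -> bool:
    sex = _get(record, "sex")
    if isinstance(sex, str):
        return sex.upper().startswith("F")
    return bool(sex)  # 1 = female by convention


def classify_mho(record: Mapping, definition: int = 3) -> PhenotypeLabel:
    """Classify one subject as MHO, MAO or NOT_OBESE.

    Parameters
    ----------
    record
        Mapping (dict, :class:`pandas.Series`) with the clinical fields the
        chosen definition requires; ``bmi`` in kg/m^2, pressures in mmHg,
        glucose/HDL/hsCRP in mg/dl.  Missing fields raise ``ValueError``
        rather than silently passing.
    definition
        1, 2 or 3 (default 3, the most comprehensive set, adding the
        hsCRP inflammation criterion).
    """
    if definition not in (1, 2, 3):
        raise ValueError(f"definition must be 1, 2 or 3, got {definition!r}")
    for name in _REQUIRED_FIELDS[definition]:
        _get(record, name)
    if definition in (2, 3):
        _ratio_from_record(record)

    bmi = float(_get(record, "bmi"))
    if bmi < 30:
        return PhenotypeLabel(NOT_OBESE, definition, {"obese": False})

    female = _is_female(record)
    criteria: dict[str, bool] = {"obese": True}
    criteria["no_hypertension"] = (
        float(_get(record, "sbp")) <= 130
        and float(_get(record, "dbp")) <= 85
        and not bool(_get(record, "bp_medication"))
    )
    glucose = float(_get(record, "glucose"))
    if definition == 1:
        criteria["no_diabetes"] = glucose <= 126
        hdl = float(_get(record, "hdl"))
        criteria["hdl_ok"] = hdl >= (50 if female else 40)
    else:
        criteria["no_prediabetes"] = glucose <= 100
        criteria["homa_ok"] = float(_get(record, "homa_ir")) <= 5.1
        ratio = _ratio_from_record(record)
        criteria["tg_hdl_ok"] = ratio <= (1.32 if female else 1.65)
        if definition == 3:
            criteria["crp_ok"] = float(_get(record, "hscrp")) <= 0.3

    label = MHO if all(criteria.values()) else MAO
    return PhenotypeLabel(label, definition, criteria)


def classify_cohort(clinical: pd.DataFrame, definition: int = 3) -> pd.DataFrame:
    """Classify every row of a clinical table.

    Returns a data frame indexed like ``clinical`` with a ``label``
    column plus one boolean column per criterion (audit trail).
    """
    rows = []
    for _, rec in clinical.iterrows():
        res = classify_mho(rec, definition=definition)
        rows.append({"label": res.label, **res.criteria})
    return pd.DataFrame(rows, index=clinical.index)


def group_summary(
    records: pd.DataFrame,
    labels,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean, SD (n-1), min, max and geometric mean per variable.

    The geometric mean exp(mean(ln x)) is reported for strictly positive
    variables; groups containing non-positive values get NaN there, with
    a warning.
    """
    labels = pd.Series(np.asarray(labels), index=records.index, name="group")
    if variables is None:
        variables = [c for c in records.columns if pd.api.types.is_numeric_dtype(records[c])]
    out = []
    for group, sub in records.groupby(labels):
        if len(sub) < 1:
            continue
        for var in variables:
            x = sub[var].astype(float).to_numpy()
            row = {
                "group": group,
                "variable": var,
                "n": len(x),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
            if np.all(x > 0):
                row["geometric_mean"] = float(np.exp(np.mean(np.log(x))))
            else:
                warnings.warn(
                    f"non-positive values in {var!r} for group {group!r}; "
                    "geometric mean omitted"
                )
                row["geometric_mean"] = float("nan")
            out.append(row)
    if not out:
        raise ValueError("no records to summarize")
    return pd.DataFrame(out).set_index(["group", "variable"])
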