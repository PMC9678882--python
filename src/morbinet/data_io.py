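"""Loading, filtering and describing cohort tables.

Input files are delimited text (CSV or TSV inferred from the extension)
with a header row naming every schema column; condition indicators are
coded 0/1. Obesity is derived from BMI (WHO cut-off, >= 30 kg/m^2) when the
file carries a ``bmi`` column but no ``obesity`` column.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from morbinet.schema import (
    Cohort,
    CohortValidationError,
    SchemaError,
    VariableSchema,
    canonical_schema,
)

logger = logging.getLogger(__name__)

OBESITY_BMI_CUTOFF = 30.0  # WHO: obese iff BMI >= 30 kg/m^2, boundary inclusive


def derive_obesity(bmi) -> Union[int, float, np.ndarray, pd.Series]:
    """Binary obesity indicator from BMI: 1 iff BMI >= 30.0 kg/m^2.

    Missing BMI propagates to missing obesity. Non-missing BMI must be
    positive.
    """
    arr = pd.Series(np.asarray(bmi, dtype=float).ravel())
    if ((arr <= 0) & arr.notna()).any():
        raise CohortValidationError("BMI must be positive")
    out = (arr >= OBESITY_BMI_CUTOFF).astype(float)
    out[arr.isna()] = np.nan
    if np.isscalar(bmi) or getattr(bmi, "ndim", 1) == 0:
        v = out.iloc[0]
        return float("nan") if np.isnan(v) else int(v)
    if isinstance(bmi, pd.Series):
        return pd.Series(out.to_numpy(), index=bmi.index)
    return out.to_numpy()


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, comment="#")


_COVARIATE_DTYPES = {
    "sex": "categorical",
    "age": "continuous",
    "social_class": "categorical",
    "bmi": "continuous",
}


def infer_schema(path) -> VariableSchema:
    """Infer a schema from a file header: known covariate names are typed
    as covariates, every other column as a binary condition."""
    from morbinet.schema import Variable

    table = _read_delimited(Path(path))
    variables = []
    slot = 0
    for name in table.columns:
        if name in _COVARIATE_DTYPES:
            variables.append(Variable(name, "covariate", _COVARIATE_DTYPES[name]))
        else:
            slot += 1
            variables.append(Variable(name, "condition", "binary", slot=slot))
    return VariableSchema(variables)


def load_cohort(
    path,
    schema: Optional[VariableSchema] = None,
    missing_policy: str = "listwise",
) -> Cohort:
    """Load a delimited cohort file against a schema.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row naming every schema column.
    schema : VariableSchema, optional
        Defaults to the canonical 32-slot survey schema.
    missing_policy : {"listwise", "as_zero"}
        How rows with missing condition values are handled. Listwise
        deletion drops the row (logged); ``as_zero`` recodes missing
        condition values to 0 with a warning. Sex-specific items are only
        required for rows of the matching sex.
    """
    if missing_policy not in ("listwise", "as_zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    schema = schema if schema is not None else canonical_schema()
    path = Path(path)
    table = _read_delimited(path)

    if "obesity" in schema.condition_names and "obesity" not in table.columns:
        if "bmi" in table.columns:
            table["obesity"] = derive_obesity(table["bmi"])
            logger.info("derived obesity from bmi (cut-off %.1f)", OBESITY_BMI_CUTOFF)

    missing_cols = [v.name for v in schema if v.name not in table.columns]
    if missing_cols:
        raise SchemaError(f"columns missing from {path.name}: {missing_cols}")
    table = table[[v.name for v in schema]]

    for name in schema.condition_names:
        col = table[name]
        bad = ~(col.isna() | col.isin((0, 1)))
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"condition {name!r} has non-binary value at row {idx}"
            )

    pair = schema.shared_slot_pair()
    required = dict.fromkeys(schema.condition_names, None)
    if pair is not None:
        male, female = pair
        sex = table["sex"].astype(str).str.lower()
        required[male.name] = sex.isin(("male", "m", "1"))
        required[female.name] = ~sex.isin(("male", "m", "1"))

    missing_mask = pd.Series(False, index=table.index)
    for name in schema.condition_names:
        isna = table[name].isna()
        applies = required[name]
        missing_mask |= isna if applies is None else (isna & applies)

    if missing_mask.any():
        if missing_policy == "listwise":
            logger.warning(
                "listwise deletion of %d rows with missing condition values",
                int(missing_mask.sum()),
            )
            table = table.loc[~missing_mask]
        else:
            logger.warning(
                "recoding missing condition values to 0 in %d rows",
                int(missing_mask.sum()),
            )
            table = table.copy()
            for name in schema.condition_names:
                applies = required[name]
                fill = table[name].isna() if applies is None else (
                    table[name].isna() & applies
                )
                table.loc[fill, name] = 0

    return Cohort(table.reset_index(drop=True), schema)


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort as delimited text that round-trips through load_cohort."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cohort.data.to_csv(path, sep=sep, index=False)
    return path


def apply_multimorbidity_filter(cohort: Cohort, min_conditions: int = 2) -> Cohort:
    """Retain respondents with at least ``min_conditions`` diagnosed conditions.

    Multimorbidity is operationally two or more concurrent chronic diseases;
    sex-specific slots count for the matching sex only.
    """
    if min_conditions < 1:
        raise ValueError("min_conditions must be >= 1")
    counts = cohort.condition_counts()
    kept = cohort.data.loc[(counts >= min_conditions).to_numpy()]
    if len(kept) == 0:
        raise CohortValidationError(
            f"no rows with >= {min_conditions} conditions remain"
        )
    return Cohort(kept.reset_index(drop=True), cohort.schema)


def prevalence_table(cohort: Cohort, by: Optional[str] = None) -> pd.DataFrame:
    """Per-condition prevalence (percent of applicable respondents).

    Sex-specific items use the matching-sex denominator. With ``by``, one
    row per (condition, stratum); empty strata yield missing percentages.
    """
    pair = cohort.schema.shared_slot_pair()
    sex_req = {}
    if pair is not None:
        male, female = pair
        sex = cohort.data["sex"].astype(str).str.lower()
        is_male = sex.isin(("male", "m", "1"))
        sex_req[male.name] = is_male
        sex_req[female.name] = ~is_male

    def _one(frame_index) -> pd.DataFrame:
        rows = []
        for v in cohort.schema:
            if v.role != "condition":
                continue
            mask = frame_index
            if v.name in sex_req:
                mask = mask & sex_req[v.name]
            col = cohort.data.loc[mask, v.name].dropna()
            n = len(col)
            pct = 100.0 * col.mean() if n > 0 else np.nan
            rows.append({"condition": v.name, "n": n, "percent": pct})
        return pd.DataFrame(rows)

    all_rows = pd.Series(True, index=cohort.data.index)
    if by is None:
        return _one(all_rows)
    if by not in cohort.data.columns:
        raise SchemaError(f"no covariate {by!r} to stratify by")
    frames = []
    for value in sorted(cohort.data[by].astype(str).unique()):
        mask = cohort.data[by].astype(str) == value
        tab = _one(mask)
        tab.insert(0, by, value)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def write_prevalence(table: pd.DataFrame, path) -> Path:
    """Write a prevalence table as TSV (condition, n, percent)."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
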