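"""Variable schema and cohort container for survey-style multimorbidity data.

A cohort is a person x variable table: ~32 binary chronic-condition
indicators (0 absence / 1 presence) plus covariates (age in years, sex,
occupation-based social class SC1-SC6, BMI). One positional slot may be
shared by a sex-specific pair (prostate problems for men / menopausal
problems for women); in pooled analyses that slot takes the sex-appropriate
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A column required by the schema is absent or misdeclared."""


class CohortValidationError(ValueError):
    """A cohort value violates the schema (e.g. non-binary condition)."""


@dataclass(frozen=True)
class Variable:
    """One column of the cohort table.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    role : {"condition", "covariate"}
    dtype : {"binary", "continuous", "categorical"}
        Condition variables must be binary.
    sex_specific : {"male", "female", None}
        Set for items asked of one sex only.
    slot : int, optional
        Positional index used in network outputs. Exactly one sex-specific
        pair may share a slot.
    """

    name: str
    role: str
    dtype: str = "binary"
    sex_specific: Optional[str] = None
    slot: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ("condition", "covariate"):
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.dtype not in ("binary", "continuous", "categorical"):
            raise SchemaError(f"unknown dtype {self.dtype!r} for {self.name!r}")
        if self.role == "condition" and self.dtype != "binary":
            raise SchemaError(f"condition {self.name!r} must be binary")
        if self.sex_specific not in (None, "male", "female"):
            raise SchemaError(f"bad sex_specific {self.sex_specific!r}")


class VariableSchema:
    """An ordered collection of :class:`Variable` with integrity checks."""

    def __init__(self, variables: Iterable[Variable]):
        self.variables = list(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dup = {n for n in names if names.count(n) > 1}
            raise SchemaError(f"duplicate variable names: {sorted(dup)}")
        shared: dict[int, list[Variable]] = {}
        for v in self.variables:
            if v.role == "condition" and v.slot is not None:
                shared.setdefault(v.slot, []).append(v)
        pairs = {s: vs for s, vs in shared.items() if len(vs) > 1}
        for s, vs in pairs.items():
            sexes = {v.sex_specific for v in vs}
            if len(vs) != 2 or sexes != {"male", "female"}:
                raise SchemaError(
                    f"slot {s} shared by {[v.name for v in vs]}; only one "
                    "male/female pair may share a slot"
                )
        if len(pairs) > 1:
            raise SchemaError("at most one sex-specific slot pair is allowed")
        self._shared_slot = next(iter(pairs)) if pairs else None

    def __iter__(self) -> Iterator[Variable]:
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def condition_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "condition"]

    @property
    def covariate_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "covariate"]

    @property
    def shared_slot(self) -> Optional[int]:
        """Slot index shared by the sex-specific pair, or None."""
        return self._shared_slot

    def shared_slot_pair(self) -> Optional[tuple[Variable, Variable]]:
        """(male variable, female variable) sharing a slot, or None."""
        if self._shared_slot is None:
            return None
        vs = [
            v
            for v in self.variables
            if v.role == "condition" and v.slot == self._shared_slot
        ]
        male = next(v for v in vs if v.sex_specific == "male")
        female = next(v for v in vs if v.sex_specific == "female")
        return male, female


# Canonical 32-slot condition list of the Spanish European Health Survey
# analysis: slot 30 is the prostate/menopausal sex-specific pair and slot 32
# is obesity derived from BMI.
_CANONICAL_CONDITIONS = [
    (1, "hypertension"),
    (2, "infarction"),
    (3, "coronary_disease"),
    (4, "other_heart"),
    (5, "varicose_veins"),
    (6, "arthrosis"),
    (7, "lumbar_pain"),
    (8, "cervical_pain"),
    (9, "allergy"),
    (10, "asthma"),
    (11, "respiratory_disease"),
    (12, "diabetes"),
    (13, "stomach_ulcer"),
    (14, "urinary_incontinence"),
    (15, "cholesterol"),
    (16, "cataracts"),
    (17, "skin_condition"),
    (18, "constipation"),
    (19, "hepatic_dysfunction"),
    (20, "depression"),
    (21, "anxiety"),
    (22, "other_mental"),
    (23, "stroke"),
    (24, "migraine"),
    (25, "haemorrhoids"),
    (26, "cancer"),
    (27, "osteoporosis"),
    (28, "thyroid_disease"),
    (29, "kidney_disease"),
    (31, "accidents"),
    (32, "obesity"),
]


def canonical_schema(include_bmi: bool = True) -> VariableSchema:
    """The canonical survey schema: 32 condition slots plus covariates.

    Slot 30 holds the sex-specific pair (``prostate_problems`` for men,
    ``menopausal_problems`` for women). Obesity (slot 32) is a condition
    column; when absent from a file it is derived from BMI at load time.
    """
    conditions = [
        Variable(name, "condition", "binary", slot=slot)
        for slot, name in _CANONICAL_CONDITIONS
    ]
    conditions.append(
        Variable("prostate_problems", "condition", "binary", "male", slot=30)
    )
    conditions.append(
        Variable("menopausal_problems", "condition", "binary", "female", slot=30)
    )
    conditions.sort(key=lambda v: (v.slot, v.name))
    covariates = [
        Variable("sex", "covariate", "categorical"),
        Variable("age", "covariate", "continuous"),
        Variable("social_class", "covariate", "categorical"),
    ]
    if include_bmi:
        covariates.append(Variable("bmi", "covariate", "continuous"))
    return VariableSchema(conditions + covariates)


def generic_schema(p: int, covariates: bool = True) -> VariableSchema:
    """Schema for synthetic cohorts: conditions ``c01..cP`` plus covariates."""
    width = max(2, len(str(p)))
    conds = [
        Variable(f"c{i + 1:0{width}d}", "condition", "binary", slot=i + 1)
        for i in range(p)
    ]
    covs = (
        [
            Variable("sex", "covariate", "categorical"),
            Variable("age", "covariate", "continuous"),
            Variable("social_class", "covariate", "categorical"),
        ]
        if covariates
        else []
    )
    return VariableSchema(conds + covs)


@dataclass
class Cohort:
    """A validated person x variable table plus its schema."""

    data: pd.DataFrame
    schema: VariableSchema = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise CohortValidationError("cohort has no rows")
        missing = [v.name for v in self.schema if v.name not in self.data.columns]
        if missing:
            raise SchemaError(f"columns missing from table: {missing}")
        for name in self.schema.condition_names:
            col = self.data[name]
            bad = ~(col.isna() | col.isin((0, 1)))
            if bad.any():
                idx = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"condition {name!r} has non-binary value at row {idx}"
                )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        """Number of analysis nodes (shared sex-specific pair counts once)."""
        p = len(self.schema.condition_names)
        return p - 1 if self.schema.shared_slot is not None else p

    def analysis_matrix(self) -> pd.DataFrame:
        """Condition indicators as network nodes, one column per slot.

        The sex-specific pair is merged into a single ``prostate_menopausal``
        column holding the sex-appropriate value for each row.
        """
        pair = self.schema.shared_slot_pair()
        cols = {}
        merged_done = False
        for v in self.schema:
            if v.role != "condition":
                continue
            if pair is not None and v in pair:
                if merged_done:
                    continue
                male, female = pair
                sex = self.data["sex"].astype(str)
                merged = np.where(
                    sex.str.lower().isin(("male", "m", "1")),
                    self.data[male.name],
                    self.data[female.name],
                )
                cols["prostate_menopausal"] = merged
                merged_done = True
            else:
                cols[v.name] = self.data[v.name].to_numpy()
        out = pd.DataFrame(cols, index=self.data.index)
        return out.fillna(0).astype(np.int8)

    def condition_counts(self) -> pd.Series:
        """Per-row count of diagnosed conditions.

        Sex-specific items count only for rows of the matching sex (the
        analysis matrix already holds the sex-appropriate slot value).
        """
        return self.analysis_matrix().sum(axis=1)

    def stratify(self, by: str) -> dict[str, "Cohort"]:
        """Split into sub-cohorts by a covariate value (e.g. sex)."""
        if by not in self.data.columns:
            raise SchemaError(f"no covariate {by!r} to stratify by")
        out = {}
        for value, frame in self.data.groupby(by, sort=True, observed=True):
            out[str(value)] = Cohort(frame.reset_index(drop=True), self.schema)
        return out
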