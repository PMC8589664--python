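"""Cohort tables: the tabular container every analysis stage consumes.

A cohort is one row per patient with the 30 PANSS item scores (P1..P7,
N1..N7, G1..G16, integers 1-7), demographics (age, sex), functional
outcomes (GAF, SOFAS, working, living independently, symptomatic
remission, diagnosis) and an optional metabolite panel.  PANSS items must
be complete for every patient entering stratification; everything else may
be missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANSS_ITEMS: tuple[str, ...] = tuple(
    [f"P{i}" for i in range(1, 8)]
    + [f"N{i}" for i in range(1, 8)]
    + [f"G{i}" for i in range(1, 17)]
)

OUTCOME_CONTINUOUS = ("gaf", "sofas")
OUTCOME_BINARY = ("working", "living_independently", "remission")
OUTCOME_CATEGORICAL = ("diagnosis",)

_CORE_COLUMNS = ("patient_id", *PANSS_ITEMS, "age", "sex")
_KNOWN_COLUMNS = set(_CORE_COLUMNS) | set(OUTCOME_CONTINUOUS) | set(OUTCOME_BINARY) | set(OUTCOME_CATEGORICAL)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema invariants."""


@dataclass
class Cohort:
    """Validated cohort table.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per patient.  Must contain ``patient_id``, the 30 PANSS
        columns, ``age`` and ``sex``; outcome and metabolite columns are
        optional and may contain missing values.
    """

    df: pd.DataFrame
    metabolite_columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate(self.df)
        if not self.metabolite_columns:
            extra = [c for c in self.df.columns if c not in _KNOWN_COLUMNS]
            self.metabolite_columns = tuple(extra)

    # -- accessors -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].to_numpy()

    @property
    def panss(self) -> np.ndarray:
        """n x 30 integer matrix of PANSS item scores."""
        return self.df[list(PANSS_ITEMS)].to_numpy(dtype=float)

    @property
    def panss_df(self) -> pd.DataFrame:
        return self.df[list(PANSS_ITEMS)]

    def metabolites(self) -> pd.DataFrame:
        return self.df[list(self.metabolite_columns)]

    def __len__(self) -> int:
        return self.n


def _validate(df: pd.DataFrame) -> None:
    missing_cols = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing required columns: {missing_cols}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortValidationError(f"duplicate patient_id values: {dupes}")

    violations = []
    panss = df[list(PANSS_ITEMS)]
    for item in PANSS_ITEMS:
        col = panss[item]
        if col.isna().any():
            for row in df.index[col.isna()]:
                violations.append((df.at[row, "patient_id"], item, "missing"))
            continue
        vals = col.to_numpy()
        bad = (vals != np.round(vals)) | (vals < 1) | (vals > 7)
        for row in df.index[bad]:
            violations.append((df.at[row, "patient_id"], item, col[row]))
    if violations:
        detail = "; ".join(f"patient {p}, item {i}: {v}" for p, i, v in violations[:10])
        raise CohortValidationError(
            f"{len(violations)} PANSS violations (scores must be integers in [1,7]): {detail}"
        )

    sexes = df["sex"].dropna().unique()
    bad_sex = [s for s in sexes if s not in ("male", "female")]
    if bad_sex:
        raise CohortValidationError(f"sex values must be 'male'/'female', got {bad_sex}")
    if (df["age"].dropna() <= 0).any():
        raise CohortValidationError("age must be positive")
    for col in ("gaf", "sofas"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise CohortValidationError(f"{col} must lie in [0, 100]")


def sex_indicator(sex: pd.Series) -> np.ndarray:
    """0/1 indicator used in adjusted models (female = 1)."""
    return (sex == "female").astype(float).to_numpy()
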