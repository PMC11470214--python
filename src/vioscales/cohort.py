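"""Cohort container and column conventions.

A cohort is one consultation per row: demographics, circumstances of the
assault, physical-trauma findings, patient-reported symptom flags, the nine
7-level (0-6) Likert scales, the physician identifier and the certified days
of total incapacity to work (TIW).  A ``feature_spec`` maps every variable
used for clustering to its type (``binary`` or ``numeric``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: The nine 0-6 Likert instruments, in reporting order: six self-rated
#: (pain / fear / perceived life threat, each at assault time and at
#: consultation time) and three physician-rated (global functional
#: impairment, quality of the patient-physician interaction, and the
#: psychosomatic index attributing impairment to psychological vs physical
#: trauma).
SCALE_COLUMNS = [
    "pain_assault",
    "pain_consultation",
    "fear_assault",
    "fear_consultation",
    "life_threat_assault",
    "life_threat_consultation",
    "functional_impairment",
    "interaction_quality",
    "psychosomatic_index",
]

#: Patient-reported psychological-trauma symptom concepts; cohort columns
#: are prefixed with ``symptom_``.
SYMPTOM_CONCEPTS = ["sleep_disorder", "loss_of_appetite", "stress_symptoms", "pain", "fear"]

SYMPTOM_COLUMNS = [f"symptom_{c}" for c in SYMPTOM_CONCEPTS]

#: Numeric clustering variables.
NUMERIC_FEATURES = ["age", "delay_hours"]

SCALE_MIN = 0
SCALE_MAX = 6


@dataclass
class Cohort:
    """An ordered collection of patient consultations.

    Parameters
    ----------
    df:
        One row per patient.  Must contain ``patient_id`` (unique) and
        ``physician_id``; scale columns use pandas' nullable ``Int64`` so
        missing scores survive CSV round-trips as empty fields.
    feature_spec:
        Mapping of clustering variable name to ``"binary"`` or ``"numeric"``.
    """

    df: pd.DataFrame
    feature_spec: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "patient_id" not in self.df.columns:
            raise ValueError("cohort frame must contain a 'patient_id' column")
        if self.df["patient_id"].duplicated().any():
            dup = self.df.loc[self.df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValueError(f"duplicate patient_id: {dup!r}")
        missing = [v for v in self.feature_spec if v not in self.df.columns]
        if missing:
            raise ValueError(f"feature_spec names absent from the cohort: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def clustering_features(self) -> list[str]:
        return list(self.feature_spec)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), dict(self.feature_spec))

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort as UTF-8 CSV; missing values become empty fields."""
        self.df.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path, feature_spec: dict[str, str] | None = None) -> "Cohort":
        df = pd.read_csv(path, encoding="utf-8")
        for col in SCALE_COLUMNS + ["tiw_days"]:
            if col in df.columns:
                df[col] = df[col].astype("Int64")
        if feature_spec is None:
            feature_spec = infer_feature_spec(df)
        return cls(df, feature_spec)


#: Columns never used as clustering variables even when present.
_NON_CLUSTERING = set(
    SCALE_COLUMNS
    + SYMPTOM_COLUMNS
    + [
        "patient_id",
        "physician_id",
        "true_profile",
        "profile",
        "tiw_days",
        "certificate_text",
        "second_evaluation",
        "intentional",
    ]
)


def infer_feature_spec(df: pd.DataFrame, include_tiw: bool = False) -> dict[str, str]:
    """Build a feature spec from column conventions.

    Numeric variables are ``age`` and ``delay_hours``; every other
    non-reserved column whose values are 0/1 (or boolean) is binary.  Scales,
    symptom flags and TIW are excluded by default: scales are evaluated
    *against* the typology, so letting them shape it would be circular.  Set
    ``include_tiw`` to add the TIW outcome as a numeric clustering variable.
    """
    spec: dict[str, str] = {}
    for col in df.columns:
        if col in _NON_CLUSTERING:
            continue
        if col in NUMERIC_FEATURES:
            spec[col] = "numeric"
            continue
        vals = df[col].dropna().unique()
        if len(vals) and set(vals) <= {0, 1, True, False}:
            spec[col] = "binary"
    if include_tiw and "tiw_days" in df.columns:
        spec["tiw_days"] = "numeric"
    return spec
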