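"""Cohort table schema: the 18 survey variables plus the binary delay outcome.

The outcome ``delay`` encodes healthcare-seeking delay — an interval longer
than 14 days between symptom onset and first professional medical contact.
Distances are kilometres; quality ratings are 0-10 self-reported scores; all
categorical variables are binary (1 = yes / the first listed level).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CONTINUOUS_VARIABLES = (
    "age",
    "dist_village",
    "dist_township",
    "dist_county",
    "township_quality",
    "county_quality",
)

BINARY_VARIABLES = (
    "gender",  # 1 = male
    "education",  # 1 = above primary school
    "occupation",  # 1 = farming
    "chinese_communication",  # 1 = able to communicate in Chinese
    "financial_difficulty",
    "chronic_disease",
    "symptom_severity",
    "musculoskeletal",
    "cardiopulmonary",
    "gastrointestinal",
    "neurological",
    "other_symptoms",
)

FEATURE_COLUMNS = CONTINUOUS_VARIABLES + BINARY_VARIABLES
OUTCOME = "delay"
ALL_COLUMNS = FEATURE_COLUMNS + (OUTCOME,)

VARIABLE_KINDS = {v: "continuous" for v in CONTINUOUS_VARIABLES}
VARIABLE_KINDS.update({v: "binary" for v in BINARY_VARIABLES})

# bounds used for validation of generated / user-entered data
VALUE_RANGES = {
    "age": (25.0, 72.0),
    "dist_village": (0.0, None),
    "dist_township": (0.0, None),
    "dist_county": (0.0, None),
    "township_quality": (0.0, 10.0),
    "county_quality": (0.0, 10.0),
}


def validate_cohort(table: pd.DataFrame, require_outcome: bool = True) -> None:
    """Raise ``ValueError`` if the table does not follow the cohort schema."""
    needed = ALL_COLUMNS if require_outcome else FEATURE_COLUMNS
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if require_outcome and len(table):
        vals = set(table[OUTCOME].dropna().unique())
        if not vals <= {0, 1}:
            raise ValueError(f"outcome column must be 0/1, found {sorted(vals)}")


def read_cohort(path: str | Path, require_outcome: bool = True) -> pd.DataFrame:
    """Read a cohort CSV and validate it against the schema."""
    table = pd.read_csv(path)
    validate_cohort(table, require_outcome=require_outcome)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(table, require_outcome=OUTCOME in table.columns)
    table.to_csv(path, index=False)


def write_schema_file(path: str | Path) -> None:
    """Write the machine-readable schema description (JSON)."""
    import json

    spec = {
        "outcome": OUTCOME,
        "variables": {
            name: {
                "kind": VARIABLE_KINDS[name],
                "range": VALUE_RANGES.get(name),
            }
            for name in FEATURE_COLUMNS
        },
    }
    Path(path).write_text(json.dumps(spec, indent=2))
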