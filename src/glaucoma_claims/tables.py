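"""Reading and writing the pipeline's delimited tables.

Every table the pipeline writes starts with a ``# schema:`` comment line so
downstream stages (and humans) can tell what they are reading; readers skip
comment lines, so the files stay plain CSV for pandas/R/Excel.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMA_VERSION = 1

#: Column layouts of the five input tables plus the generator's coverage
#: (observability) table. Dates are ISO-8601 strings on disk.
SCHEMAS: dict[str, list[str]] = {
    "pharmacy": ["patient_id", "dispense_date", "product_code", "quantity_ml", "period_field"],
    "diagnosis": ["patient_id", "diagnosis_date", "icd10_code"],
    "procedure": ["patient_id", "procedure_date", "category"],
    "checkup": ["patient_id", "checkup_date"],  # plus covariate columns
    "coverage": ["patient_id", "obs_start", "obs_end"],
}

_DATE_COLUMNS = {
    "dispense_date", "diagnosis_date", "procedure_date", "checkup_date",
    "obs_start", "obs_end", "index_date", "second_line_start", "surgery_date",
}


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write ``df`` as CSV with a schema-version header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: glaucoma-claims/{schema} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping comment lines and parsing date columns."""
    df = pd.read_csv(path, comment="#")
    for col in df.columns:
        if col in _DATE_COLUMNS:
            df[col] = pd.to_datetime(df[col])
    return df
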