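"""Readers and writers for the tabular record dialect and the run config.

The record dialect is tab-separated text with an explicit header line and a
second ``#units`` line; values never contain tabs or semicolons, so files
diff cleanly.  Mandatory columns:

    record_id genotype day protocol_tag Ca Ci A gs_h2o PPFD Tleaf Fs
    Fm_prime RWC O2_condition

Extra columns pass through untouched.  Validation reports offending rows
with line numbers; invalid rows are excluded only when ``lenient=True`` is
requested, otherwise reading fails.

The run configuration is plain ``key = value`` text; values are coerced to
int/float/bool where they parse as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = [
    "record_id", "genotype", "day", "protocol_tag", "Ca", "Ci", "A",
    "gs_h2o", "PPFD", "Tleaf", "Fs", "Fm_prime", "RWC", "O2_condition",
]

NUMERIC_COLUMNS = ["day", "Ca", "Ci", "A", "gs_h2o", "PPFD", "Tleaf",
                   "Fs", "Fm_prime", "RWC"]

UNITS = {
    "record_id": "-", "genotype": "-", "day": "d", "protocol_tag": "-",
    "Ca": "umol/mol", "Ci": "umol/mol", "A": "umol/m2/s",
    "gs_h2o": "mol_H2O/m2/s", "PPFD": "umol/m2/s", "Tleaf": "degC",
    "Fs": "a.u.", "Fm_prime": "a.u.", "RWC": "%", "O2_condition": "-",
}

#: fixed float formatting keeps re-runs byte-identical
FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    pass


class RecordValidationError(ValueError):
    def __init__(self, problems):
        self.problems = problems
        super().__init__(
            "invalid records:\n" + "\n".join(problems[:20])
            + ("" if len(problems) <= 20 else f"\n... {len(problems)} total"))


@dataclass
class ValidationReport:
    n_rows: int
    n_flagged: int
    problems: list


def write_records(df: pd.DataFrame, path) -> None:
    """Write a record table in the dialect (header + units row + data)."""
    path = Path(path)
    cols = [c for c in MANDATORY_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in MANDATORY_COLUMNS]
    units = "\t".join("#units" if i == 0 else UNITS.get(c, "-")
                      for i, c in enumerate(["_"] + cols[1:]))
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write(units + "\n")
        df[cols].to_csv(fh, sep="\t", index=False, header=False,
                        float_format=FLOAT_FORMAT, lineterminator="\n")


def read_records(path, lenient: bool = False):
    """Read and validate a record table.

    Returns ``(records, report)``.  Physically impossible rows (Fm' < Fs,
    non-positive fluorescence, negative conductance) are listed in the
    report with their line numbers; with ``lenient=True`` they are dropped,
    otherwise any flagged row raises :class:`RecordValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", skiprows=[1], dtype=str,
                     keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    problems = []
    for col in NUMERIC_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        for idx in df.index[bad]:
            problems.append(
                f"line {idx + 3}: non-numeric {col}={df.loc[idx, col]!r}")
        df[col] = converted
    df["day"] = df["day"].astype("Int64")

    flagged = pd.Series(False, index=df.index)
    checks = [
        (df["Fm_prime"] < df["Fs"], "Fm' < Fs (saturating-pulse failure)"),
        (df["Fs"] <= 0, "non-positive Fs"),
        (df["gs_h2o"] < 0, "negative gs"),
        (df["PPFD"] < 0, "negative PPFD"),
    ]
    for mask, msg in checks:
        mask = mask.fillna(False)
        for idx in df.index[mask]:
            problems.append(f"line {idx + 3}: {msg}")
        flagged |= mask
    for col in NUMERIC_COLUMNS:
        flagged |= df[col].isna()

    report = ValidationReport(n_rows=len(df), n_flagged=int(flagged.sum()),
                              problems=problems)
    if report.n_flagged and not lenient:
        raise RecordValidationError(problems)
    df = df[~flagged].reset_index(drop=True)
    df["day"] = df["day"].astype(int)
    for col in ("Ca", "Ci", "A", "gs_h2o", "PPFD", "Tleaf", "Fs",
                "Fm_prime", "RWC"):
        df[col] = df[col].astype(float)
    return df, report


def write_table(df: pd.DataFrame, path) -> None:
    """Plain TSV writer with the package's fixed float format."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_config(path) -> dict:
    """Parse a plain-text ``key = value`` configuration file."""
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = _coerce(value)
    return out


def _coerce(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if "," in value:
        return tuple(_coerce(v.strip()) for v in value.split(","))
    return value
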