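"""Long-format periodontal chart model: schema, validation, CSV round-trip.

A chart table holds one row per patient x tooth x site with baseline (T0)
and reevaluation (T1) measurements plus patient- and tooth-level covariates.
Probing depths and recession are whole millimetres (clinical probes read in
1 mm steps); missing values are explicit nulls end-to-end — nothing is
defaulted at parse time, the imputation module is the only place a null is
ever filled.

Chart CSV dialect: comma-separated, UTF-8, header row, empty cell = missing,
booleans serialized as ``true``/``false``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import InvalidFDIError, parse_fdi

__all__ = [
    "SITES",
    "INTERPROXIMAL_SITES",
    "CHART_COLUMNS",
    "PerioDataset",
    "ValidationReport",
    "SchemaError",
    "validate_dataset",
    "read_chart_csv",
    "write_chart_csv",
]

#: The six probing sites per tooth. Mesial/distal positions are the
#: interproximal ("interdental") sites used for staging CAL maxima and
#: root-length lookup.
SITES = (
    "mesiobuccal",
    "buccal",
    "distobuccal",
    "mesiooral",
    "oral",
    "distooral",
)
INTERPROXIMAL_SITES = frozenset(
    {"mesiobuccal", "distobuccal", "mesiooral", "distooral"}
)

# column -> pandas nullable dtype
CHART_COLUMNS: dict[str, str] = {
    "patient_id": "string",
    "fdi": "Int64",
    "site": "string",
    "ppd_t0": "Int64",
    "ppd_t1": "Int64",
    "recession_t0": "Int64",
    "bop_t0": "boolean",
    "bop_t1": "boolean",
    "plaque_t0": "boolean",
    "furcation_t0": "Int64",
    "mobility": "Int64",
    "restoration": "boolean",
    "vitality": "boolean",
    "percussion": "boolean",
    "cold_sensitivity": "boolean",
    "age": "Int64",
    "sex": "string",
    "bmi": "Float64",
    "antibiotics": "boolean",
    "family_history": "boolean",
    "ortho_history": "boolean",
    "diabetes": "boolean",
    "stress": "Int64",
    "smoking_type": "string",
    "cigarettes_per_day": "Int64",
}

MANDATORY_COLUMNS = ("patient_id", "fdi", "site", "ppd_t0")

_KEY = ["patient_id", "fdi", "site"]
_NONNEG_INT = ("ppd_t0", "ppd_t1", "recession_t0", "cigarettes_per_day", "age")
_ORDINAL_RANGE = {"furcation_t0": (0, 3), "mobility": (0, 3), "stress": (1, 10)}


class SchemaError(ValueError):
    """Raised when a chart table lacks mandatory columns."""


@dataclass
class ValidationReport:
    n_input_rows: int = 0
    n_accepted: int = 0
    missing_counts: dict[str, int] = field(default_factory=dict)
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class PerioDataset:
    """Validated long table of tooth-site records grouped by patient."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patients(self) -> list:
        return list(self.records["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return self.records["patient_id"].nunique()

    def teeth_present(self, patient_id) -> set[int]:
        mask = self.records["patient_id"] == patient_id
        return set(self.records.loc[mask, "fdi"].astype(int).unique())

    def for_patient(self, patient_id) -> pd.DataFrame:
        return self.records[self.records["patient_id"] == patient_id]

    def equals(self, other: "PerioDataset") -> bool:
        a = self.records.sort_values(_KEY).reset_index(drop=True)
        b = other.records.sort_values(_KEY).reset_index(drop=True)
        return a.equals(b)

    def copy(self) -> "PerioDataset":
        return PerioDataset(self.records.copy(), dict(self.provenance))


def _coerce_schema(table: pd.DataFrame) -> pd.DataFrame:
    """Coerce columns to the nullable chart dtypes; add absent optional
    columns as all-null. Uncoercible cells become null (caught later as
    rejects only for mandatory fields)."""
    out = pd.DataFrame(index=table.index)
    for col, dtype in CHART_COLUMNS.items():
        if col in table.columns:
            s = table[col]
            if dtype == "boolean" and s.dtype == object:
                s = s.map(
                    {"true": True, "false": False, True: True, False: False,
                     "True": True, "False": False, 1: True, 0: False},
                    na_action="ignore",
                )
            if dtype == "Int64":
                num = pd.to_numeric(s, errors="coerce")
                # reject-not-round: non-integers become null here, flagged below
                frac = num.astype(float) % 1
                num = num.where((frac == 0) | num.isna())
                s = num.astype("Int64")
            out[col] = s.astype(dtype)  # type: ignore[call-overload]
        else:
            out[col] = pd.Series(pd.NA, index=table.index, dtype=dtype)  # type: ignore[arg-type]
    return out


def validate_dataset(
    raw_table: pd.DataFrame, provenance: dict | None = None
) -> tuple[PerioDataset, ValidationReport]:
    """Validate a raw chart table into a :class:`PerioDataset`.

    Every rejected row is kept in the report with a reason; nothing is
    silently dropped. Unknown columns are ignored with a warning.
    """
    report = ValidationReport(n_input_rows=len(raw_table))
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw_table.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    extra = [c for c in raw_table.columns if c not in CHART_COLUMNS]
    if extra:
        report.warnings.append(f"ignored unknown columns: {extra}")

    table = _coerce_schema(raw_table)
    reasons = pd.Series("", index=table.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        mask = mask.fillna(False).astype(bool)
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    for col in ("patient_id", "fdi", "site", "ppd_t0"):
        # uncoercible mandatory cells (e.g. non-integer ppd) land here too
        flag(table[col].isna(), f"missing mandatory field '{col}'")

    valid_fdi = table["fdi"].map(
        lambda v: not pd.isna(v) and _is_valid_fdi(int(v))
    )
    flag(~valid_fdi & table["fdi"].notna(), "invalid FDI tooth number")
    flag(~table["site"].isin(SITES) & table["site"].notna(), "unknown site name")
    for col in _NONNEG_INT:
        flag(table[col] < 0, "negative measurement")
    for col, (lo, hi) in _ORDINAL_RANGE.items():
        flag((table[col] < lo) | (table[col] > hi), f"{col} out of range")
    flag(table.duplicated(subset=_KEY, keep="first"), "duplicate key")

    ok = reasons == ""
    accepted = table[ok].reset_index(drop=True)
    rejected = table[~ok].copy()
    rejected["reject_reason"] = reasons[~ok]
    report.rejected = rejected.reset_index(drop=True)
    report.n_accepted = len(accepted)
    report.missing_counts = {
        c: int(accepted[c].isna().sum()) for c in CHART_COLUMNS
    }

    incomplete = (
        accepted.groupby(["patient_id", "fdi"], observed=True)["site"]
        .nunique()
        .lt(len(SITES))
        .sum()
    )
    if incomplete:
        report.warnings.append(f"{int(incomplete)} teeth charted at <6 sites")
    over = accepted.groupby("patient_id", observed=True)["fdi"].nunique().gt(32)
    if over.any():
        report.warnings.append(f"{int(over.sum())} patients list >32 teeth")

    return PerioDataset(accepted, provenance or {}), report


def _is_valid_fdi(fdi: int) -> bool:
    try:
        parse_fdi(fdi)
        return True
    except InvalidFDIError:
        return False


def write_chart_csv(dataset: PerioDataset, path) -> None:
    """Write a chart CSV (empty cell = missing, booleans as true/false)."""
    df = dataset.records.copy()
    for col, dtype in CHART_COLUMNS.items():
        if dtype == "boolean":
            df[col] = df[col].map({True: "true", False: "false"}, na_action="ignore")
    df.to_csv(path, index=False, na_rep="")


def read_chart_csv(path) -> tuple[PerioDataset, ValidationReport]:
    """Read and validate a chart CSV; returns dataset + validation report."""
    try:
        raw = pd.read_csv(path, dtype=object, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read chart CSV {path!r}: {exc}") from exc
    raw = raw.replace({"": None}).replace({np.nan: None})
    return validate_dataset(raw, provenance={"source": str(path)})


def chart_csv_string(dataset: PerioDataset) -> str:
    buf = io.StringIO()
    write_chart_csv(dataset, buf)
    return buf.getvalue()
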