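"""Clinically motivated per-field imputation of periodontal charts.

Each field has its own rule chosen by the clinical likelihood of
non-notation: signs a clinician records only when present (bleeding on
probing, percussion sensitivity, restorations, recession, mobility,
smoking, diabetes, antibiotic use, family or orthodontic history) are
imputed as non-occurrence; vitality and cold sensitivity, which default to
a normal response, are imputed as positive. Stress is filled with the
patient-level median, BMI with the patient-level mean. Furcation and
plaque have dedicated structural rules (see :func:`impute_furcation` and
the donor-based plaque vote).

Every imputed cell carries a provenance tag in the report so audits can
separate observed from imputed data; observed values are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .anatomy import parse_fdi
from .chart import CHART_COLUMNS, PerioDataset

__all__ = [
    "ImputationReport",
    "ClinicalImputer",
    "impute_dataset",
    "impute_furcation",
    "impute_plaque",
]

#: null -> non-occurrence (False / 0 mm / "none" / 0 per day)
_NON_OCCURRENCE: dict[str, object] = {
    "bop_t0": False,
    "bop_t1": False,
    "percussion": False,
    "restoration": False,
    "recession_t0": 0,
    "diabetes": False,
    "smoking_type": "none",
    "cigarettes_per_day": 0,
    "mobility": 0,
    "antibiotics": False,
    "family_history": False,
    "ortho_history": False,
}
#: null -> positive / normal response
_POSITIVE: dict[str, object] = {"vitality": True, "cold_sensitivity": True}

#: fields with no imputation rule (identity and demographic fields are
#: expected complete; staging needs age and sex as recorded)
UNHANDLED_FIELDS = ("patient_id", "fdi", "site", "ppd_t0", "ppd_t1",
                    "age", "sex")


@dataclass
class ImputationReport:
    counts: dict[str, int] = field(default_factory=dict)
    rules: dict[str, str] = field(default_factory=dict)
    unhandled: tuple[str, ...] = UNHANDLED_FIELDS
    cells: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["row", "field", "rule"]))

    def total(self) -> int:
        return int(sum(self.counts.values()))


def impute_furcation(ppd_t0: int, recession_t0: int, furcation_capable: bool) -> int:
    """Furcation grade from total probing depth for fully-missing patients.

    Single-rooted teeth cannot develop furcation involvement and always
    grade 0. Otherwise the total of probing depth and recession maps to a
    grade: < 3 mm -> 0, 3-6 mm inclusive -> 1, > 6 mm -> 2 (the bounds are
    read inclusive so integer totals partition with no gap).
    """
    if ppd_t0 < 0 or recession_t0 < 0:
        raise ValueError("measurements must be non-negative")
    if not furcation_capable:
        return 0
    total = ppd_t0 + recession_t0
    if total < 3:
        return 0
    if total <= 6:
        return 1
    return 2


class ClinicalImputer(BaseEstimator, TransformerMixin):
    """Rule-based chart imputer with a sklearn transformer surface.

    Parameters
    ----------
    ppd_window : int, default 1
        Half-width (mm) of the "comparable PPD" window used when voting
        plaque from donor sites.

    Attributes
    ----------
    stress_median_ : float
        Patient-level median stress (interpolated convention: mean of the
        two central order statistics at even counts).
    bmi_mean_ : float
        Patient-level mean BMI.
    plaque_donors_ : pandas.DataFrame
        Observed plaque rows (tooth_type, site, ppd_t0, plaque_t0) used as
        the donor pool for patients whose plaque is entirely missing.
    report_ : ImputationReport
        Report of the most recent :meth:`transform`.
    """

    def __init__(self, ppd_window: int = 1):
        self.ppd_window = ppd_window

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X: PerioDataset | pd.DataFrame, y=None) -> "ClinicalImputer":
        df = X.records if isinstance(X, PerioDataset) else X
        per_patient = df.groupby("patient_id", observed=True)
        stress = per_patient["stress"].first().dropna()
        bmi = per_patient["bmi"].first().dropna()
        if stress.empty:
            raise ValueError("stress is entirely missing; supply an explicit default")
        if bmi.empty:
            raise ValueError("BMI is entirely missing; supply an explicit default")
        self.stress_median_ = float(stress.median())
        self.bmi_mean_ = float(bmi.mean())
        observed = df[df["plaque_t0"].notna()].copy()
        observed["tooth_type"] = [parse_fdi(f).tooth_type
                                  for f in observed["fdi"].astype(int)]
        self.plaque_donors_ = observed[
            ["patient_id", "tooth_type", "site", "ppd_t0", "plaque_t0"]
        ].reset_index(drop=True)
        return self

    def transform(self, X: PerioDataset | pd.DataFrame) -> PerioDataset | pd.DataFrame:
        as_dataset = isinstance(X, PerioDataset)
        df = (X.records if as_dataset else X).copy().reset_index(drop=True)
        report = ImputationReport()
        cells: list[pd.DataFrame] = []

        def record(mask: pd.Series, col: str, rule: str) -> None:
            n = int(mask.sum())
            report.counts[col] = report.counts.get(col, 0) + n
            report.rules[col] = rule
            if n:
                cells.append(pd.DataFrame(
                    {"row": np.flatnonzero(mask), "field": col, "rule": rule}))

        for col, value in _NON_OCCURRENCE.items():
            mask = df[col].isna()
            df.loc[mask, col] = value
            record(mask, col, "non-occurrence")
        for col, value in _POSITIVE.items():
            mask = df[col].isna()
            df.loc[mask, col] = value
            record(mask, col, "positive")

        mask = df["stress"].isna()
        df.loc[mask, "stress"] = int(round(self.stress_median_))
        record(mask, "stress", "patient-level median")
        mask = df["bmi"].isna()
        df.loc[mask, "bmi"] = self.bmi_mean_
        record(mask, "bmi", "patient-level mean")

        df, plaque_cells = self._impute_plaque(df)
        for sub in plaque_cells:
            record(sub[0], "plaque_t0", sub[1])

        df, furc_cells = self._impute_furcation_field(df)
        for sub in furc_cells:
            record(sub[0], "furcation_t0", sub[1])

        for col in CHART_COLUMNS:
            df[col] = df[col].astype(CHART_COLUMNS[col])  # type: ignore[call-overload]
        report.cells = (pd.concat(cells, ignore_index=True) if cells
                        else report.cells)
        self.report_ = report
        if as_dataset:
            return PerioDataset(df, dict(X.provenance))
        return df

    # -- structural rules ---------------------------------------------------
    def _impute_plaque(self, df: pd.DataFrame):
        cells = []
        null = df["plaque_t0"].isna()
        if not null.any():
            return df, cells
        all_null_patients = set(
            df.groupby("patient_id", observed=True)["plaque_t0"]
            .apply(lambda s: s.isna().all())
            .pipe(lambda s: s[s].index)
        )
        patient_all_null = df["patient_id"].isin(all_null_patients)
        single = null & ~patient_all_null
        df.loc[single, "plaque_t0"] = False
        cells.append((single, "single-cell no-plaque"))

        whole = null & patient_all_null
        if whole.any():
            donors = self.plaque_donors_
            votes = []
            for idx in np.flatnonzero(whole):
                row = df.iloc[idx]
                ttype = parse_fdi(int(row["fdi"])).tooth_type
                pool = donors[
                    (donors["tooth_type"] == ttype)
                    & (donors["site"] == row["site"])
                    & ((donors["ppd_t0"] - row["ppd_t0"]).abs() <= self.ppd_window)
                    & (donors["patient_id"] != row["patient_id"])
                ]
                if pool.empty:
                    votes.append(False)  # documented fallback
                else:
                    frac = pool["plaque_t0"].astype(bool).mean()
                    votes.append(bool(frac > 0.5))  # tie -> no plaque
            df.loc[whole, "plaque_t0"] = votes
            cells.append((whole, "donor majority vote"))
        return df, cells

    def _impute_furcation_field(self, df: pd.DataFrame):
        cells = []
        null = df["furcation_t0"].isna()
        if not null.any():
            return df, cells
        capable = pd.Series(
            [parse_fdi(int(f)).furcation_capable for f in df["fdi"]],
            index=df.index,
        )
        all_null_patients = set(
            df.groupby("patient_id", observed=True)["furcation_t0"]
            .apply(lambda s: s.isna().all())
            .pipe(lambda s: s[s].index)
        )
        patient_all_null = df["patient_id"].isin(all_null_patients)

        partial = null & ~patient_all_null
        df.loc[partial, "furcation_t0"] = 0
        cells.append((partial, "no involvement at unnoted sites"))

        whole = null & patient_all_null
        if whole.any():
            ppd = df.loc[whole, "ppd_t0"].astype(int)
            rec = df.loc[whole, "recession_t0"].astype(int)
            cap = capable[whole]
            df.loc[whole, "furcation_t0"] = [
                impute_furcation(p, r, c) for p, r, c in zip(ppd, rec, cap)
            ]
            cells.append((whole, "total-probing-depth mapping"))
        return df, cells


def impute_dataset(dataset: PerioDataset,
                   ppd_window: int = 1) -> tuple[PerioDataset, ImputationReport]:
    """Fit-and-apply the full rule set; returns imputed dataset + report.

    Recession must be resolved before the furcation mapping runs; the
    transformer orders rules accordingly (non-occurrence fills recession
    first).
    """
    imputer = ClinicalImputer(ppd_window=ppd_window).fit(dataset)
    out = imputer.transform(dataset)
    return out, imputer.report_


def impute_plaque(dataset: PerioDataset, patient_id,
                  ppd_window: int = 1) -> PerioDataset:
    """Impute plaque for one patient (thin wrapper over the transformer)."""
    imputer = ClinicalImputer(ppd_window=ppd_window).fit(dataset)
    df = dataset.records.copy().reset_index(drop=True)
    sub = df[df["patient_id"] == patient_id].copy()
    out, _ = imputer._impute_plaque(
        pd.concat([sub, df[df["patient_id"] != patient_id]]).reset_index(drop=True)
    )
    out = out[out["patient_id"] == patient_id]
    df.loc[df["patient_id"] == patient_id, "plaque_t0"] = out["plaque_t0"].to_numpy()
    df["plaque_t0"] = df["plaque_t0"].astype("boolean")
    return PerioDataset(df, dict(dataset.provenance))
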