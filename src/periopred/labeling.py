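"""Outcome targets and task-dataset assembly.

Three clinically motivated prediction tasks are derived from a chart:

* ``ppd_category`` — multiclass: post-therapy probing depth category
  (1: <= 3 mm healthy, 2: 4-5 mm moderate, 3: >= 6 mm deep), over all
  sites, informing the need for different follow-up treatments.
* ``improvement`` — binary: whether a baseline-affected pocket
  (PPD >= 4 mm) fails to improve after therapy.
* ``closure`` — binary: whether a baseline-affected pocket fails to close
  (closure: PPD <= 3 mm, or 4 mm without bleeding on probing).

For the binary tasks the POSITIVE class is the adverse outcome
(non-improvement / non-closure): the clinically relevant minority event.
Features are the baseline (T0) predictor schema on patient, tooth and site
level; categorical predictors are encoded downstream (one-hot or target
encoding fitted on training folds only), so the task dataset keeps them raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import parse_fdi
from .chart import PerioDataset

__all__ = [
    "TASKS",
    "NUMERIC_FEATURES",
    "CATEGORICAL_FEATURES",
    "TaskDataset",
    "ppd_category",
    "improvement_label",
    "closure_label",
    "build_task_dataset",
]

TASKS = ("ppd_category", "improvement", "closure")
ENCODINGS = ("one_hot", "target")

# Frozen predictor schema, all measured at T0.
NUMERIC_FEATURES = (
    "age", "bmi", "stress", "cigarettes_per_day",
    "ppd_t0", "recession_t0", "furcation_t0", "mobility", "root_count",
    "antibiotics", "family_history", "ortho_history", "diabetes",
    "bop_t0", "plaque_t0", "restoration", "vitality", "percussion",
    "cold_sensitivity",
)
CATEGORICAL_FEATURES = ("sex", "smoking_type", "fdi", "tooth_type", "site")

_BASELINE_AFFECTED_MM = 4  # inclusion filter: pockets with PPD_t0 >= 4 mm


def ppd_category(ppd) -> np.ndarray | int:
    """Pocket-depth category: <=3 mm -> 1, 4-5 mm -> 2, >=6 mm -> 3."""
    arr = np.asarray(ppd)
    if (arr < 0).any():
        raise ValueError("PPD must be non-negative")
    cat = np.where(arr <= 3, 1, np.where(arr <= 5, 2, 3))
    return cat if cat.ndim else int(cat)


def improvement_label(ppd_t0, ppd_t1, min_decrease: int = 1):
    """Adverse non-improvement label: True when the pocket did not shrink
    by at least ``min_decrease`` mm (default: any strict integer decrease
    counts as improvement)."""
    improved = np.asarray(ppd_t1) <= np.asarray(ppd_t0) - min_decrease
    adverse = ~improved
    return adverse if adverse.ndim else bool(adverse)


def closure_label(ppd_t1, bop_t1):
    """Adverse non-closure label: closure is PPD <= 3 mm, or exactly 4 mm
    without bleeding on probing, at reevaluation."""
    ppd = np.asarray(ppd_t1)
    bop = np.asarray(bop_t1, dtype=bool)
    closed = (ppd <= 3) | ((ppd == 4) & ~bop)
    adverse = ~closed
    return adverse if adverse.ndim else bool(adverse)


@dataclass
class TaskDataset:
    """Feature matrix + labels + patient groups for one prediction task."""

    task: str
    features: pd.DataFrame
    labels: np.ndarray
    groups: np.ndarray
    encoding: str = "one_hot"
    numeric_cols: tuple[str, ...] = NUMERIC_FEATURES
    categorical_cols: tuple[str, ...] = CATEGORICAL_FEATURES
    n_excluded_missing_t1: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def is_binary(self) -> bool:
        return self.task in ("improvement", "closure")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def build_task_dataset(
    dataset: PerioDataset,
    task: str,
    encoding: str = "one_hot",
    min_decrease: int = 1,
) -> TaskDataset:
    """Assemble the encoded-ready task dataset from an imputed chart.

    The multiclass task uses every site with a reevaluation measurement;
    the binary tasks include only baseline-affected sites (PPD_t0 >= 4 mm).
    Sites without a T1 probing depth are excluded and counted. Raises if
    any predictor still contains nulls — run the imputer first.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")

    df = dataset.records.copy()
    n_missing_t1 = int(df["ppd_t1"].isna().sum())
    df = df[df["ppd_t1"].notna()]
    if task in ("improvement", "closure"):
        df = df[df["ppd_t0"] >= _BASELINE_AFFECTED_MM]
    df = df.reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no eligible sites for task {task!r}")

    anat = [parse_fdi(int(f)) for f in df["fdi"]]
    df["tooth_type"] = [a.tooth_type for a in anat]
    df["root_count"] = [a.root_count for a in anat]

    feats = pd.DataFrame(index=df.index)
    for col in NUMERIC_FEATURES:
        feats[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    for col in CATEGORICAL_FEATURES:
        feats[col] = df[col].astype(str).astype("category")

    null_cols = [c for c in feats.columns if feats[c].isna().any()]
    if null_cols:
        raise ValueError(
            f"predictors {null_cols} contain missing values; impute first"
        )

    if task == "ppd_category":
        labels = ppd_category(df["ppd_t1"].astype(int).to_numpy())
    elif task == "improvement":
        labels = improvement_label(
            df["ppd_t0"].astype(int).to_numpy(),
            df["ppd_t1"].astype(int).to_numpy(),
            min_decrease=min_decrease,
        ).astype(int)
    else:
        bop = df["bop_t1"]
        if bop.isna().any():
            raise ValueError("bop_t1 contains missing values; impute first")
        labels = closure_label(
            df["ppd_t1"].astype(int).to_numpy(), bop.astype(bool).to_numpy()
        ).astype(int)

    return TaskDataset(
        task=task,
        features=feats,
        labels=np.asarray(labels),
        groups=df["patient_id"].to_numpy(),
        encoding=encoding,
        n_excluded_missing_t1=n_missing_t1,
        meta={"min_decrease": min_decrease},
    )
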