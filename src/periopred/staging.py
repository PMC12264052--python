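"""Periodontitis stage / grade / extent engine (2018 classification).

Works from chart data alone, without radiographs:

* CAL (clinical attachment loss) is estimated from baseline probing depth
  and recession: ``CAL = PPD - 3`` when recession is absent (3 mm being the
  average physiological sulcus depth) and ``CAL = PPD + recession``
  otherwise, floored at 0 mm.
* Masticatory function is proxied by the number of occluding
  maxillary-mandibular tooth pairs (14 standard pairs, third molars
  excluded).
* Bone loss [%] = CAL / root length x 100, with root length looked up by
  sex, arch and tooth type from a configurable table of literature-typical
  mean root lengths.
* Stage from the maximum interdental CAL with severity modifiers (deep
  pockets at non-adjacent teeth, furcation involvement, occluding pairs);
  grade from the bone-loss/age ratio and smoking; extent from the fraction
  of teeth at the maximum stage (> 30% = generalized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Final, Iterable, Mapping

import numpy as np
import pandas as pd

from .anatomy import OCCLUDING_PAIRS, parse_fdi
from .chart import INTERPROXIMAL_SITES, PerioDataset

__all__ = [
    "NO_PERIODONTITIS",
    "PatientClassification",
    "RootLengthTable",
    "estimate_cal",
    "count_occluding_pairs",
    "bone_loss_percent",
    "assign_stage",
    "assign_grade",
    "assign_extent",
    "classify_patient",
    "classify_cohort",
]

#: Sentinel returned when the maximum interdental CAL is below 1 mm and a
#: stage is therefore undefined.
NO_PERIODONTITIS: Final[str] = "no periodontitis"

_PHYSIOLOGIC_SULCUS_MM = 3


def estimate_cal(ppd_t0: int, recession_t0: int) -> int:
    """Estimate clinical attachment loss (mm) from PPD and recession.

    With no recession the junctional epithelium is assumed at its
    physiological position, so attachment loss is the probing depth in
    excess of the 3 mm physiological sulcus. With recession the whole
    probed depth plus the exposed root counts as lost attachment. Floored
    at 0 since negative attachment loss is not meaningful.
    """
    if ppd_t0 < 0 or recession_t0 < 0:
        raise ValueError("PPD and recession must be non-negative")
    cal = ppd_t0 - _PHYSIOLOGIC_SULCUS_MM if recession_t0 == 0 else ppd_t0 + recession_t0
    return max(cal, 0)


def count_occluding_pairs(present_fdi: Iterable[int]) -> int:
    """Count standard occluding pairs with both teeth present (max 14)."""
    present = set()
    for fdi in present_fdi:
        parse_fdi(fdi)  # raises InvalidFDIError on bad input
        present.add(int(fdi))
    return sum(1 for a, b in OCCLUDING_PAIRS if a in present and b in present)


def bone_loss_percent(cal: float, root_length: float) -> float:
    """Percentage of root length lost to attachment loss; not capped at 100."""
    if root_length <= 0:
        raise ValueError("root length must be positive")
    if cal < 0:
        raise ValueError("CAL must be non-negative")
    return 100.0 * cal / root_length


# --------------------------------------------------------------------------
# Root length table
# --------------------------------------------------------------------------

# Literature-typical mean root lengths in mm by (arch, tooth_type), with a
# sex offset (male values; females average slightly shorter roots). These
# are shipped defaults, not measured values: substitute a study-specific
# table via RootLengthTable(mapping=...) or from_json for auditable runs.
_DEFAULT_LENGTHS: Mapping[tuple[str, str], float] = {
    ("upper", "incisor"): 13.0,
    ("upper", "canine"): 16.5,
    ("upper", "premolar"): 13.5,
    ("upper", "molar"): 13.0,
    ("lower", "incisor"): 12.5,
    ("lower", "canine"): 15.5,
    ("lower", "premolar"): 14.0,
    ("lower", "molar"): 14.0,
}
_FEMALE_OFFSET_MM = -0.5


@dataclass(frozen=True)
class RootLengthTable:
    """Mean root length (mm) lookup by sex, arch and tooth type.

    The mapping is keyed ``(sex, arch, tooth_type)``; interproximal sites of
    the same tooth share one value. All lengths must be positive and the
    table must cover every combination a chart can produce.
    """

    mapping: Mapping[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mapping:
            full = {
                (sex, arch, ttype): length + (_FEMALE_OFFSET_MM if sex == "female" else 0.0)
                for (arch, ttype), length in _DEFAULT_LENGTHS.items()
                for sex in ("male", "female")
            }
            object.__setattr__(self, "mapping", full)
        if any(v <= 0 for v in self.mapping.values()):
            raise ValueError("all root lengths must be positive")

    def lookup(self, sex: str, fdi: int, site: str | None = None) -> float:
        tooth = parse_fdi(fdi)
        key = (str(sex), tooth.arch, tooth.tooth_type)
        if key not in self.mapping:
            raise KeyError(f"root length table has no entry for {key}")
        return self.mapping[key]

    @classmethod
    def from_json(cls, path) -> "RootLengthTable":
        with open(path) as fh:
            raw = json.load(fh)
        mapping = {tuple(k.split("|")): float(v) for k, v in raw.items()}
        return cls(mapping=mapping)  # type: ignore[arg-type]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"|".join(k): v for k, v in self.mapping.items()}, fh, indent=1)


# --------------------------------------------------------------------------
# Stage / grade / extent
# --------------------------------------------------------------------------

_ARCH_ORDER: dict[int, int] = {}
for i, fdi in enumerate([18, 17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27, 28]):
    _ARCH_ORDER[fdi] = i
for i, fdi in enumerate([48, 47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37, 38]):
    _ARCH_ORDER[fdi] = 100 + i  # offset keeps arches disjoint


def _teeth_non_adjacent(a: int, b: int) -> bool:
    """Teeth are adjacent iff immediate neighbours within one dental arch."""
    return abs(_ARCH_ORDER[a] - _ARCH_ORDER[b]) != 1


def _has_two_nonadjacent(teeth: set[int]) -> bool:
    teeth = sorted(teeth)
    return any(
        _teeth_non_adjacent(a, b)
        for i, a in enumerate(teeth)
        for b in teeth[i + 1:]
    )


def assign_stage(
    max_interdental_cal: int,
    deep_ppd_teeth: set[int] | None = None,
    max_furcation: int = 0,
    n_opposing: int = 14,
) -> int | str:
    """Assign periodontitis stage 1-4 from summary severity measures.

    ``deep_ppd_teeth`` is the set of teeth with PPD >= 6 mm at any site;
    the stage-3 escalation from the 3-4 mm CAL band requires two of them to
    be non-adjacent (not immediate arch neighbours), or furcation
    involvement grade 2-3. CAL >= 5 mm gives stage 3 with preserved
    occlusion (>= 10 opposing pairs) and stage 4 otherwise.

    Returns :data:`NO_PERIODONTITIS` when max CAL < 1 mm.
    """
    cal = max_interdental_cal
    if cal < 0:
        raise ValueError("CAL must be non-negative")
    if cal < 1:
        return NO_PERIODONTITIS
    if cal <= 2:
        return 1
    if cal <= 4:
        escalate = max_furcation >= 2 or (
            deep_ppd_teeth is not None and _has_two_nonadjacent(set(deep_ppd_teeth))
        )
        return 3 if escalate else 2
    return 3 if n_opposing >= 10 else 4


def assign_grade(
    max_bone_loss_pct: float,
    age: float,
    cigarettes_per_day: int = 0,
    strict: bool = False,
) -> str:
    """Assign grade A/B/C from the bone-loss/age ratio and smoking.

    The ratio of percentage bone loss to age is the indirect progression
    estimate: < 0.25 grade A, 0.25-1 grade B, > 1 grade C (boundaries 0.25
    and 1.0 assigned to B). Smoking acts as a grade modifier: >= 1
    cigarette/day lifts A to B, > 10/day lifts to C.

    ``strict=True`` applies the literal band predicate where any smoker
    below 10 cigarettes/day (including non-smokers, 0/day) qualifies for B
    via the OR clause; kept only for comparison since its conditions
    overlap.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    if max_bone_loss_pct < 0 or cigarettes_per_day < 0:
        raise ValueError("bone loss and cigarette count must be non-negative")
    ratio = max_bone_loss_pct / age
    if strict:
        if ratio > 1 or cigarettes_per_day > 10:
            return "C"
        if (0.25 < ratio < 1) or cigarettes_per_day < 10:
            return "B"
        return "A"
    if ratio > 1 or cigarettes_per_day > 10:
        return "C"
    if 0.25 <= ratio <= 1 or cigarettes_per_day >= 1:
        return "B"
    return "A"


def assign_extent(
    tooth_at_max_stage: Iterable[bool], n_teeth_present: int
) -> tuple[str, float]:
    """Classify extent from the share of teeth at the maximum stage.

    Returns ``(extent, extent_pct)`` where extent is ``"generalized"`` iff
    the percentage strictly exceeds 30.
    """
    if n_teeth_present <= 0:
        raise ValueError("need at least one tooth present")
    n_max = int(np.sum(np.asarray(list(tooth_at_max_stage), dtype=bool)))
    pct = 100.0 * n_max / n_teeth_present
    return ("generalized" if pct > 30.0 else "localized"), pct


@dataclass(frozen=True)
class PatientClassification:
    """Stage/grade/extent triple with all intermediates for audit."""

    patient_id: object
    stage: int | str
    grade: str | None
    extent: str | None
    max_interdental_cal: int
    n_opposing: int
    max_bone_loss_pct: float
    extent_pct: float
    n_teeth_present: int
    n_teeth_max_stage: int

    @property
    def has_periodontitis(self) -> bool:
        return self.stage != NO_PERIODONTITIS


def classify_patient(
    dataset: PerioDataset,
    patient_id,
    root_table: RootLengthTable | None = None,
    strict_grade: bool = False,
) -> PatientClassification:
    """Compose CAL -> occlusion -> bone loss -> stage -> grade -> extent.

    CAL maxima are taken over interproximal (mesial/distal) sites only.
    Missing recession is treated as 0 mm and missing furcation as no
    involvement — the same non-occurrence reading the imputation module
    applies — so the classifier is usable on raw or imputed charts alike.
    """
    chart = dataset.for_patient(patient_id)
    if chart.empty:
        raise KeyError(f"patient {patient_id!r} not in dataset")
    root_table = root_table or RootLengthTable()

    teeth = sorted(int(f) for f in chart["fdi"].unique())
    n_opposing = count_occluding_pairs(teeth)

    inter = chart[chart["site"].isin(INTERPROXIMAL_SITES) & chart["ppd_t0"].notna()]
    if inter.empty:
        raise ValueError(f"patient {patient_id!r} has no valid interdental site")
    ppd = inter["ppd_t0"].astype(int).to_numpy()
    rec = inter["recession_t0"].fillna(0).astype(int).to_numpy()
    cal = np.array([estimate_cal(p, r) for p, r in zip(ppd, rec)])
    max_cal = int(cal.max())

    deep = chart[chart["ppd_t0"].notna() & (chart["ppd_t0"].astype("Int64") >= 6)]
    deep_teeth = set(deep["fdi"].astype(int).unique())
    max_furc = int(chart["furcation_t0"].fillna(0).astype(int).max()) if len(chart) else 0

    stage = assign_stage(max_cal, deep_teeth, max_furc, n_opposing)

    sexes = chart["sex"].dropna().unique()
    sex = str(sexes[0]) if len(sexes) else "male"
    root_len = np.array([root_table.lookup(sex, f) for f in inter["fdi"].astype(int)])
    bone = np.array([bone_loss_percent(c, r) for c, r in zip(cal, root_len)])
    max_bone = float(bone.max())

    if stage == NO_PERIODONTITIS:
        return PatientClassification(
            patient_id=patient_id, stage=stage, grade=None, extent=None,
            max_interdental_cal=max_cal, n_opposing=n_opposing,
            max_bone_loss_pct=max_bone, extent_pct=0.0,
            n_teeth_present=len(teeth), n_teeth_max_stage=0,
        )

    age_vals = chart["age"].dropna()
    if age_vals.empty:
        raise ValueError(f"patient {patient_id!r} has no age; cannot grade")
    age = float(age_vals.iloc[0])
    cigs_vals = chart["cigarettes_per_day"].dropna()
    cigs = int(cigs_vals.iloc[0]) if len(cigs_vals) else 0
    grade = assign_grade(max_bone, age, cigs, strict=strict_grade)

    # a tooth counts toward extent when its own max interdental CAL reaches
    # the lower bound of the CAL band that produced the patient's stage
    band_floor = {1: 1, 2: 3, 3: 3 if max_cal <= 4 else 5, 4: 5}[int(stage)]
    per_tooth_cal = (
        pd.Series(cal, index=inter["fdi"].astype(int).to_numpy())
        .groupby(level=0)
        .max()
    )
    flags = [per_tooth_cal.get(t, 0) >= band_floor for t in teeth]
    extent, extent_pct = assign_extent(flags, len(teeth))

    return PatientClassification(
        patient_id=patient_id, stage=stage, grade=grade, extent=extent,
        max_interdental_cal=max_cal, n_opposing=n_opposing,
        max_bone_loss_pct=max_bone, extent_pct=extent_pct,
        n_teeth_present=len(teeth), n_teeth_max_stage=int(sum(flags)),
    )


def classify_cohort(
    dataset: PerioDataset,
    root_table: RootLengthTable | None = None,
    strict_grade: bool = False,
) -> pd.DataFrame:
    """One classification row per patient; column per intermediate."""
    rows = [
        classify_patient(dataset, pid, root_table, strict_grade).__dict__
        for pid in dataset.patients
    ]
    return pd.DataFrame(rows)
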