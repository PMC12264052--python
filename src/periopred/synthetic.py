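"""Synthetic periodontal cohort generator.

Emulates the statistical structure of a step-II therapy cohort: six sites
per tooth in FDI notation, integer-mm probing depths and recession, binary
bleeding-on-probing (BOP) and plaque, ordinal furcation and mobility, and
patient covariates. Baseline pocket-depth categories (healthy <= 3 mm,
moderate 4-5 mm, deep >= 6 mm) are drawn from configurable proportions
(default 79.8% / 14.6% / 5.6%); the post-therapy category follows a
row-stochastic transition matrix whose defaults encode that ~95% of healthy
sites stay healthy, ~60% of moderate pockets close, and ~66% of deep
pockets improve.

Patient covariates influence only the therapy response (the probability of
category improvement, through log-odds shifts on mean-centred covariates),
never baseline severity — a deliberate simplification that keeps
parameter-recovery tests interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .anatomy import ALL_FDI, parse_fdi
from .chart import CHART_COLUMNS, PerioDataset, SITES, validate_dataset

__all__ = ["CohortConfig", "generate_cohort", "inject_missingness"]

#: Fields that may never be made missing (dataset identity + the one
#: measurement every downstream task keys on).
PROTECTED_FIELDS = frozenset({"patient_id", "fdi", "site", "ppd_t0"})

_PPD_SUPPORT = {0: ([1, 2, 3], [0.20, 0.35, 0.45]),
                1: ([4, 5], [0.60, 0.40]),
                2: ([6, 7, 8, 9, 10], [0.40, 0.25, 0.15, 0.12, 0.08])}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """Study-condition parameters of the simulated cohort."""

    n_patients: int = 100
    seed: int = 0
    baseline_category_probs: tuple[float, float, float] = (0.798, 0.146, 0.056)
    transition_matrix: tuple[tuple[float, ...], ...] = (
        (0.95, 0.05, 0.00),
        (0.60, 0.33, 0.07),
        (0.33, 0.33, 0.34),
    )
    # patient covariate distributions
    age_mean: float = 52.0
    age_sd: float = 12.0
    female_frac: float = 0.5
    smoker_frac: float = 0.25
    cigarettes_mean: float = 12.0  # among smokers
    diabetes_frac: float = 0.10
    antibiotics_frac: float = 0.20
    family_history_frac: float = 0.30
    ortho_history_frac: float = 0.10
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    tooth_missing_prob: float = 0.08
    # log-odds shift on the improvement probability per unit of the
    # (mean-centred) covariate; centring keeps marginal transition rates at
    # the matrix values while making the response covariate-dependent
    effect_shifts: dict[str, float] = field(default_factory=lambda: {
        "cigarettes_per_day": -0.06,
        "diabetes": -0.5,
        "antibiotics": 0.6,
        "stress": -0.05,
    })
    missingness_rates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        probs = np.asarray(self.baseline_category_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-12:
            raise ValueError("baseline_category_probs must be a 3-simplex")
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (3, 3) or (tm < 0).any() or (tm > 1).any():
            raise ValueError("transition_matrix must be 3x3 with entries in [0,1]")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        for name in ("female_frac", "smoker_frac", "diabetes_frac",
                     "antibiotics_frac", "family_history_frac",
                     "ortho_history_frac", "tooth_missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _sample_patients(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    age = np.clip(np.rint(rng.normal(cfg.age_mean, cfg.age_sd, n)), 18, 90).astype(int)
    smoker = rng.random(n) < cfg.smoker_frac
    cigs = np.where(
        smoker, 1 + rng.poisson(max(cfg.cigarettes_mean - 1, 0.0), n), 0
    ).astype(int)
    smoking_type = np.where(
        smoker,
        rng.choice(["cigarette", "pipe", "cigar"], n, p=[0.9, 0.05, 0.05]),
        "none",
    )
    return pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": np.where(rng.random(n) < cfg.female_frac, "female", "male"),
        "bmi": np.round(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 16, 45), 1),
        "antibiotics": rng.random(n) < cfg.antibiotics_frac,
        "family_history": rng.random(n) < cfg.family_history_frac,
        "ortho_history": rng.random(n) < cfg.ortho_history_frac,
        "diabetes": rng.random(n) < cfg.diabetes_frac,
        "stress": (1 + rng.binomial(9, 0.4, n)).astype(int),
        "smoking_type": smoking_type,
        "cigarettes_per_day": cigs,
    })


def _draw_ppd(cats: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ppd = np.zeros(len(cats), dtype=int)
    for cat, (support, probs) in _PPD_SUPPORT.items():
        mask = cats == cat
        ppd[mask] = rng.choice(support, size=int(mask.sum()), p=probs)
    return ppd


def _transition(cats: np.ndarray, cfg: CohortConfig, eta: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    tm = np.asarray(cfg.transition_matrix, dtype=float)
    t1 = np.empty(len(cats), dtype=int)
    for cat in (0, 1, 2):
        mask = cats == cat
        if not mask.any():
            continue
        row = tm[cat]
        p_imp = row[:cat].sum()  # mass on strictly better categories
        probs = np.tile(row, (int(mask.sum()), 1))
        if 0.0 < p_imp < 1.0:
            shifted = _sigmoid(
                np.log(p_imp / (1 - p_imp)) + eta[mask]
            )
            probs[:, :cat] *= (shifted / p_imp)[:, None]
            probs[:, cat:] *= ((1 - shifted) / (1 - p_imp))[:, None]
        # vectorized categorical draw via inverse CDF
        u = rng.random(int(mask.sum()))
        t1[mask] = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)
    return t1


def generate_cohort(config: CohortConfig) -> PerioDataset:
    """Generate a complete (no-missing) synthetic cohort.

    Deterministic under a fixed ``config.seed``. The output always passes
    :func:`periopred.chart.validate_dataset` with an empty reject list.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _sample_patients(config, rng)

    frames = []
    for _, pat in patients.iterrows():
        present = [f for f in ALL_FDI if rng.random() >= config.tooth_missing_prob]
        if not present:
            present = [int(rng.choice(ALL_FDI))]
        teeth = pd.DataFrame({"fdi": np.repeat(present, len(SITES)),
                              "site": np.tile(SITES, len(present))})
        for k, v in pat.items():
            teeth[k] = v
        frames.append(teeth)
    df = pd.concat(frames, ignore_index=True)
    n = len(df)

    t0 = rng.choice(3, size=n, p=np.asarray(config.baseline_category_probs))
    df["ppd_t0"] = _draw_ppd(t0, rng)
    rec = (rng.random(n) < 0.15) * (1 + rng.poisson(1.0, n))
    df["recession_t0"] = rec.astype(int)

    # covariate-dependent therapy response on mean-centred covariates
    eta = np.zeros(n)
    for cov, shift in config.effect_shifts.items():
        x = pd.to_numeric(df[cov], errors="coerce").astype(float).to_numpy()
        eta += shift * (x - x.mean())
    t1 = _transition(t0, config, eta, rng)
    df["ppd_t1"] = _draw_ppd(t1, rng)

    df["bop_t0"] = rng.random(n) < _sigmoid(-1.8 + 0.5 * (df["ppd_t0"].to_numpy() - 3))
    df["bop_t1"] = rng.random(n) < _sigmoid(-1.8 + 0.5 * (df["ppd_t1"].to_numpy() - 3))
    df["plaque_t0"] = rng.random(n) < _sigmoid(-0.8 + 0.3 * (df["ppd_t0"].to_numpy() - 3))

    furc_capable = np.array([parse_fdi(f).furcation_capable for f in df["fdi"]])
    total = df["ppd_t0"].to_numpy() + df["recession_t0"].to_numpy()
    furc = np.where(total < 3, 0, np.where(total <= 6, 1, 2))
    df["furcation_t0"] = np.where(furc_capable, furc, 0)

    mob = np.rint(np.maximum(0, (df["ppd_t0"].to_numpy() - 4) / 2.0)
                  + rng.normal(0, 0.4, n))
    df["mobility"] = np.clip(mob, 0, 3).astype(int)
    df["restoration"] = rng.random(n) < 0.25
    df["vitality"] = rng.random(n) < 0.95
    df["percussion"] = rng.random(n) < 0.05
    df["cold_sensitivity"] = rng.random(n) < 0.85

    df = df[list(CHART_COLUMNS)]
    dataset, report = validate_dataset(df, provenance={"source": "synthetic",
                                                       "seed": config.seed})
    assert report.n_rejected == 0, "generator produced invalid rows"

    if config.missingness_rates:
        dataset = inject_missingness(dataset, config.missingness_rates,
                                     seed=config.seed + 1)
    return dataset


def inject_missingness(
    dataset: PerioDataset, rates: dict[str, float], seed: int
) -> PerioDataset:
    """Null each targeted field independently at its rate.

    Identity fields and baseline PPD are protected and may not be nulled.
    """
    for col, rate in rates.items():
        if col in PROTECTED_FIELDS and rate > 0:
            raise ValueError(f"field {col!r} is protected and cannot be nulled")
        if col not in CHART_COLUMNS:
            raise KeyError(f"unknown chart field {col!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = dataset.records.copy()
    for col, rate in rates.items():
        if rate == 0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = pd.NA
        out[col] = out[col].astype(CHART_COLUMNS[col])  # type: ignore[call-overload]
    return PerioDataset(out, dict(dataset.provenance))
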