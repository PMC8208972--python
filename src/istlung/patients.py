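"""Synthetic verification patients and cohorts.

Three literature-style presets span the verification cases: a healthy adult
(sigma_V = 0.3, sigma_P = 0.5), an emphysema patient with widened ventilation
heterogeneity (sigma_V = 1.2), and a pulmonary-embolism patient with widened
perfusion heterogeneity (sigma_V = 0.8, sigma_P = 1.3), all sharing the same
totals V_A = 2.3 L and Q_P = 4.9 L/min so the presets differ only in
distribution shape.

The cohort generator emulates a 32-healthy / 72-COPD study population: ages
Normal(53, 22) and Normal(67, 10) truncated to [20, 90]; healthy heterogeneity
indices follow the age-normalisation lines sigma_V = 0.0043*age + 0.46 and
sigma_P = 0.0045*age + 0.75 plus Gaussian scatter; COPD subjects inflate the
age-predicted value by a GOLD-grade factor.  The per-GOLD inflation factors
are synthetic calibration constants (chosen so pooled COPD %-predicted
sigma_V is about 140), not physiological measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .recovery import ISTMeasurement, run_ist
from .simulator import LognormalSpec, ThetaParams, VentilatorSettings

__all__ = [
    "PatientPreset",
    "SubjectRecord",
    "PRESET_NAMES",
    "GOLD_LABELS",
    "preset",
    "generate_measurement",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_records",
]

GOLD_LABELS = ("healthy", "GOLD1", "GOLD2", "GOLD3", "GOLD4")

#: Synthetic per-GOLD inflation of the age-predicted heterogeneity indices.
GOLD_INFLATION = {"GOLD1": 1.15, "GOLD2": 1.30, "GOLD3": 1.45, "GOLD4": 1.60}

# age-normalisation lines of the healthy population (see cohort module)
_SLOPE_V, _INTERCEPT_V = 0.0043, 0.46
_SLOPE_P, _INTERCEPT_P = 0.0045, 0.75
# residual scatter about the age lines, calibrated so the pooled
# %-of-age-predicted moments come out near 100 +/- 17 (healthy) and
# 140 +/- 26 (pooled COPD) for the ventilation index
_HEALTHY_SD_V, _HEALTHY_SD_P = 0.13, 0.26
_COPD_SD_V, _COPD_SD_P = 0.15, 0.21
_SIGMA_FLOOR = 0.05


@dataclass(frozen=True)
class PatientPreset:
    """Named verification patient with known generating parameters."""

    name: str
    theta: ThetaParams


_PRESETS = {
    "healthy": PatientPreset(
        "healthy",
        ThetaParams(2.3, 4.9, LognormalSpec(1.0, 0.3), LognormalSpec(1.0, 0.5)),
    ),
    "emphysema": PatientPreset(
        "emphysema",
        ThetaParams(2.3, 4.9, LognormalSpec(1.0, 1.2), LognormalSpec(1.0, 0.5)),
    ),
    "embolism": PatientPreset(
        "embolism",
        ThetaParams(2.3, 4.9, LognormalSpec(1.0, 0.8), LognormalSpec(1.0, 1.3)),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> PatientPreset:
    """Return the named verification preset (immutable)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


def generate_measurement(
    theta: ThetaParams,
    settings: VentilatorSettings | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    **run_ist_kwargs,
) -> ISTMeasurement:
    """Noisy synthetic IST measurement from known lung parameters.

    Runs the forward IST map and applies independent multiplicative Gaussian
    noise with coefficient of variation ``noise_cv`` to each of the four
    observables (observables are strictly positive scale quantities, hence
    multiplicative).  ``noise_cv = 0`` returns the noise-free forward result
    retagged as a measurement.  Deterministic given ``seed``.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    settings = settings or VentilatorSettings()
    clean = run_ist(theta, settings, **run_ist_kwargs)
    values = clean.observables
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        for _ in range(100):
            noisy = values * (1.0 + noise_cv * rng.standard_normal(4))
            if np.all(noisy > 0):
                values = noisy
                break
        else:
            raise ConfigurationError(
                "noise repeatedly drove an observable non-positive; lower noise_cv"
            )
    return ISTMeasurement(
        elv_180=float(values[0]),
        elv_60=float(values[1]),
        qp_180=float(values[2]),
        qp_60=float(values[3]),
        dead_space=settings.dead_space,
        source="measured",
    )


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic cohort member."""

    id: str
    age: float
    group: str
    sigma_v: float
    sigma_p: float

    def __post_init__(self):
        if not (self.age > 0):
            raise ConfigurationError("age must be > 0")
        if not (self.sigma_v > 0 and self.sigma_p > 0):
            raise ConfigurationError("sigma_v and sigma_p must be > 0")
        if self.group not in GOLD_LABELS:
            raise ConfigurationError(f"unknown group {self.group!r}")


def _truncated_normal(rng, mean, sd, low, high, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= low) & (draw <= high)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(n_healthy: int, n_copd: int, seed: int = 0) -> list[SubjectRecord]:
    """Generate a synthetic healthy/COPD cohort of heterogeneity indices.

    COPD subjects are split as evenly as possible across GOLD 1-4 (extras go
    to the lower grades).  All indices are floored at 0.05.
    """
    if n_healthy < 0 or n_copd < 0:
        raise ConfigurationError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []

    ages_h = _truncated_normal(rng, 53.0, 22.0, 20.0, 90.0, n_healthy)
    for i, age in enumerate(ages_h):
        sv = _SLOPE_V * age + _INTERCEPT_V + rng.normal(0.0, _HEALTHY_SD_V)
        sp = _SLOPE_P * age + _INTERCEPT_P + rng.normal(0.0, _HEALTHY_SD_P)
        records.append(
            SubjectRecord(
                id=f"H{i + 1:03d}",
                age=float(age),
                group="healthy",
                sigma_v=float(max(sv, _SIGMA_FLOOR)),
                sigma_p=float(max(sp, _SIGMA_FLOOR)),
            )
        )

    ages_c = _truncated_normal(rng, 67.0, 10.0, 20.0, 90.0, n_copd)
    grades = [f"GOLD{1 + (i % 4)}" for i in range(n_copd)]
    for i, (age, grade) in enumerate(zip(ages_c, sorted(grades))):
        factor = GOLD_INFLATION[grade]
        sv = (_SLOPE_V * age + _INTERCEPT_V) * factor + rng.normal(0.0, _COPD_SD_V)
        sp = (_SLOPE_P * age + _INTERCEPT_P) * factor + rng.normal(0.0, _COPD_SD_P)
        records.append(
            SubjectRecord(
                id=f"C{i + 1:03d}",
                age=float(age),
                group=grade,
                sigma_v=float(max(sv, _SIGMA_FLOOR)),
                sigma_p=float(max(sp, _SIGMA_FLOOR)),
            )
        )
    return records


def cohort_to_frame(records) -> pd.DataFrame:
    """Tidy cohort table: id, age_years, group, sigma_v, sigma_p."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age_years": [r.age for r in records],
            "group": [r.group for r in records],
            "sigma_v": [r.sigma_v for r in records],
            "sigma_p": [r.sigma_p for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    return [
        SubjectRecord(
            id=str(row["id"]),
            age=float(row["age_years"]),
            group=str(row["group"]),
            sigma_v=float(row["sigma_v"]),
            sigma_p=float(row["sigma_p"]),
        )
        for _, row in df.iterrows()
    ]
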