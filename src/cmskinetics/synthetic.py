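"""Synthetic study generator.

Emulates the data the hydrolysis/quantitation pipeline consumes so that
every stage can be exercised and validated without instrument data:

* percent-remaining hydrolysis series per temperature, generated from the
  reversible CMS ⇌ CS model with forward rates following an Arrhenius law
  and multiplicative Gaussian noise (LC-MS peak-area noise scales with
  signal, so a constant coefficient of variation is the realistic choice);
* replicate calibration point sets that are linear (colistin A/B) or
  quadratic (CMS) in concentration with additive response noise;
* a truth manifest recording every generating parameter, for
  parameter-recovery tests.

All generation is deterministic under the design seed; distinct
temperatures and analytes draw from independent sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .arrhenius import GAS_CONSTANT, fit_arrhenius
from .calibration import CSA_MASS_FRACTION, CalibrationCurve, partition_cs
from .fitting import hydrolysis_sampling_schedule
from .kinetics import (
    ConcentrationSeries,
    ReversibleRateParams,
    TemperaturePoint,
    closed_form_remaining,
)

__all__ = [
    "StudyDesign",
    "StudyBundle",
    "default_arrhenius_truth",
    "generate_decay_series",
    "generate_calibration_set",
    "generate_full_study",
    "default_calibration_truth",
]


def default_arrhenius_truth() -> tuple[float, float]:
    """(Ea, lnA) implied by the reference forward rate constants.

    Obtained by the same ln k vs 1/T regression the analysis module uses,
    so noiseless generation followed by fitting is an exact round trip.
    """
    fit = fit_arrhenius(
        [(TemperaturePoint(T), k) for T, k in reference.FORWARD_RATE_CONSTANTS.items()]
    )
    return fit.Ea, fit.lnA


@dataclass(frozen=True)
class StudyDesign:
    """Generating parameters of a synthetic hydrolysis + calibration study.

    Defaults reproduce the reference study conditions: accelerated runs at
    40/50/60 deg C plus a 20 deg C verification run, sampling every 2 min to
    10 min then every 10 min to 130 min, reverse rates fixed per temperature,
    and 2 % multiplicative noise on percent-remaining values.
    """

    temperatures_C: tuple[float, ...] = (40.0, 50.0, 60.0)
    verification_temperature_C: float = reference.VERIFICATION_TEMPERATURE_C
    schedule_end: float = 130.0
    arrhenius_truth: tuple[float, float] = field(default_factory=default_arrhenius_truth)
    reverse_rates: dict = field(
        default_factory=lambda: dict(reference.REVERSE_RATE_CONSTANTS)
    )
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.temperatures_C)) != len(self.temperatures_C):
            raise ValueError("temperatures must be distinct")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def schedule(self) -> np.ndarray:
        return hydrolysis_sampling_schedule(self.schedule_end)

    def k_forward(self, temperature_C: float) -> float:
        Ea, lnA = self.arrhenius_truth
        T_K = TemperaturePoint(temperature_C).temperature_K
        return float(np.exp(lnA - Ea / (GAS_CONSTANT * T_K)))

    def params(self, temperature_C: float) -> ReversibleRateParams:
        k_r = self.reverse_rates.get(temperature_C)
        if k_r is None:
            k_r = float(np.mean(list(self.reverse_rates.values())))
        return ReversibleRateParams(self.k_forward(temperature_C), k_r)


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in streams])


def generate_decay_series(
    design: StudyDesign, temperature_C: float
) -> ConcentrationSeries:
    """Percent-remaining series at one temperature of the design.

    Values are the closed-form reversible trajectory started at 100 %,
    perturbed multiplicatively by Normal(0, noise_cv) draws; t = 0 is
    anchored at exactly 100 (the normalisation point carries no noise).
    Draws that would go negative are truncated at 0.
    """
    valid = set(design.temperatures_C) | {design.verification_temperature_C}
    if temperature_C not in valid:
        raise ValueError(f"{temperature_C} deg C is not part of the design")
    t = design.schedule
    clean = closed_form_remaining(100.0, design.params(temperature_C), t)
    rng = _rng(design.seed, 1, round(temperature_C * 10))
    noisy = clean * (1.0 + rng.normal(0.0, design.noise_cv, size=t.size))
    noisy[0] = 100.0
    return ConcentrationSeries(
        times=t,
        values=np.clip(noisy, 0.0, None),
        unit_tag="percent",
        temperature_C=temperature_C,
    )


def generate_calibration_set(
    truth: CalibrationCurve,
    levels,
    n_runs: int = 3,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate calibration points: truth(level) + Normal(0, noise_sd).

    Returns a long table with columns ``analyte, run, level_ug_mL, response``.
    Levels outside the truth's fitted range raise a design warning.
    """
    levels = np.asarray(levels, dtype=float)
    lo, hi = truth.conc_range
    if np.any(levels < lo - 1e-9) or np.any(levels > hi + 1e-9):
        import warnings

        warnings.warn(
            f"some levels fall outside the truth range [{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    rng = _rng(seed, 2, sum(ord(c) for c in truth.analyte))
    rows = []
    for run in range(1, n_runs + 1):
        resp = truth.predict(levels) + rng.normal(0.0, noise_sd, size=levels.size)
        for lev, r in zip(levels, resp):
            rows.append(
                {
                    "analyte": truth.analyte,
                    "run": run,
                    "level_ug_mL": float(lev),
                    "response": float(r),
                }
            )
    return pd.DataFrame(rows)


def default_calibration_truth(analyte: str) -> CalibrationCurve:
    """Reference-condition true calibration curve for one analyte."""
    analyte = analyte.upper()
    if analyte == "CSA":
        coeffs, order = reference.CSA_CURVE_COEFFS, 1
        levels = [partition_cs(t, CSA_MASS_FRACTION)[0] for t in reference.CS_TOTAL_LEVELS]
    elif analyte == "CSB":
        coeffs, order = reference.CSB_CURVE_COEFFS, 1
        levels = [partition_cs(t, CSA_MASS_FRACTION)[1] for t in reference.CS_TOTAL_LEVELS]
    elif analyte == "CMS":
        coeffs, order = reference.CMS_CURVE_COEFFS, 2
        levels = list(reference.CMS_LEVELS)
    else:
        raise ValueError(f"unknown analyte {analyte!r}")
    c = np.asarray(coeffs, dtype=float)
    return CalibrationCurve(
        analyte=analyte,
        order=order,
        coefficients=c,
        standard_errors=np.zeros_like(c),
        r_squared=1.0,
        conc_range=(min(levels), max(levels)),
        sse=0.0,
        n_obs=len(levels),
    )


def calibration_levels(analyte: str) -> list[float]:
    """Nominal concentration levels (ug/mL) of the reference design."""
    return _levels(analyte)


def _levels(analyte: str) -> list[float]:
    analyte = analyte.upper()
    if analyte == "CMS":
        return [float(v) for v in reference.CMS_LEVELS]
    idx = 0 if analyte == "CSA" else 1
    return [
        float(partition_cs(t, CSA_MASS_FRACTION)[idx])
        for t in reference.CS_TOTAL_LEVELS
    ]


@dataclass(frozen=True)
class StudyBundle:
    """Everything a full synthetic study produces."""

    design: StudyDesign
    series: dict  # temperature_C -> ConcentrationSeries
    calibration: dict  # analyte -> DataFrame
    truth: dict  # generating-parameter manifest

    def truth_manifest(self) -> dict:
        return self.truth


#: Additive response-noise SDs per analyte; chosen so mid-range %RSD of the
#: synthetic responses sits in the few-percent band typical of the assay.
CALIBRATION_NOISE_SD = {"CSA": 20.0, "CSB": 60.0, "CMS": 30.0}


def generate_full_study(design: StudyDesign, n_runs: int = 3) -> StudyBundle:
    """Generate hydrolysis series for every design temperature plus
    replicate calibration sets for all three analytes, with a truth manifest."""
    temps = list(design.temperatures_C) + [design.verification_temperature_C]
    series = {T: generate_decay_series(design, T) for T in temps}
    calibration = {}
    for analyte, sd in CALIBRATION_NOISE_SD.items():
        truth = default_calibration_truth(analyte)
        calibration[analyte] = generate_calibration_set(
            truth, _levels(analyte), n_runs=n_runs, noise_sd=sd, seed=design.seed
        )
    Ea, lnA = design.arrhenius_truth
    truth = {
        "seed": design.seed,
        "noise_cv": design.noise_cv,
        "arrhenius": {"Ea_J_per_mol": Ea, "lnA": lnA},
        "rates": {
            str(T): {
                "k_forward": design.params(T).k_forward,
                "k_reverse": design.params(T).k_reverse,
            }
            for T in temps
        },
        "calibration": {
            a: {
                "order": default_calibration_truth(a).order,
                "coefficients": [
                    float(c) for c in default_calibration_truth(a).coefficients
                ],
                "noise_sd": CALIBRATION_NOISE_SD[a],
                "levels": _levels(a),
            }
            for a in CALIBRATION_NOISE_SD
        },
    }
    return StudyBundle(design=design, series=series, calibration=calibration, truth=truth)
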