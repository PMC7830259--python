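"""Arrhenius analysis: temperature dependence of the hydrolysis rate.

The rate constant of an elementary reaction follows

    ln k = ln A - Ea / (R T),

with activation energy Ea (J mol^-1), pre-exponential factor A and the gas
constant R = 8.314 J mol^-1 K^-1.  Fitting ln k against 1/T by ordinary
least squares across the accelerated-condition temperatures yields Ea and
ln A; the fitted line is then extrapolated to milder temperatures to predict
rate constants, half-lives and times to a target completeness of hydrolysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import ReversibleRateParams, TemperaturePoint, half_life

__all__ = [
    "GAS_CONSTANT",
    "ArrheniusFit",
    "ArrheniusModel",
    "fit_arrhenius",
    "percent_error",
    "time_to_remaining",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class ArrheniusFit:
    """OLS fit of ln k on 1/T.

    ``Ea`` is -slope * R in J mol^-1, ``lnA`` the intercept (ln of min^-1).
    ``points`` keeps the (T_K, k) pairs the fit was built from so that
    predictions can be flagged as interpolation or extrapolation.
    """

    Ea: float
    lnA: float
    r_squared: float
    points: tuple[tuple[float, float], ...]
    Ea_se: float
    R_const: float = GAS_CONSTANT

    def predict_k(self, T: TemperaturePoint | float) -> float:
        """Rate constant at temperature ``T`` (min^-1).

        Accepts a :class:`TemperaturePoint` or plain Celsius.  Strictly
        increasing in T for Ea > 0.
        """
        T_K = self._as_kelvin(T)
        return float(np.exp(self.lnA - self.Ea / (self.R_const * T_K)))

    def is_extrapolation(self, T: TemperaturePoint | float) -> bool:
        T_K = self._as_kelvin(T)
        fitted = [p[0] for p in self.points]
        return T_K < min(fitted) - 1e-9 or T_K > max(fitted) + 1e-9

    def predict_half_life(self, T: TemperaturePoint | float, exact: bool = False) -> float:
        """Half-life (min) at ``T`` from the predicted rate constant."""
        return half_life(self.predict_k(T), exact=exact)

    def rate_table(self, temperatures_C, exact: bool = False):
        """Per-temperature (T_C, k, t_1/2) rows, flagging extrapolations."""
        rows = []
        for T_C in temperatures_C:
            k = self.predict_k(T_C)
            rows.append(
                {
                    "temperature_C": float(T_C),
                    "k_per_min": k,
                    "half_life_min": half_life(k, exact=exact),
                    "extrapolated": self.is_extrapolation(T_C),
                }
            )
        return rows

    def summary(self) -> str:
        lines = [
            f"Arrhenius fit on {len(self.points)} temperatures",
            f"  Ea  = {self.Ea:,.0f} J mol^-1  (se {self.Ea_se:,.0f})",
            f"  lnA = {self.lnA:.3f} (k in min^-1)",
            f"  R^2 = {self.r_squared:.4f}",
        ]
        return "\n".join(lines)

    @staticmethod
    def _as_kelvin(T) -> float:
        if isinstance(T, TemperaturePoint):
            return T.temperature_K
        return TemperaturePoint(float(T)).temperature_K


class ArrheniusModel:
    """Arrhenius regression model over (temperature, rate constant) pairs."""

    def __init__(self, points):
        pts = []
        for T, k in points:
            if not isinstance(T, TemperaturePoint):
                T = TemperaturePoint(float(T))
            if k <= 0:
                raise ValueError(f"rate constants must be positive, got {k}")
            pts.append((T.temperature_K, float(k)))
        if len({T_K for T_K, _ in pts}) < 2:
            raise ValueError("need >= 2 distinct temperatures for the regression")
        self.points = tuple(pts)

    def fit(self) -> ArrheniusFit:
        T_K = np.array([p[0] for p in self.points])
        lnk = np.log([p[1] for p in self.points])
        res = stats.linregress(1.0 / T_K, lnk)
        r2 = 1.0 if len(self.points) == 2 else float(res.rvalue**2)
        se = float(res.stderr) * GAS_CONSTANT if np.isfinite(res.stderr) else np.nan
        return ArrheniusFit(
            Ea=float(-res.slope * GAS_CONSTANT),
            lnA=float(res.intercept),
            r_squared=r2,
            points=self.points,
            Ea_se=se,
        )


def fit_arrhenius(points) -> ArrheniusFit:
    """Convenience wrapper around :class:`ArrheniusModel`."""
    return ArrheniusModel(points).fit()


def percent_error(k_observed: float, k_predicted: float) -> float:
    """Relative verification error (k_obs - k_pred) / k_pred, as a fraction.

    Used to check an out-of-range experimental rate constant against the
    Arrhenius extrapolation; positive means the reaction ran faster than
    predicted.
    """
    if k_observed <= 0 or k_predicted <= 0:
        raise ValueError("rate constants must be positive")
    return (k_observed - k_predicted) / k_predicted


def time_to_remaining(params: ReversibleRateParams, target: float) -> float:
    """Time (min) for the reversible scheme to decay to ``target`` % remaining.

    Inverts the closed form started at 100 %:

        t = ln((100 - A_eq) / (target - A_eq)) / (k_f + k_r).

    ``target`` must lie strictly between the equilibrium floor
    ``A_eq = 100 k_r / (k_f + k_r)`` and 100.
    """
    a_eq = 100.0 * params.equilibrium_fraction()
    if not a_eq < target < 100.0:
        raise ValueError(
            f"target {target}% unreachable: equilibrium floor is {a_eq:.3g}%"
        )
    return float(np.log((100.0 - a_eq) / (target - a_eq)) / params.k_observed)
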