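"""Rate-constant estimation from percent-remaining time series.

Two estimators, mirroring how acid-hydrolysis kinetics are analysed in
practice:

* an early-window log-linear fit — ordinary least squares of ln(% remaining)
  on time over the first minutes of the run, where the reverse reaction is
  negligible and the decay is effectively first order
  (``ln C_t = ln C_0 - k t``);

* a full-course nonlinear least-squares fit of the reversible scheme,
  minimising the sum of squared deviations between the observed percent
  remaining and the closed-form trajectory of CMS ⇌ CS over
  (k_forward, k_reverse).

Both are exposed statsmodels-style: a model object built from a
:class:`~cmskinetics.kinetics.ConcentrationSeries` whose ``fit()`` returns a
results object with estimates, uncertainties and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinetics import ConcentrationSeries, ReversibleRateParams, closed_form_remaining

__all__ = [
    "FirstOrderFit",
    "ReversibleFitResult",
    "FirstOrderDecayModel",
    "ReversibleHydrolysisModel",
    "fit_first_order_early",
    "fit_reversible",
    "hydrolysis_sampling_schedule",
]


def hydrolysis_sampling_schedule(end: float = 130.0) -> np.ndarray:
    """Standard sampling grid: every 2 min to 10 min, then every 10 min.

    Reflects the dense early sampling needed to pin the fast initial decay
    plus sparse late sampling to the end of the run (default 130 min,
    18 points).
    """
    if end < 10:
        raise ValueError(f"schedule end must be >= 10 min, got {end}")
    early = np.arange(0.0, 10.0 + 1e-9, 2.0)
    late = np.arange(20.0, end + 1e-9, 10.0)
    return np.concatenate([early, late])


@dataclass(frozen=True)
class FirstOrderFit:
    """OLS fit of ln(% remaining) on time over an early window.

    ``k = -slope`` is the apparent first-order rate constant (min^-1);
    ``intercept`` estimates ln of the initial percent.  A non-decaying
    (flat or rising) window is flagged via ``decaying``.
    """

    slope: float
    intercept: float
    r_squared: float
    k: float
    window_end: float
    slope_se: float
    intercept_se: float
    n_obs: int

    @property
    def decaying(self) -> bool:
        return self.slope < 0

    def summary(self) -> str:
        return (
            f"First-order early-window fit (t <= {self.window_end:g} min, "
            f"n = {self.n_obs})\n"
            f"  ln(%) = {self.slope:+.5g} (+/-{self.slope_se:.2g}) * t "
            f"+ {self.intercept:.4f} (+/-{self.intercept_se:.2g})\n"
            f"  k = {self.k:.4g} min^-1    R^2 = {self.r_squared:.4f}"
        )


class FirstOrderDecayModel:
    """Early-window first-order decay model for a hydrolysis series."""

    def __init__(self, series: ConcentrationSeries, window_end: float = 10.0):
        self.series = series
        self.window_end = float(window_end)

    def fit(self) -> FirstOrderFit:
        mask = self.series.times <= self.window_end
        t = self.series.times[mask]
        v = self.series.values[mask]
        if t.size < 3:
            raise ValueError(
                f"need >= 3 points with t <= {self.window_end}, got {t.size}"
            )
        if np.any(v <= 0):
            raise ValueError("log-linear fit undefined: non-positive value in window")
        res = stats.linregress(t, np.log(v))
        r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
        return FirstOrderFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=r2,
            k=float(-res.slope),
            window_end=self.window_end,
            slope_se=float(res.stderr),
            intercept_se=float(res.intercept_stderr),
            n_obs=int(t.size),
        )


def fit_first_order_early(
    series: ConcentrationSeries, window_end: float = 10.0
) -> FirstOrderFit:
    """Convenience wrapper around :class:`FirstOrderDecayModel`."""
    return FirstOrderDecayModel(series, window_end=window_end).fit()


@dataclass(frozen=True)
class ReversibleFitResult:
    """Nonlinear least-squares estimates of (k_forward, k_reverse).

    ``covariance`` is the 2x2 parameter covariance from the Gauss-Newton
    approximation; when k_reverse sits at its zero bound the reverse-rate
    row/column is undefined and reported as NaN.  ``bse`` holds the two
    standard errors on the same convention.
    """

    params: ReversibleRateParams
    sse: float
    n_obs: int
    converged: bool
    covariance: np.ndarray | None
    message: str = ""

    @property
    def bse(self) -> np.ndarray:
        if self.covariance is None:
            return np.array([np.nan, np.nan])
        return np.sqrt(np.diag(self.covariance))

    @property
    def at_reverse_bound(self) -> bool:
        return self.covariance is None or np.isnan(self.covariance[1, 1])

    def predict(self, t, c0: float = 100.0):
        return closed_form_remaining(c0, self.params, t)

    def summary(self) -> str:
        se = self.bse
        se_f = f"{se[0]:.2g}" if np.isfinite(se[0]) else "n/a"
        se_r = f"{se[1]:.2g}" if np.isfinite(se[1]) else "undefined (at bound)"
        return (
            f"Reversible CMS<=>CS fit (n = {self.n_obs}, "
            f"converged = {self.converged})\n"
            f"  k_forward = {self.params.k_forward:.4g} min^-1  (se {se_f})\n"
            f"  k_reverse = {self.params.k_reverse:.4g} min^-1  (se {se_r})\n"
            f"  SSE = {self.sse:.4g} %^2"
        )


class ReversibleHydrolysisModel:
    """Full-course reversible-model fit of a percent-remaining series.

    The objective is the unweighted sum of squares on the percent scale,

        SSE(k_f, k_r) = sum_i (y_i - A(t_i; k_f, k_r))^2,

    with A the closed-form trajectory started at 100 %.  k_forward is bounded
    below by 0 (exclusive), k_reverse by 0 (inclusive).  When no starting
    point is supplied, k_forward is seeded from the early-window log-linear
    fit and k_reverse from the last observed value read as the equilibrium
    plateau.

    Parameters
    ----------
    series : ConcentrationSeries
        Percent-remaining series starting at t = 0 (the value there is
        treated as 100 %).
    epsilon : float
        Convergence tolerance on the relative SSE change (default 1e-8).
    """

    def __init__(self, series: ConcentrationSeries, epsilon: float = 1e-8):
        if len(series) < 5:
            raise ValueError("reversible fit needs a series of >= 5 points")
        self.series = series
        self.epsilon = float(epsilon)
        self.c0 = 100.0

    def _default_init(self) -> ReversibleRateParams:
        try:
            k0 = fit_first_order_early(self.series).k
        except ValueError:
            k0 = np.nan
        if not np.isfinite(k0) or k0 <= 0:
            k0 = 0.01
        # last value read as plateau: A_eq/c0 = k_r/(k_f+k_r)
        frac = min(max(self.series.values[-1] / self.c0, 0.0), 0.99)
        k_r0 = k0 * frac / (1.0 - frac)
        return ReversibleRateParams(k_forward=k0, k_reverse=max(k_r0, 0.0))

    def fit(self, init: ReversibleRateParams | None = None) -> ReversibleFitResult:
        if np.all(np.diff(self.series.values) >= 0):
            import warnings

            warnings.warn(
                "series is non-decreasing over time; the hydrolysis model "
                "is likely misspecified for these data",
                stacklevel=2,
            )
        if init is None:
            init = self._default_init()

        t, y = self.series.times, self.series.values

        def residuals(theta):
            kf, kr = theta
            return y - closed_form_remaining(
                self.c0, ReversibleRateParams(max(kf, 1e-12), max(kr, 0.0)), t
            )

        sol = optimize.least_squares(
            residuals,
            x0=[init.k_forward, init.k_reverse],
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            ftol=self.epsilon,
            xtol=1e-12,
            gtol=1e-12,
        )
        kf, kr = sol.x
        params = ReversibleRateParams(k_forward=float(kf), k_reverse=float(kr))
        sse = float(2.0 * sol.cost)
        n = len(self.series)

        cov = self._covariance(sol, n, sse)
        return ReversibleFitResult(
            params=params,
            sse=sse,
            n_obs=n,
            converged=bool(sol.success),
            covariance=cov,
            message=str(sol.message),
        )

    @staticmethod
    def _covariance(sol, n: int, sse: float) -> np.ndarray | None:
        dof = n - 2
        if dof <= 0:
            return None
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (sse / dof)
        except np.linalg.LinAlgError:
            return None
        if sol.x[1] <= 1e-8 or sol.active_mask[1] != 0:
            # reverse rate pinned at its physical bound: its sampling
            # uncertainty is one-sided and the Wald covariance is meaningless
            cov = cov.copy()
            cov[1, :] = np.nan
            cov[:, 1] = np.nan
        return cov


def fit_reversible(
    series: ConcentrationSeries,
    init: ReversibleRateParams | None = None,
    epsilon: float = 1e-8,
) -> ReversibleFitResult:
    """Convenience wrapper around :class:`ReversibleHydrolysisModel`."""
    return ReversibleHydrolysisModel(series, epsilon=epsilon).fit(init=init)
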