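"""LC-MS quantitation statistics for the CMS/colistin assay.

Covers everything needed to turn instrument responses into concentrations
and to validate that pipeline:

* polynomial calibration curves (linear for colistin A/B, quadratic for the
  heterogeneous CMS peak) with coefficient standard errors and R^2;
* replicate-curve pooling via the extra sum-of-squares F test — independent
  per-run fits against a single global fit with shared parameters;
* detection/quantitation limits LOD = 3.3 sigma/S and LOQ = 10 sigma/S;
* the fixed colistin A : colistin B mass split of the reference standard;
* indirect determination of circulating prodrug,
  CMS = CS_total(after hydrolysis) - CS_before(hydrolysis);
* accuracy (% error vs nominal) and precision (%RSD, within-run
  repeatability and between-run intermediate precision) summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "CalibrationModel",
    "PooledCurveTest",
    "ValidationSummary",
    "fit_calibration",
    "pool_curves_f_test",
    "lod_loq",
    "partition_cs",
    "indirect_cms",
    "accuracy_precision",
    "CSA_MASS_FRACTION",
]

#: Mass fraction of colistin A in the reference standard (colistin B takes
#: the complement).  Determined once per reference batch.
CSA_MASS_FRACTION = 0.301


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted polynomial calibration curve (results object).

    ``coefficients`` are intercept-first (c0, c1[, c2]) so that
    response = c0 + c1*x + c2*x^2; ``standard_errors`` align with them.
    ``conc_range`` is the fitted concentration range (ug/mL) and bounds both
    prediction warnings and the quadratic-root selection of ``invert``.
    """

    analyte: str
    order: int
    coefficients: np.ndarray
    standard_errors: np.ndarray
    r_squared: float
    conc_range: tuple[float, float]
    sse: float
    n_obs: int

    @property
    def slope(self) -> float:
        """First-order coefficient; the S of the LOD/LOQ formulas."""
        return float(self.coefficients[1])

    def predict(self, concentration):
        x = np.asarray(concentration, dtype=float)
        out = np.polynomial.polynomial.polyval(x, self.coefficients)
        return float(out) if out.ndim == 0 else out

    def invert(self, response: float) -> float:
        """Concentration producing ``response``; inverse of :meth:`predict`.

        Linear curves invert algebraically; quadratic curves take the unique
        real root of c2*x^2 + c1*x + (c0 - y) = 0 inside the calibration
        range (a monotone curve on the range guarantees at most one).
        """
        lo, hi = self.conc_range
        if self.order == 1:
            c0, c1 = self.coefficients
            x = (response - c0) / c1
            if not (lo - 1e-9 <= x <= hi + 1e-9):
                raise ValueError(
                    f"response {response:g} maps to {x:g} ug/mL, outside the "
                    f"calibrated range [{lo:g}, {hi:g}]"
                )
            return float(x)
        c0, c1, c2 = self.coefficients
        roots = np.roots([c2, c1, c0 - response])
        real = roots[np.abs(roots.imag) < 1e-9].real
        in_range = [r for r in real if lo - 1e-9 <= r <= hi + 1e-9]
        if len(in_range) != 1:
            raise ValueError(
                f"calibration inversion ambiguous: {len(in_range)} roots of the "
                f"quadratic lie in [{lo:g}, {hi:g}] for response {response:g}"
            )
        return float(in_range[0])

    def summary(self) -> str:
        terms = []
        names = ["", "x", "x^2"]
        for i in range(self.order, -1, -1):
            terms.append(
                f"{self.coefficients[i]:+.4g}(+/-{self.standard_errors[i]:.3g})"
                f"{names[i]}"
            )
        return (
            f"{self.analyte} calibration (order {self.order}, n = {self.n_obs}, "
            f"range {self.conc_range[0]:g}-{self.conc_range[1]:g} ug/mL)\n"
            f"  y = {' '.join(terms)}\n"
            f"  R^2 = {self.r_squared:.4f}"
        )


class CalibrationModel:
    """Least-squares polynomial calibration model.

    Parameters
    ----------
    concentrations, responses : array-like
        Paired calibration points (ug/mL, instrument response).
    order : {1, 2}
        Polynomial order; 1 for the colistin forms, 2 for CMS.
    analyte : str
        Label carried into the results object.
    """

    def __init__(self, concentrations, responses, order: int = 1, analyte: str = ""):
        x = np.asarray(concentrations, dtype=float)
        y = np.asarray(responses, dtype=float)
        if order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if x.size != y.size or x.size < order + 2:
            raise ValueError(f"need >= {order + 2} paired points for order {order}")
        if np.any(x <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(x).size < order + 1:
            raise ValueError(
                "rank-deficient design: too few distinct concentration levels"
            )
        self.x, self.y, self.order, self.analyte = x, y, int(order), analyte

    def fit(self) -> CalibrationCurve:
        X = np.vander(self.x, self.order + 1, increasing=True)
        coef, _, _, _ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ coef
        sse = float(resid @ resid)
        dof = self.x.size - (self.order + 1)
        cov = np.linalg.inv(X.T @ X) * (sse / dof) if dof > 0 else np.full(
            (self.order + 1, self.order + 1), np.nan
        )
        tss = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - sse / tss if tss > 0 else 1.0
        return CalibrationCurve(
            analyte=self.analyte,
            order=self.order,
            coefficients=coef,
            standard_errors=np.sqrt(np.diag(cov)),
            r_squared=max(0.0, min(1.0, r2)),
            conc_range=(float(self.x.min()), float(self.x.max())),
            sse=sse,
            n_obs=int(self.x.size),
        )


def fit_calibration(points, order: int = 1, analyte: str = "") -> CalibrationCurve:
    """Fit a calibration curve from (concentration, response) pairs."""
    x, y = zip(*points)
    return CalibrationModel(x, y, order=order, analyte=analyte).fit()


@dataclass(frozen=True)
class PooledCurveTest:
    """Extra sum-of-squares F test of replicate calibration curves."""

    F: float
    p_value: float
    pooled: CalibrationCurve
    sse_separate: float
    sse_pooled: float
    df_separate: int
    df_pooled: int

    @property
    def curves_differ(self) -> bool:
        return self.p_value < 0.05


def pool_curves_f_test(replicates, order: int = 1, analyte: str = "") -> PooledCurveTest:
    """Compare independent per-run calibration fits with one global fit.

    ``replicates`` is a sequence (>= 2) of point sets, each a list of
    (concentration, response) pairs.  The null model shares all coefficients
    across runs; the alternative fits each run separately.  Unequal designs
    across runs are allowed.  Identical replicates give F = 0, p = 1.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicate curves to pool")
    sep_sse = 0.0
    sep_df = 0
    all_pts = []
    for rep in replicates:
        curve = fit_calibration(rep, order=order, analyte=analyte)
        sep_sse += curve.sse
        sep_df += curve.n_obs - (order + 1)
        all_pts.extend(rep)
    pooled = fit_calibration(all_pts, order=order, analyte=analyte)
    pool_df = pooled.n_obs - (order + 1)
    num_df = pool_df - sep_df
    if sep_df <= 0 or num_df <= 0:
        raise ValueError("insufficient degrees of freedom for the F test")
    num = (pooled.sse - sep_sse) / num_df
    den = sep_sse / sep_df
    if den == 0.0:
        # identical duplicated data: no between- or within-curve variation
        F = 0.0 if num <= 1e-12 else np.inf
    else:
        F = max(num / den, 0.0)
    p = float(stats.f.sf(F, num_df, sep_df)) if np.isfinite(F) else 0.0
    return PooledCurveTest(
        F=float(F),
        p_value=p,
        pooled=pooled,
        sse_separate=sep_sse,
        sse_pooled=pooled.sse,
        df_separate=sep_df,
        df_pooled=pool_df,
    )


def lod_loq(sigma: float, slope: float) -> tuple[float, float]:
    """Limits of detection and quantitation: (3.3 sigma/S, 10 sigma/S)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if slope <= 0:
        raise ValueError("slope must be positive")
    return 3.3 * sigma / slope, 10.0 * sigma / slope


def partition_cs(
    total_cs: float, csa_fraction: float = CSA_MASS_FRACTION
) -> tuple[float, float]:
    """Split a total colistin amount into (colistin A, colistin B).

    Mass is conserved exactly: csa + csb == total_cs.
    """
    if total_cs < 0:
        raise ValueError("total colistin must be non-negative")
    if not 0 < csa_fraction < 1:
        raise ValueError("csa_fraction must lie in (0, 1)")
    csa = total_cs * csa_fraction
    return csa, total_cs - csa


def indirect_cms(
    cs_total: float, cs_before: float, hydrolysis_complete: bool = True
) -> tuple[float, bool]:
    """Circulating prodrug by difference: CS_total - CS_before hydrolysis.

    Returns ``(cms, caveat)``; ``caveat`` is True when the hydrolysis
    protocol was flagged sub-complete, in which case the difference
    underestimates the true CMS.
    """
    if cs_before < 0:
        raise ValueError("pre-hydrolysis colistin must be non-negative")
    if cs_total < cs_before:
        raise ValueError(
            f"assay inconsistency: CS after hydrolysis ({cs_total:g}) below "
            f"pre-hydrolysis CS ({cs_before:g}) implies negative CMS"
        )
    return cs_total - cs_before, not hydrolysis_complete


@dataclass(frozen=True)
class ValidationSummary:
    """Per-level accuracy and precision of the assay.

    One row per concentration level: ``pct_error`` is the worst absolute
    percent deviation of a run mean from nominal, ``repeatability_rsd`` the
    worst within-run %RSD, ``intermediate_rsd`` the %RSD of the run means
    (NaN when a single run).  ``sigma`` is the response standard deviation
    at the lowest level, the sigma of the LOD/LOQ formulas.
    """

    table: pd.DataFrame
    sigma: float

    def summary(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.2f}")


def accuracy_precision(measured: pd.DataFrame, nominal: dict) -> ValidationSummary:
    """Accuracy/precision summary from a level x run replicate table.

    Parameters
    ----------
    measured : DataFrame
        Columns ``level`` (nominal key), ``run`` (run label) and ``value``
        (measured concentration or response); >= 2 replicates per
        level-run cell.
    nominal : dict
        Nominal value per level; all must be non-zero.
    """
    required = {"level", "run", "value"}
    if not required <= set(measured.columns):
        raise ValueError(f"measured table needs columns {sorted(required)}")
    rows = []
    sigma = np.nan
    for level, grp in measured.groupby("level", sort=True):
        nom = nominal[level]
        if nom == 0:
            raise ValueError("nominal value of 0 leaves %error undefined")
        run_means, run_rsds = [], []
        for _, cell in grp.groupby("run"):
            v = cell["value"].to_numpy(dtype=float)
            if v.size < 2:
                run_rsds.append(np.nan)
            else:
                m = v.mean()
                run_rsds.append(100.0 * v.std(ddof=1) / m if m != 0 else np.nan)
            run_means.append(v.mean())
        run_means = np.asarray(run_means)
        pct_err = float(np.max(100.0 * np.abs(run_means - nom) / abs(nom)))
        inter = (
            float(100.0 * run_means.std(ddof=1) / run_means.mean())
            if run_means.size > 1
            else np.nan
        )
        rows.append(
            {
                "level": level,
                "nominal": nom,
                "pct_error": pct_err,
                "repeatability_rsd": float(np.nanmax(run_rsds))
                if not np.all(np.isnan(run_rsds))
                else np.nan,
                "intermediate_rsd": inter,
            }
        )
    table = pd.DataFrame(rows)
    low = table["level"].iloc[0]
    low_vals = measured.loc[measured["level"] == low, "value"].to_numpy(dtype=float)
    if low_vals.size > 1:
        sigma = float(low_vals.std(ddof=1))
    return ValidationSummary(table=table, sigma=sigma)
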