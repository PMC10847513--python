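"""Michaelis-Menten fitting, standard-addition quantification, LOD/LOQ,
and coupled-assay stoichiometry checks.

The double-reciprocal (Lineweaver-Burk) fit is unweighted ordinary least
squares of 1/v on 1/S, as drawn in classical plots; its heteroscedasticity
caveat is emitted as a warning and a nonlinear fit can always be
co-reported.  LOD/LOQ follow the 3*sigma / 10*sigma convention (the ratio
pins the convention; configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .errors import CalibrationError, KineticFitError, UndefinedRatioError

__all__ = [
    "KineticDataset",
    "KineticFit",
    "CalibrationSeries",
    "QuantResult",
    "fit_michaelis_menten",
    "standard_addition",
    "lod_loq",
    "stoichiometry_check",
]


@dataclass
class KineticDataset:
    """Initial-velocity data: substrate concentrations and rates."""

    substrate: np.ndarray  # mM
    rate: np.ndarray  # arbitrary units / min
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate.shape != self.rate.shape:
            raise KineticFitError("substrate and rate lengths differ")
        if np.any(self.substrate <= 0):
            raise KineticFitError("substrate concentrations must be > 0")
        if len(np.unique(self.substrate)) < 3:
            raise KineticFitError("need >= 3 distinct substrate concentrations")


@dataclass(frozen=True)
class KineticFit:
    km: float  # same unit as substrate (mM by convention)
    vmax: float
    km_se: float
    vmax_se: float
    r_squared: float
    method: str  # 'double_reciprocal' | 'nonlinear'
    flags: tuple[str, ...] = ()

    @property
    def km_um(self) -> float:
        """Km in μM when substrate was supplied in mM."""
        return self.km * 1000.0


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(
    data: KineticDataset, method: str = "double_reciprocal"
) -> KineticFit:
    """Fit Km and Vmax.

    ``double_reciprocal``: OLS of 1/v on 1/S; Km = slope/intercept and
    Vmax = 1/intercept, with delta-method standard errors.  ``nonlinear``:
    least squares on v = Vmax*S/(Km+S), initialised from the reciprocal
    fit when possible.
    """
    s, v = data.substrate, data.rate
    if method == "double_reciprocal":
        if np.any(v <= 0):
            raise KineticFitError(
                "nonpositive rates cannot be inverted; use method='nonlinear'"
            )
        warnings.warn(
            "double-reciprocal OLS weights low rates heavily (heteroscedastic);"
            " consider co-reporting the nonlinear fit",
            stacklevel=2,
        )
        x, y = 1.0 / s, 1.0 / v
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        intercept, slope = res.params
        cov = res.cov_params()
        flags = []
        if intercept <= 0:
            flags.append("fit-failure: nonpositive reciprocal intercept")
            km = slope / intercept if intercept != 0 else np.inf
            vmax = 1.0 / intercept if intercept != 0 else np.inf
            return KineticFit(km, vmax, np.nan, np.nan, res.rsquared,
                              "double_reciprocal", tuple(flags))
        km = slope / intercept
        vmax = 1.0 / intercept
        if abs(slope) < 1e-12 * max(1.0, abs(intercept)):
            flags.append("zero-order regime: Km -> 0")
        # delta method: km = b/a, vmax = 1/a with a=intercept, b=slope
        a, b = intercept, slope
        var_a, var_b = cov[0, 0], cov[1, 1]
        cov_ab = cov[0, 1]
        km_var = (var_b / a**2) + (b**2 * var_a / a**4) - 2 * b * cov_ab / a**3
        vmax_var = var_a / a**4
        return KineticFit(
            km=km,
            vmax=vmax,
            km_se=float(np.sqrt(max(km_var, 0.0))),
            vmax_se=float(np.sqrt(max(vmax_var, 0.0))),
            r_squared=float(res.rsquared),
            method="double_reciprocal",
            flags=tuple(flags),
        )
    if method == "nonlinear":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                init = fit_michaelis_menten(data, "double_reciprocal")
                p0 = [max(init.vmax, 1e-9), max(init.km, 1e-9)]
        except KineticFitError:
            p0 = [float(np.max(v)), float(np.median(s))]
        popt, pcov = curve_fit(_mm, s, v, p0=p0, maxfev=10000)
        vmax, km = popt
        resid = v - _mm(s, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        flags = []
        if km <= 0 or vmax <= 0:
            flags.append("fit-failure: nonpositive parameter")
        se = np.sqrt(np.diag(pcov))
        return KineticFit(
            km=float(km),
            vmax=float(vmax),
            km_se=float(se[1]),
            vmax_se=float(se[0]),
            r_squared=r2,
            method="nonlinear",
            flags=tuple(flags),
        )
    raise KineticFitError(f"unknown method {method!r}")


@dataclass
class CalibrationSeries:
    """Spiked-amount / detector-response series."""

    amount: np.ndarray  # pmol (or any amount unit)
    response: np.ndarray
    blank_sd: float = 0.0
    design: str = "standard_addition"  # or 'external'

    def __post_init__(self):
        self.amount = np.asarray(self.amount, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.amount.shape != self.response.shape:
            raise CalibrationError("amount and response lengths differ")
        if np.any(self.amount < 0):
            raise CalibrationError("amounts must be >= 0")
        if self.blank_sd < 0:
            raise CalibrationError("blank_sd must be >= 0")
        if self.design not in ("standard_addition", "external"):
            raise CalibrationError(f"unknown design {self.design!r}")


@dataclass(frozen=True)
class QuantResult:
    amount_per_assay: float
    amount_se: float
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    sigma: float
    lod: float | None = None
    loq: float | None = None
    per_gram: float | None = None  # amount / g fresh weight when mass given
    per_gram_se: float | None = None
    flags: tuple[str, ...] = ()


def standard_addition(
    series: CalibrationSeries, tissue_mass: float | None = None
) -> QuantResult:
    """Endogenous amount by x-intercept extrapolation of a spike series.

    OLS of response on added amount; endogenous amount = -x-intercept =
    intercept/slope, with first-order error propagation from the
    slope/intercept covariance.
    """
    if series.design != "standard_addition":
        raise CalibrationError("series design must be 'standard_addition'")
    if len(series.amount) < 3:
        raise CalibrationError("need >= 3 points for standard addition")
    if not np.any(series.amount == 0):
        raise CalibrationError("standard addition requires a zero-spike point")
    X = sm.add_constant(series.amount)
    res = sm.OLS(series.response, X).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise CalibrationError(f"calibration failure: slope {slope:.4g} <= 0")
    cov = res.cov_params()
    var_a, var_b, cov_ab = cov[0, 0], cov[1, 1], cov[0, 1]
    x0 = intercept / slope
    flags = []
    if x0 < 0:
        flags.append("negative endogenous estimate")
    x0_var = (var_a / slope**2) + (intercept**2 * var_b / slope**4) \
        - 2 * intercept * cov_ab / slope**3
    x0_se = float(np.sqrt(max(x0_var, 0.0)))
    per_gram = per_gram_se = None
    if tissue_mass is not None:
        if tissue_mass <= 0:
            raise CalibrationError("tissue mass must be > 0")
        per_gram = x0 / tissue_mass
        per_gram_se = x0_se / tissue_mass
    lod = loq = None
    if series.blank_sd is not None:
        lod, loq = lod_loq(slope, series.blank_sd)
    return QuantResult(
        amount_per_assay=float(x0),
        amount_se=x0_se,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(np.sqrt(var_b)),
        intercept_se=float(np.sqrt(var_a)),
        sigma=float(np.sqrt(res.scale)),
        lod=lod,
        loq=loq,
        per_gram=per_gram,
        per_gram_se=per_gram_se,
        flags=tuple(flags),
    )


def lod_loq(
    slope: float,
    blank_sd: float,
    k_lod: float = 3.0,
    k_loq: float = 10.0,
) -> tuple[float, float]:
    """Detection/quantification limits: k*sigma/slope (default 3 and 10)."""
    if slope <= 0:
        raise CalibrationError(f"slope must be > 0, got {slope}")
    if blank_sd < 0:
        raise CalibrationError("blank_sd must be >= 0")
    return k_lod * blank_sd / slope, k_loq * blank_sd / slope


def stoichiometry_check(
    product_a: float, product_b: float, tolerance: float = 0.15
) -> tuple[bool, float]:
    """Equimolarity check: pass iff |a/b - 1| <= tolerance."""
    if product_a < 0 or product_b < 0:
        raise UndefinedRatioError("amounts must be >= 0")
    if product_b == 0:
        raise UndefinedRatioError("product_b is zero; ratio undefined")
    ratio = product_a / product_b
    return abs(ratio - 1.0) <= tolerance, ratio
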