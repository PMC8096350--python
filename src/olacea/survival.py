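"""Parametric survival curves for progression-free and overall survival.

The state transitions of the cohort model are driven by parametric
survival functions fitted to digitized Kaplan-Meier coordinates.  Five
families are supported, all in *rate form* with a shape ``gamma`` and a
rate-like scale ``lam`` (time in months unless stated otherwise):

========== =======================================  =====================
family     S(t)                                     median
========== =======================================  =====================
exponential  exp(-lam * t)                          ln(2)/lam
weibull      exp(-lam * t**gamma)                   (ln(2)/lam)**(1/gamma)
gompertz     exp(-lam/gamma * (exp(gamma*t) - 1))   ln(1+gamma*ln2/lam)/gamma
loglogistic  1 / (1 + lam * t**gamma)               (1/lam)**(1/gamma)
lognormal    1 - Phi((ln t - ln scale)/shape)       scale
========== =======================================  =====================

The log-logistic rate form is the base-case family: with time in months
it reproduces the source trial's published medians from the shipped
shape/scale pairs (e.g. placebo PFS ~4.0 months, placebo OS ~18.4
months), whereas a "scale = characteristic time" reading would imply
sub-day medians.  The convention is carried explicitly on each curve via
``time_unit`` rather than hard-coded downstream.

For the Gompertz family the shape may be any real number (negative shape
gives a defective distribution with a surviving fraction ``exp(lam/gamma)``);
for the log-normal, ``shape`` is the log-scale standard deviation and
``scale`` the median time.  Both are used only during model selection,
never in the base case.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SurvivalFamily",
    "ParametricSurvival",
    "KMCurvePoints",
    "FitResult",
    "InsufficientDataError",
    "FitConvergenceError",
    "CohortExhaustedError",
    "survival_at",
    "median_survival",
    "transition_probability",
    "fit_curve",
    "fit_all_families",
    "select_best_model",
    "fit_ipd_mle",
    "read_km_csv",
    "write_km_csv",
]


class SurvivalFamily(str, enum.Enum):
    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    GOMPERTZ = "gompertz"
    LOGLOGISTIC = "loglogistic"
    LOGNORMAL = "lognormal"


#: Number of free parameters per family (exponential has no shape).
N_FREE_PARAMS: Mapping[SurvivalFamily, int] = {
    SurvivalFamily.EXPONENTIAL: 1,
    SurvivalFamily.WEIBULL: 2,
    SurvivalFamily.GOMPERTZ: 2,
    SurvivalFamily.LOGLOGISTIC: 2,
    SurvivalFamily.LOGNORMAL: 2,
}

#: Fixed order used to break exact-AIC ties in model selection.
FAMILY_TIEBREAK_ORDER: Sequence[SurvivalFamily] = (
    SurvivalFamily.EXPONENTIAL,
    SurvivalFamily.WEIBULL,
    SurvivalFamily.LOGLOGISTIC,
    SurvivalFamily.LOGNORMAL,
    SurvivalFamily.GOMPERTZ,
)


class InsufficientDataError(ValueError):
    """Too few usable (0 < S < 1, t > 0) points to fit a curve."""


class FitConvergenceError(RuntimeError):
    """Nonlinear refinement failed; carries the linearized estimate."""

    def __init__(self, message: str, linearized: "FitResult" | None = None):
        super().__init__(message)
        self.linearized = linearized


class CohortExhaustedError(ZeroDivisionError):
    """Conditional transition probability requested from S(t_start) = 0."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival curve in rate form.

    Parameters
    ----------
    family : SurvivalFamily
    shape : float
        gamma; dimensionless.  Ignored by the exponential family (keep 1.0).
        Any real for Gompertz, strictly positive otherwise.
    scale : float
        lam; rate-like, units time**(-gamma) for the Weibull/log-logistic
        rate forms.  Strictly positive.
    time_unit : str
        Unit of ``t`` as the curve is parameterized: "months" (default),
        "days" or "years".
    """

    family: SurvivalFamily
    shape: float
    scale: float
    time_unit: str = "months"

    def __post_init__(self) -> None:
        family = SurvivalFamily(self.family)
        object.__setattr__(self, "family", family)
        if not (math.isfinite(self.shape) and math.isfinite(self.scale)):
            raise ValueError("survival parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if family is not SurvivalFamily.GOMPERTZ and self.shape <= 0:
            raise ValueError(f"shape must be > 0 for {family.value}, got {self.shape}")
        if self.time_unit not in ("months", "days", "years"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")

    # -- evaluation ------------------------------------------------------

    def survival(self, t):
        """S(t) for scalar or array t >= 0 (in this curve's time unit)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("survival requires t >= 0")
        gamma, lam = self.shape, self.scale
        with np.errstate(divide="ignore", over="ignore"):
            if self.family is SurvivalFamily.EXPONENTIAL:
                s = np.exp(-lam * t_arr)
            elif self.family is SurvivalFamily.WEIBULL:
                s = np.exp(-lam * t_arr**gamma)
            elif self.family is SurvivalFamily.GOMPERTZ:
                if gamma == 0.0:  # exponential limit
                    cumhaz = lam * t_arr
                else:
                    cumhaz = lam * np.expm1(gamma * t_arr) / gamma
                s = np.exp(-cumhaz)
            elif self.family is SurvivalFamily.LOGLOGISTIC:
                s = 1.0 / (1.0 + lam * t_arr**gamma)
            else:  # lognormal: shape = sigma, scale = median time
                s = np.where(
                    t_arr > 0,
                    stats.norm.sf((np.log(np.maximum(t_arr, 1e-300)) - math.log(lam)) / gamma),
                    1.0,
                )
        s = np.clip(s, 0.0, 1.0)
        return float(s) if np.isscalar(t) or np.ndim(t) == 0 else s

    def median(self) -> float:
        """Time at which S(t) = 0.5; ``inf`` if never reached."""
        gamma, lam = self.shape, self.scale
        ln2 = math.log(2.0)
        if self.family is SurvivalFamily.EXPONENTIAL:
            return ln2 / lam
        if self.family is SurvivalFamily.WEIBULL:
            return (ln2 / lam) ** (1.0 / gamma)
        if self.family is SurvivalFamily.LOGLOGISTIC:
            return (1.0 / lam) ** (1.0 / gamma)
        if self.family is SurvivalFamily.LOGNORMAL:
            return lam
        # Gompertz: cumulative hazard lam/gamma*(e^{gamma t}-1) = ln 2
        if gamma == 0.0:
            return ln2 / lam
        arg = 1.0 + gamma * ln2 / lam
        if arg <= 0.0:  # defective: plateau above 0.5, median never reached
            return math.inf
        return math.log(arg) / gamma

    def transition_probability(self, t_start: float, t_end: float) -> float:
        """Conditional probability of the event in (t_start, t_end].

        ``1 - S(t_end)/S(t_start)``, clamped to [0, 1].
        """
        if t_start < 0 or t_end < t_start:
            raise ValueError("require 0 <= t_start <= t_end")
        s0 = self.survival(t_start)
        if s0 <= 0.0:
            raise CohortExhaustedError(
                f"S({t_start}) = 0: the cohort is exhausted, conditional "
                "transition probability is undefined"
            )
        p = 1.0 - self.survival(t_end) / s0
        return min(max(p, 0.0), 1.0)


# -- module-level functional wrappers -----------------------------------


def survival_at(model: ParametricSurvival, t) -> float:
    """S(t) of ``model`` at time ``t`` (model's own time unit)."""
    return model.survival(t)


def median_survival(model: ParametricSurvival) -> float:
    """Median survival time (closed form; ``inf`` when S plateaus above 0.5)."""
    return model.median()


def transition_probability(model: ParametricSurvival, t_start: float, t_end: float) -> float:
    """Conditional event probability 1 - S(t_end)/S(t_start), clamped to [0,1]."""
    return model.transition_probability(t_start, t_end)


# -- digitized KM coordinates -------------------------------------------


@dataclass(frozen=True)
class KMCurvePoints:
    """Digitized Kaplan-Meier coordinates for one endpoint and arm.

    Times are strictly increasing and survival values lie in [0, 1];
    digitization jitter can make raw values non-monotone, which
    :meth:`repair_monotonic` fixes by a running minimum while the raw
    points stay untouched on the original object.
    """

    endpoint: str  # "PFS" | "OS"
    arm: str  # "olaparib" | "placebo"
    time: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time and survival must be 1-D arrays of equal length")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "survival", s)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def is_monotonic(self) -> bool:
        return bool(np.all(np.diff(self.survival) <= 0))

    def repair_monotonic(self) -> "KMCurvePoints":
        """Enforce non-increasing survival by a running minimum."""
        return KMCurvePoints(
            self.endpoint, self.arm, self.time, np.minimum.accumulate(self.survival)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "endpoint": self.endpoint,
                "arm": self.arm,
                "time_months": self.time,
                "survival": self.survival,
            }
        )


def read_km_csv(path) -> list[KMCurvePoints]:
    """Read KM coordinates from a headered CSV (endpoint, arm, time_months, survival)."""
    df = pd.read_csv(path, comment="#")
    required = {"endpoint", "arm", "time_months", "survival"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"KM CSV is missing columns: {sorted(missing)}")
    curves = []
    for (endpoint, arm), grp in df.groupby(["endpoint", "arm"], sort=False):
        grp = grp.sort_values("time_months")
        curves.append(
            KMCurvePoints(
                str(endpoint),
                str(arm),
                grp["time_months"].to_numpy(),
                grp["survival"].to_numpy(),
            )
        )
    return curves


def write_km_csv(curves: Iterable[KMCurvePoints], path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(path, index=False)


# -- fitting -------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """A fitted survival curve with its objective value and AIC."""

    model: ParametricSurvival
    objective_label: str  # "sse" (survival-scale least squares) or "loglik"
    objective_value: float
    aic: float
    n_points: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.aic):
            raise ValueError("AIC must be finite")
        if self.n_points < N_FREE_PARAMS[self.model.family] + 1:
            raise ValueError("need at least one more point than free parameters")

    @property
    def n_free_params(self) -> int:
        return N_FREE_PARAMS[self.model.family]

    def to_record(self) -> dict:
        return {
            "family": self.model.family.value,
            "shape": self.model.shape,
            "scale": self.model.scale,
            "aic": self.aic,
            "objective": self.objective_label,
            "objective_value": self.objective_value,
            "n_points": self.n_points,
        }


def _linearized_init(family: SurvivalFamily, t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Initial (shape, scale) from the family's linearizing transform.

    Weibull: ln(-ln S) = ln lam + gamma ln t; log-logistic:
    logit(1 - S) = ln lam + gamma ln t; log-normal: probit(1 - S) linear
    in ln t.  Exponential: least squares of -ln S on t through the
    origin.  Gompertz has no linearization; start from the exponential
    rate with a small positive shape.
    """
    log_t = np.log(t)
    if family is SurvivalFamily.EXPONENTIAL:
        lam = float(np.sum(t * (-np.log(s))) / np.sum(t * t))
        return 1.0, max(lam, 1e-12)
    if family is SurvivalFamily.WEIBULL:
        y = np.log(-np.log(s))
    elif family is SurvivalFamily.LOGLOGISTIC:
        y = np.log((1.0 - s) / s)
    elif family is SurvivalFamily.LOGNORMAL:
        y = stats.norm.ppf(1.0 - s)
    else:  # gompertz
        lam = float(np.sum(t * (-np.log(s))) / np.sum(t * t))
        return 0.01, max(lam, 1e-12)
    slope, intercept = np.polyfit(log_t, y, 1)
    if family is SurvivalFamily.LOGNORMAL:
        if slope <= 0:  # degenerate digitization; fall back to a broad start
            return 1.0, float(np.exp(np.median(log_t)))
        sigma = 1.0 / slope
        mu = -intercept * sigma
        return sigma, float(np.exp(mu))
    gamma = max(float(slope), 1e-6)
    lam = float(np.exp(intercept))
    return gamma, max(lam, 1e-300)


def _pack(family: SurvivalFamily, shape: float, scale: float) -> np.ndarray:
    if family is SurvivalFamily.EXPONENTIAL:
        return np.array([math.log(scale)])
    if family is SurvivalFamily.GOMPERTZ:  # shape unconstrained
        return np.array([shape, math.log(scale)])
    return np.array([math.log(shape), math.log(scale)])


def _unpack(family: SurvivalFamily, theta: np.ndarray) -> tuple[float, float]:
    if family is SurvivalFamily.EXPONENTIAL:
        return 1.0, float(np.exp(theta[0]))
    if family is SurvivalFamily.GOMPERTZ:
        return float(theta[0]), float(np.exp(theta[1]))
    return float(np.exp(theta[0])), float(np.exp(theta[1]))


def _sse(family: SurvivalFamily, shape: float, scale: float, t: np.ndarray, s: np.ndarray) -> float:
    model = ParametricSurvival(family, shape, scale)
    resid = model.survival(t) - s
    return float(np.dot(resid, resid))


def _aic_from_sse(sse: float, n: int, k: int) -> float:
    # Gaussian least-squares AIC; SSE floored so a machine-perfect fit
    # still yields a finite (very negative) criterion.
    return n * math.log(max(sse, 1e-300) / n) + 2 * k


def fit_curve(
    points: KMCurvePoints,
    family: SurvivalFamily | str,
    refine: bool = True,
) -> FitResult:
    """Fit one parametric family to digitized KM coordinates.

    The closed-form linearizing transform of the family gives the
    starting values; these are then refined by nonlinear least squares
    on the survival scale (the objective actually reported).  AIC is the
    Gaussian least-squares form ``n*ln(SSE/n) + 2k``.

    Points with S = 0, S = 1 or t = 0 carry no information on the
    linearized scale and are excluded; at least three usable points (and
    more than the number of free parameters) are required.

    Raises
    ------
    InsufficientDataError
        Fewer than three usable points.
    FitConvergenceError
        The nonlinear refinement failed; the exception carries the
        linearized estimate in ``.linearized``.
    """
    family = SurvivalFamily(family)
    mask = (points.time > 0) & (points.survival > 0) & (points.survival < 1)
    t = points.time[mask]
    s = points.survival[mask]
    k = N_FREE_PARAMS[family]
    if len(t) < max(3, k + 1):
        raise InsufficientDataError(
            f"need >= {max(3, k + 1)} points with t > 0 and 0 < S < 1, got {len(t)}"
        )
    n = len(t)

    shape0, scale0 = _linearized_init(family, t, s)
    lin_model = ParametricSurvival(family, shape0, scale0, points_time_unit(points))
    lin_sse = _sse(family, shape0, scale0, t, s)
    lin_result = FitResult(lin_model, "sse", lin_sse, _aic_from_sse(lin_sse, n, k), n)
    if not refine:
        return lin_result

    def residuals(theta: np.ndarray) -> np.ndarray:
        shape, scale = _unpack(family, theta)
        model = ParametricSurvival(family, shape, scale)
        return model.survival(t) - s

    try:
        sol = optimize.least_squares(
            residuals, _pack(family, shape0, scale0), method="lm", max_nfev=10_000
        )
    except Exception as exc:  # numerical blow-up inside the solver
        raise FitConvergenceError(f"{family.value} refinement failed: {exc}", lin_result)
    if not sol.success:
        raise FitConvergenceError(
            f"{family.value} refinement did not converge: {sol.message}", lin_result
        )
    shape, scale = _unpack(family, sol.x)
    sse = _sse(family, shape, scale, t, s)
    if sse > lin_sse:  # refinement may not worsen the objective
        shape, scale, sse = shape0, scale0, lin_sse
    model = ParametricSurvival(family, shape, scale, points_time_unit(points))
    return FitResult(model, "sse", sse, _aic_from_sse(sse, n, k), n)


def points_time_unit(points: KMCurvePoints) -> str:
    """KM CSV times are months by contract (column ``time_months``)."""
    return "months"


def fit_all_families(
    points: KMCurvePoints,
    families: Sequence[SurvivalFamily | str] = tuple(FAMILY_TIEBREAK_ORDER),
) -> list[FitResult]:
    """Fit every requested family; families whose refinement fails are
    dropped with a warning (their linearized estimate is not entered
    into model selection)."""
    fits = []
    for family in families:
        try:
            fits.append(fit_curve(points, family))
        except FitConvergenceError as exc:
            warnings.warn(f"dropping {SurvivalFamily(family).value}: {exc}", stacklevel=2)
    if not fits:
        raise FitConvergenceError("no family converged on these points")
    return fits


def select_best_model(fits: Sequence[FitResult]) -> FitResult:
    """Minimum-AIC fit; exact ties go to fewer parameters, then to the
    fixed family order (exponential, weibull, loglogistic, lognormal,
    gompertz)."""
    if not fits:
        raise ValueError("select_best_model requires at least one fit")
    order = list(FAMILY_TIEBREAK_ORDER)
    return min(
        fits,
        key=lambda f: (f.aic, f.n_free_params, order.index(f.model.family)),
    )


# -- alternative MLE backend (validation only) ---------------------------

_LIFELINES_FITTERS: dict[SurvivalFamily, str] = {
    SurvivalFamily.EXPONENTIAL: "ExponentialFitter",
    SurvivalFamily.WEIBULL: "WeibullFitter",
    SurvivalFamily.LOGLOGISTIC: "LogLogisticFitter",
    SurvivalFamily.LOGNORMAL: "LogNormalFitter",
}


def fit_ipd_mle(time, event, family: SurvivalFamily | str) -> FitResult:
    """Maximum-likelihood fit on (pseudo) individual-patient data.

    A validation backend, not the default fitting route: lifelines does
    the likelihood work and the result is converted to the rate-form
    parameterization used here.  Gompertz is not supported.
    """
    import lifelines

    family = SurvivalFamily(family)
    if family not in _LIFELINES_FITTERS:
        raise NotImplementedError(f"MLE backend does not support {family.value}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    fitter = getattr(lifelines, _LIFELINES_FITTERS[family])()
    fitter.fit(time, event_observed=event)
    if family is SurvivalFamily.EXPONENTIAL:
        shape, scale = 1.0, 1.0 / fitter.lambda_
    elif family is SurvivalFamily.WEIBULL:
        shape = fitter.rho_
        scale = fitter.lambda_ ** (-fitter.rho_)
    elif family is SurvivalFamily.LOGLOGISTIC:
        shape = fitter.beta_
        scale = fitter.alpha_ ** (-fitter.beta_)
    else:  # lognormal
        shape = fitter.sigma_
        scale = math.exp(fitter.mu_)
    model = ParametricSurvival(family, float(shape), float(scale))
    loglik = float(fitter.log_likelihood_)
    k = N_FREE_PARAMS[family]
    return FitResult(model, "loglik", loglik, -2.0 * loglik + 2 * k, len(time))
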