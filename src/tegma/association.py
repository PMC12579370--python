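"""Association between the early reaction time and later TEG parameters.

Each relationship is summarized three ways, mirroring standard practice for
viscoelastic-assay method studies:

* Pearson product-moment correlation with a two-sided t-based p-value;
* a mean-structure fit — a three-parameter exponential decay
  ``y = a * exp(-b * x) + c`` for the maximum-amplitude (MA) channels, or an
  ordinary least-squares line for the device-derived activated clotting time
  (TEG-ACT), which is an affine re-expression of the reaction time;
* goodness-of-fit diagnostics: R², mean absolute error (MAE) and root mean
  square error (RMSE) of the fitted curve.

The decay model is fitted by nonlinear least squares with the decay rate
``b`` kept positive through a log parameterization (a sign flip on ``b``
paired with a sign flip on ``a`` reproduces the same curve family, so the
constraint is an identifiability choice, not a restriction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError, FitFailure

__all__ = [
    "ExpDecayModel",
    "LinearModel",
    "FitDiagnostics",
    "pearson_correlation",
    "fit_exp_decay",
    "fit_linear",
    "goodness_of_fit",
]

#: iteration cap for the nonlinear solver (documented so bootstrap failure
#: accounting is reproducible); least_squares counts function evaluations,
#: roughly n_params + 1 per iteration.
MAX_ITER = 200
#: relative reduction in the sum of squared residuals at convergence
SSE_RTOL = 1e-10


@dataclass(frozen=True)
class ExpDecayModel:
    """Parameters of ``y = a * exp(-b * x) + c``.

    ``a`` is the initial offset from the asymptote (may be negative for an
    increasing curve), ``b`` the decay rate per minute (always positive),
    ``c`` the asymptotic value in outcome units.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"decay rate b must be positive, got {self.b}")
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("model parameters must be finite")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(-self.b * x) + self.c


@dataclass(frozen=True)
class LinearModel:
    """Parameters of ``y = slope * x + intercept``."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.slope, self.intercept])):
            raise ValueError("model parameters must be finite")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class FitDiagnostics:
    """Correlation and accuracy summary of one fitted relationship.

    ``r`` is the signed Pearson correlation between predictor and outcome
    (its absolute value is what abstract-style summaries report); ``r2`` is
    the coefficient of determination of the fitted curve, 1 - SS_res/SS_tot.
    """

    r: float
    p_value: float
    r2: float
    mae: float
    rmse: float
    n: int


def _validated_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DegenerateDataError(
            f"x and y must be paired: {x.size} vs {y.size} values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateDataError("non-finite values in paired data")
    if x.size < min_n:
        raise DegenerateDataError(
            f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p-value.

    The p-value comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2``
    degrees of freedom. Raises :class:`DegenerateDataError`, naming the
    degenerate variable, when either input has zero variance.
    """
    x, y = _validated_pair(x, y, min_n=3)
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise DegenerateDataError(
                f"correlation undefined: {name} has zero variance",
                variable=name)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def goodness_of_fit(model, x, y) -> FitDiagnostics:
    """Diagnostics of ``model`` against paired data.

    ``r2 = 1 - SS_res / SS_tot``; when SS_tot is zero (constant outcome) r2
    is reported as 0 with a warning rather than failing, and the Pearson
    correlation is likewise reported as 0 (p = 1) by convention.
    """
    x, y = _validated_pair(x, y, min_n=2)
    resid = y - model.predict(x)
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant outcome: R^2 undefined, reported as 0",
                      stacklevel=2)
        return FitDiagnostics(r=0.0, p_value=1.0, r2=0.0,
                              mae=mae, rmse=rmse, n=int(x.size))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    if np.ptp(x) == 0:
        warnings.warn("constant predictor: correlation undefined, "
                      "reported as 0", stacklevel=2)
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(x, y)
    return FitDiagnostics(r=float(r), p_value=float(p), r2=r2,
                          mae=mae, rmse=rmse, n=int(x.size))


def _initial_guess(x, y) -> tuple[float, float, float]:
    # Decreasing curves (MA channels) start near max(y) and decay toward
    # min(y); the one increasing channel (CKH-R) has a < 0. The trend sign is
    # read off the raw correlation.
    increasing = np.corrcoef(x, y)[0, 1] > 0
    y_range = float(np.ptp(y))
    if increasing:
        c0 = float(np.max(y))
        a0 = -y_range
    else:
        c0 = float(np.min(y))
        a0 = y_range
    if a0 == 0.0:
        a0 = 1.0
    b0 = 1.0 / max(float(np.ptp(x)), 1e-12)
    return a0, b0, c0


def fit_exp_decay(x, y, init: tuple[float, float, float] | None = None,
                  ) -> tuple[ExpDecayModel, FitDiagnostics]:
    """Least-squares fit of ``y = a * exp(-b * x) + c``.

    Minimizes the sum of squared residuals with Levenberg-Marquardt over
    ``(a, log b, c)``. ``init``, when given, is an ``(a, b, c)`` starting
    point (the bootstrap passes the full-sample estimate); otherwise a
    range-based heuristic is used. Deterministic given data and init.

    Raises :class:`FitFailure` carrying the best-so-far parameters when the
    solver stops without converging, and :class:`DegenerateDataError` for
    unusable data (fewer than 4 distinct x values).
    """
    x, y = _validated_pair(x, y, min_n=4)
    if np.unique(x).size < 4:
        raise DegenerateDataError(
            "need at least 4 distinct predictor values for a 3-parameter fit",
            variable="x")

    if init is None:
        a0, b0, c0 = _initial_guess(x, y)
    else:
        a0, b0, c0 = (float(v) for v in init)
        if b0 <= 0:
            raise ValueError("init decay rate must be positive")
    theta0 = np.array([a0, np.log(b0), c0])

    def residuals(theta):
        a, log_b, c = theta
        return a * np.exp(-np.exp(log_b) * x) + c - y

    res = optimize.least_squares(
        residuals, theta0, method="lm",
        ftol=SSE_RTOL, xtol=1e-12, gtol=1e-12,
        max_nfev=MAX_ITER * (theta0.size + 1),
    )
    a, log_b, c = res.x
    sse = float(2.0 * res.cost)
    best = (float(a), float(np.exp(log_b)), float(c))
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitFailure(
            f"decay fit did not converge ({res.message})",
            best_params=best, sse=sse)
    model = ExpDecayModel(*best)
    return model, goodness_of_fit(model, x, y)


def fit_linear(x, y) -> tuple[LinearModel, FitDiagnostics]:
    """Ordinary least squares line via the closed form.

    For a fitted line R² equals the squared Pearson correlation exactly. A
    constant outcome yields slope 0 with R² reported as 0 (see
    :func:`goodness_of_fit`); identical x values are a degenerate design.
    """
    x, y = _validated_pair(x, y, min_n=2)
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            "all predictor values identical: line is not identifiable",
            variable="x")
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    model = LinearModel(slope, intercept)
    return model, goodness_of_fit(model, x, y)
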