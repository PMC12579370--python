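"""Clinically anchored reaction-time cutoffs.

The decay model ties the early CRT-R reading to the eventual clot-strength
plateau, so a clinical maximum-amplitude target ``y*`` maps back to a
reaction-time threshold by inverting the fitted curve:

    x* = -(1/b) * ln((y* - c) / a)

Uncertainty in ``x*`` is quantified by a nonparametric bootstrap: resample
measurement pairs with replacement, refit the decay model, re-invert, and
summarize the resulting cutoff distribution by its 2.5/25/50/75/97.5
percentiles (interquartile range and 95% confidence interval). The cutoff is
then assessed as a binary screen: a run is called at-risk when its CRT-R
exceeds the cutoff, and truly at-risk when its MA falls below the target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .association import ExpDecayModel, fit_exp_decay
from .errors import BootstrapUnstableError, FitFailure, NoSolutionError
from .reference import ACT_PLAUSIBLE_RANGE, ACT_TO_CRT_R_LINE

__all__ = [
    "CutoffEstimate",
    "ConfusionMetrics",
    "invert_exp_decay",
    "bootstrap_cutoff",
    "classify_at_cutoff",
    "act_to_crt_r",
    "crt_r_to_act",
]

#: minimum fraction of bootstrap replicates that must yield a cutoff
SUCCESS_FLOOR = 0.9


@dataclass(frozen=True)
class CutoffEstimate:
    """Inverted reaction-time threshold with its bootstrap summary.

    ``point`` is the inversion of the full-sample fit; ``boot_median`` is the
    headline cutoff (the median of the bootstrap distribution), flanked by
    the bootstrap interquartile range and 95% percentile interval. All
    cutoff values are in minutes.
    """

    y_target: float
    point: float
    boot_median: float
    boot_q25: float
    boot_q75: float
    boot_ci_lo: float
    boot_ci_hi: float
    n_boot_requested: int
    n_boot_succeeded: int

    def __post_init__(self) -> None:
        ordered = (self.boot_ci_lo <= self.boot_q25 <= self.boot_median
                   <= self.boot_q75 <= self.boot_ci_hi)
        if not ordered:
            raise ValueError("bootstrap percentiles out of order")
        if self.n_boot_succeeded > self.n_boot_requested:
            raise ValueError("more successes than requested replicates")


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 diagnostic performance at a cutoff.

    Positive means the outcome MA lies below the clinical target. A metric
    whose denominator is zero is ``None`` (flagged undefined) rather than an
    error; the remaining metrics are still reported.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None


def invert_exp_decay(model: ExpDecayModel, y_target: float) -> float:
    """Solve ``a * exp(-b x) + c = y_target`` for x.

    The curve is strictly monotone (b > 0), so the solution is unique when
    it exists: the target must lie strictly between the asymptote ``c`` and
    the same side as ``a`` points. Otherwise :class:`NoSolutionError` is
    raised — deliberately distinct from a fit failure.
    """
    ratio = (y_target - model.c) / model.a
    if not ratio > 0:
        raise NoSolutionError(
            f"target {y_target} is not reachable by the fitted curve "
            f"(asymptote {model.c:.4g}, initial offset {model.a:.4g})")
    return -math.log(ratio) / model.b


def bootstrap_cutoff(x, y, y_target: float, n_boot: int = 1000,
                     seed: int | np.random.Generator | None = None,
                     ) -> CutoffEstimate:
    """Percentile-bootstrap distribution of the inverted cutoff.

    ``x`` are CRT-R values (min), ``y`` the paired outcome values (already
    preprocessed: no missing entries, outliers excluded). Resampling is at
    the measurement-pair level. Each replicate refits the decay model
    starting from the full-sample estimate and inverts it at ``y_target``;
    replicates whose fit fails or whose refitted curve cannot reach the
    target are discarded and counted. Percentiles use linear interpolation
    between order statistics (the same convention as the cohort summaries).

    Raises :class:`BootstrapUnstableError` (carrying the partial cutoff
    distribution) when fewer than 90% of replicates succeed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    full_model, _ = fit_exp_decay(x, y)
    point = invert_exp_decay(full_model, y_target)
    init = (full_model.a, full_model.b, full_model.c)

    n = x.size
    cutoffs: list[float] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            model, _ = fit_exp_decay(x[idx], y[idx], init=init)
            cutoffs.append(invert_exp_decay(model, y_target))
        except (FitFailure, NoSolutionError):
            continue
    n_ok = len(cutoffs)
    if n_ok < SUCCESS_FLOOR * n_boot:
        raise BootstrapUnstableError(
            f"only {n_ok}/{n_boot} bootstrap replicates produced a cutoff",
            cutoffs=cutoffs, n_requested=n_boot, n_succeeded=n_ok)

    lo, q25, med, q75, hi = np.percentile(
        cutoffs, [2.5, 25, 50, 75, 97.5], method="linear")
    return CutoffEstimate(
        y_target=float(y_target), point=float(point),
        boot_median=float(med), boot_q25=float(q25), boot_q75=float(q75),
        boot_ci_lo=float(lo), boot_ci_hi=float(hi),
        n_boot_requested=n_boot, n_boot_succeeded=n_ok)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def classify_at_cutoff(crt_r, cutoff: float, ma, y_target: float,
                       ) -> ConfusionMetrics:
    """Evaluate the cutoff as a screen for low clot strength.

    Predicted positive iff ``crt_r > cutoff`` (strict — a run exactly at the
    cutoff is called negative); actually positive iff ``ma < y_target``
    (strict).
    """
    crt_r = np.asarray(crt_r, dtype=float).ravel()
    ma = np.asarray(ma, dtype=float).ravel()
    if crt_r.shape != ma.shape:
        raise ValueError("crt_r and ma must be paired")
    if np.isnan(crt_r).any() or np.isnan(ma).any():
        raise ValueError("classification requires non-missing pairs")
    pred = crt_r > cutoff
    actual = ma < y_target
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    tn = int(np.sum(~pred & ~actual))
    fn = int(np.sum(~pred & actual))
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn))


def _warn_if_implausible(act: np.ndarray) -> None:
    lo, hi = ACT_PLAUSIBLE_RANGE
    if np.any((act < lo) | (act > hi)):
        warnings.warn(
            f"TEG-ACT outside the observed range {lo:g}-{hi:g} s: the "
            "linear conversion is an extrapolation", stacklevel=3)


def act_to_crt_r(act):
    """Convert TEG-ACT (s) to the equivalent CRT-R (min).

    Pure arithmetic through the device's linear relationship; values outside
    the observed 60-199 s range convert with a warning, not a failure.
    """
    act_arr = np.asarray(act, dtype=float)
    _warn_if_implausible(np.atleast_1d(act_arr))
    out = ACT_TO_CRT_R_LINE.predict(act_arr)
    return float(out) if np.isscalar(act) or act_arr.ndim == 0 else out


def crt_r_to_act(crt_r):
    """Exact algebraic inverse of :func:`act_to_crt_r` (min -> s)."""
    crt_arr = np.asarray(crt_r, dtype=float)
    line = ACT_TO_CRT_R_LINE
    out = (crt_arr - line.intercept) / line.slope
    _warn_if_implausible(np.atleast_1d(out))
    return float(out) if np.isscalar(crt_r) or crt_arr.ndim == 0 else out
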