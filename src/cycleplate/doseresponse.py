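"""Robust constrained four-parameter-logistic dose-response fitting.

The model is the decreasing (inhibition) 4PL on percent-of-control data:

    y(x) = bottom + span / (1 + 10**(hill * (x - log_ec50)))

with x = log10 concentration (molar), top = bottom + span, and the box
constraints 20 < span < 100 and 0.5 < hill < 4 enforced by a sigmoid
reparameterization (so every returned fit satisfies them strictly).

Fitting minimizes a Tukey-biweight robust loss (tuning constant 4.685 times
a robust residual scale, the normalized median absolute deviation,
re-estimated at each iteration) by iteratively reweighted nonlinear least
squares.  A deterministic multi-start grid over initial log EC50 (every 0.5
log unit across the tested range) and Hill slope (1 and 2) protects against
local minima; the best solution by final robust loss wins, with ties broken
by smaller Hill slope, then smaller |log EC50|.

Fit acceptance follows screening practice: the robust residual RMSE must be
below 1.5x the global assay noise (the standard deviation of percent-of-
control values across vehicle-control wells) and the standard error of
log EC50, from the robust-weighted linearized covariance, must be below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

__all__ = [
    "LogisticFit",
    "DoseResponseSeries",
    "NonmonotonicResult",
    "fit_4pl_robust",
    "fit_4pl_least_squares",
    "assess_validity",
    "derive_potency",
    "detect_nonmonotonic",
    "logistic4",
    "tukey_loss",
]

SPAN_BOUNDS = (20.0, 100.0)
HILL_BOUNDS = (0.5, 4.0)
TUKEY_C = 4.685
_MIN_DISTINCT_CONC = 6


@dataclass(frozen=True)
class DoseResponseSeries:
    """One compound/readout dose-response series (percent-of-control)."""

    compound: str
    readout: str
    log_conc: np.ndarray      # log10 molar
    response: np.ndarray      # percent of control
    replicate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.log_conc, dtype=float)
        y = np.asarray(self.response, dtype=float)
        if x.shape != y.shape:
            raise ValueError("log_conc and response must have the same shape")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("series values must be finite")
        object.__setattr__(self, "log_conc", x)
        object.__setattr__(self, "response", y)


@dataclass(frozen=True)
class LogisticFit:
    """Constrained 4PL fit result with robust diagnostics and potency values."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    span: float
    rmse_robust: float
    se_log_ec50: float
    loss: float
    scale: float = float("nan")   # final robust residual scale (normalized MAD)
    converged: bool = False
    valid: bool = False
    reason: str = ""
    n_points: int = 0

    @property
    def ec90_log10(self) -> float:
        """log10 concentration producing 90 % of the span effect."""
        return self.log_ec50 + math.log10(9.0) / self.hill

    @property
    def emax_pct_reduction(self) -> float:
        """Maximal percent signal reduction (100 minus the lower asymptote)."""
        return 100.0 - self.bottom


def logistic4(x: np.ndarray, bottom: float, span: float, log_ec50: float, hill: float) -> np.ndarray:
    """Decreasing 4PL response at log10 concentration ``x``."""
    expo = np.clip(hill * (np.asarray(x, float) - log_ec50), -300.0, 300.0)
    return bottom + span / (1.0 + 10.0 ** expo)


def _robust_scale(resid: np.ndarray, y: np.ndarray) -> float:
    """Normalized MAD of residuals about zero, floored to avoid degeneracy."""
    mad = 1.4826 * float(np.median(np.abs(resid)))
    floor = max(1e-8, 1e-9 * max(1.0, float(np.median(np.abs(y)))))
    return max(mad, floor)


def tukey_loss(resid: np.ndarray, scale: Optional[float] = None) -> float:
    """Tukey biweight rho summed over residuals.

    When ``scale`` is omitted it is set to the normalized MAD of the
    residuals themselves, which makes loss values comparable across
    candidate solutions of the same data.
    """
    resid = np.asarray(resid, dtype=float)
    if scale is None:
        scale = _robust_scale(resid, resid)
    c = TUKEY_C * scale
    u2 = np.minimum((resid / c) ** 2, 1.0)
    return float(np.sum(c * c / 6.0 * (1.0 - (1.0 - u2) ** 3)))


def _tukey_weights(resid: np.ndarray, scale: float) -> np.ndarray:
    u = resid / (TUKEY_C * scale)
    w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
    return w


# --- box reparameterization: p = (bottom, u_span, log_ec50, u_hill) --------

def _boxed(u: float, lo: float, hi: float) -> float:
    return lo + (hi - lo) * expit(np.clip(u, -30.0, 30.0))


def _unbox(v: float, lo: float, hi: float) -> float:
    frac = np.clip((v - lo) / (hi - lo), 1e-9, 1.0 - 1e-9)
    return float(logit(frac))


def _natural(p: np.ndarray) -> tuple[float, float, float, float]:
    bottom = float(p[0])
    span = _boxed(p[1], *SPAN_BOUNDS)
    log_ec50 = float(p[2])
    hill = _boxed(p[3], *HILL_BOUNDS)
    return bottom, span, log_ec50, hill


def _jacobian_natural(x: np.ndarray, theta) -> np.ndarray:
    """Analytic Jacobian of the 4PL wrt its natural parameters."""
    bottom, span, log_ec50, hill = theta
    t = 10.0 ** (hill * (x - log_ec50))
    g = 1.0 / (1.0 + t)
    dg = t / (1.0 + t) ** 2  # = g * (1 - g)
    ln10 = math.log(10.0)
    J = np.empty((x.size, 4))
    J[:, 0] = 1.0
    J[:, 1] = g
    J[:, 2] = span * ln10 * hill * dg
    J[:, 3] = -span * ln10 * (x - log_ec50) * dg
    return J


def _irls(
    p0: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    robust: bool,
    max_iter: int = 30,
):
    """Iteratively reweighted least squares under the Tukey biweight."""
    p = np.asarray(p0, dtype=float)
    converged = False

    def resid_fun(p, sw):
        bottom, span, log_ec50, hill = _natural(p)
        return sw * (y - logistic4(x, bottom, span, log_ec50, hill))

    if robust:
        # seed weights from the start's own residuals so gross outliers do not
        # steer the first least-squares step away from the start's basin
        r0 = y - logistic4(x, *_natural(p))
        w = _tukey_weights(r0, _robust_scale(r0, y))
        if np.all(w == 0):
            w = np.ones_like(y)
    else:
        w = np.ones_like(y)

    for _ in range(max_iter if robust else 1):
        sw = np.sqrt(w)
        p_prev = p
        sol = least_squares(resid_fun, p, args=(sw,), method="lm",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        p = sol.x
        r = y - logistic4(x, *_natural(p))
        if not robust:
            converged = sol.status > 0
            w = np.ones_like(y)
            break
        s = _robust_scale(r, y)
        w_new = _tukey_weights(r, s)
        if np.all(w_new == 0):  # pathological; keep previous weights
            converged = True
            break
        weights_stable = np.max(np.abs(w_new - w)) < 1e-6
        params_stable = np.max(np.abs(p - p_prev)) < 1e-9 * (1.0 + np.max(np.abs(p)))
        w = w_new
        if weights_stable or params_stable:
            converged = True
            break
    r = y - logistic4(x, *_natural(p))
    return p, w, r, converged


def _fit(x: np.ndarray, y: np.ndarray, robust: bool, global_sd: Optional[float]) -> LogisticFit:
    if np.unique(x).size < _MIN_DISTINCT_CONC:
        raise ValueError(
            f"need at least {_MIN_DISTINCT_CONC} distinct concentrations, "
            f"got {np.unique(x).size}"
        )
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)

    # robust initial asymptotes: percentiles resist contaminated extremes
    bottom0 = float(np.percentile(y, 5))
    span0 = float(np.clip(np.percentile(y, 95) - bottom0, 21.0, 99.0))
    starts = []
    for lec in np.arange(float(x.min()), float(x.max()) + 1e-9, 0.5):
        for hill0 in (1.0, 2.0):
            starts.append(
                np.array([
                    bottom0,
                    _unbox(span0, *SPAN_BOUNDS),
                    float(lec),
                    _unbox(hill0, *HILL_BOUNDS),
                ])
            )

    best = None
    for p0 in starts:
        p, w, r, conv = _irls(p0, x, y, robust=robust)
        loss = tukey_loss(r) if robust else float(np.sum(r * r))
        bottom, span, log_ec50, hill = _natural(p)
        key = (loss, hill, abs(log_ec50))
        cand = (key, p, w, r, conv)
        if best is None or _better(key, best[0]):
            best = cand

    key, p, w, r, conv = best
    bottom, span, log_ec50, hill = _natural(p)
    theta = (bottom, span, log_ec50, hill)

    sw_sum = float(np.sum(w))
    dof = sw_sum - 4.0
    if dof > 0:
        s2 = float(np.sum(w * r * r)) / dof
        rmse = math.sqrt(s2)
    else:
        s2, rmse = float("inf"), float("inf")

    se = float("inf")
    if dof > 0:
        J = _jacobian_natural(x, theta)
        A = J.T @ (w[:, None] * J)
        try:
            if np.linalg.cond(A) < 1e12:
                cov = s2 * np.linalg.inv(A)
                if cov[2, 2] >= 0:
                    se = math.sqrt(cov[2, 2])
        except np.linalg.LinAlgError:
            pass

    fit = LogisticFit(
        bottom=bottom,
        top=bottom + span,
        log_ec50=log_ec50,
        hill=hill,
        span=span,
        rmse_robust=rmse,
        se_log_ec50=se,
        loss=key[0],
        scale=_robust_scale(r, y),
        converged=conv,
        valid=False,
        n_points=int(y.size),
    )
    return _gate(fit, global_sd)


def _better(key_a, key_b, rel_tol: float = 1e-9) -> bool:
    la, lb = key_a[0], key_b[0]
    if abs(la - lb) > rel_tol * max(abs(la), abs(lb), 1e-30):
        return la < lb
    return key_a[1:] < key_b[1:]


def _gate(fit: LogisticFit, global_sd: Optional[float]) -> LogisticFit:
    reasons = []
    if not fit.converged:
        reasons.append("optimizer did not converge")
    if not fit.se_log_ec50 < 1.0:
        reasons.append(f"SE(logEC50) = {fit.se_log_ec50:.3g} >= 1")
    if global_sd is not None:
        if global_sd <= 0:
            raise ValueError("global_sd must be > 0")
        if not fit.rmse_robust < 1.5 * global_sd:
            reasons.append(
                f"robust RMSE {fit.rmse_robust:.3g} >= 1.5 x global SD {global_sd:.3g}"
            )
    return replace(fit, valid=not reasons, reason="; ".join(reasons))


def fit_4pl_robust(
    log_conc: Sequence[float] | DoseResponseSeries,
    response: Optional[Sequence[float]] = None,
    global_sd: Optional[float] = None,
) -> LogisticFit:
    """Robust (Tukey biweight) constrained 4PL fit.

    Accepts either a :class:`DoseResponseSeries` or ``(log_conc, response)``
    arrays of log10 molar concentration and percent-of-control response.
    Replicates are fitted as individual points.  ``global_sd`` (percent
    units) enables the residual-RMSE acceptance criterion; the SE(logEC50)
    criterion is always applied.
    """
    if isinstance(log_conc, DoseResponseSeries):
        series = log_conc
        return _fit(series.log_conc, series.response, robust=True, global_sd=global_sd)
    return _fit(np.asarray(log_conc, float), np.asarray(response, float),
                robust=True, global_sd=global_sd)


def fit_4pl_least_squares(
    log_conc: Sequence[float],
    response: Sequence[float],
    global_sd: Optional[float] = None,
) -> LogisticFit:
    """Unweighted (non-robust) constrained 4PL fit, for comparison."""
    return _fit(np.asarray(log_conc, float), np.asarray(response, float),
                robust=False, global_sd=global_sd)


def assess_validity(fit: LogisticFit, global_sd: float) -> LogisticFit:
    """Apply both acceptance criteria and return the fit with ``valid`` set.

    A fit is valid iff its robust residual RMSE is below 1.5x ``global_sd``
    (the SD of percent-of-control across vehicle-control wells) and the
    standard error of log EC50 is below 1 log unit.
    """
    if global_sd <= 0:
        raise ValueError("global_sd must be > 0")
    return _gate(replace(fit, reason=""), global_sd)


def derive_potency(fit: LogisticFit) -> Optional[tuple[float, float, float]]:
    """(log EC50, log EC90, Emax percent reduction); ``None`` for invalid fits.

    For the decreasing curve, EC90 lies log10(9)/hill above EC50.
    """
    if not fit.valid:
        return None
    return fit.log_ec50, fit.ec90_log10, fit.emax_pct_reduction


@dataclass(frozen=True)
class NonmonotonicResult:
    """Rebound detection outcome with monotone segments of the mean curve."""

    nonmonotonic: bool
    segments: tuple[tuple[int, int], ...]   # index ranges into sorted concentrations
    log_conc: np.ndarray                    # sorted distinct log10 concentrations
    means: np.ndarray                       # replicate-mean response per concentration


def detect_nonmonotonic(
    log_conc: Sequence[float],
    response: Sequence[float],
    global_sd: float,
    min_points: int = 8,
) -> NonmonotonicResult:
    """Flag rebounding (non-monotonic) dose-response series.

    Replicate means are computed per distinct concentration and segmented
    into monotone runs with a 2x ``global_sd`` hysteresis.  A series is
    flagged when the response first falls below ``100 - 2*global_sd`` and a
    later concentration rebounds upward by more than ``2*global_sd`` — the
    signature of multiphasic per-cell signal changes that defeat a 4PL fit.
    """
    x = np.asarray(log_conc, dtype=float)
    y = np.asarray(response, dtype=float)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ux, inv = np.unique(xs, return_inverse=True)
    means = np.bincount(inv, weights=ys) / np.bincount(inv)
    if ux.size < min_points:
        return NonmonotonicResult(False, ((0, max(ux.size - 1, 0)),), ux, means)

    t = 2.0 * global_sd
    pivots: list[int] = []
    direction = 0
    run_min, imin = means[0], 0
    run_max, imax = means[0], 0
    rebound = False
    for i in range(1, ux.size):
        m = means[i]
        if direction == 0:
            if m < run_min:
                run_min, imin = m, i
            if m > run_max:
                run_max, imax = m, i
            if m < run_max - t:
                direction = -1
                run_min, imin = m, i
            elif m > run_min + t:
                direction = 1
                run_max, imax = m, i
        elif direction == -1:
            if m < run_min:
                run_min, imin = m, i
            elif m > run_min + t:            # confirmed valley -> rising
                pivots.append(imin)
                if run_min < 100.0 - t:
                    rebound = True
                direction = 1
                run_max, imax = m, i
        else:
            if m > run_max:
                run_max, imax = m, i
            elif m < run_max - t:            # confirmed peak -> falling
                pivots.append(imax)
                direction = -1
                run_min, imin = m, i

    bounds = [0] + pivots + [ux.size - 1]
    segments = tuple((bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1))
    return NonmonotonicResult(rebound, segments, ux, means)
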