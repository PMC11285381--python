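"""Cosinor model of the circadian rhythm and its dichotomization.

The cosinor model is the cosine regression

    r(t) = mes + amp * cos((t - phi) * 2*pi / T)

with *mes* the midline estimating statistic of rhythm, *amp* the amplitude,
*phi* the acrophase (time of peak activity) and *T* the period, fixed at
1440 min (24 h). ``t`` is the 1-minute epoch index measured from the start
of the series, so ``phi`` shares that origin; it is normalized into
``[0, T)`` using the cosine symmetry ``amp*cos(x) = -amp*cos(x + pi)`` so
that ``amp >= 0`` always.

For fixed T the model is linear in ``(mes, a, b)`` after the identity
``amp*cos(w(t-phi)) = a*cos(wt) + b*sin(wt)`` with ``a = amp*cos(w*phi)``,
``b = amp*sin(w*phi)``; ordinary least squares on that basis is the exact
global minimizer of the sum of squared residuals and is the default solver.
An iterative nonlinear least-squares path (analytic Jacobian, multi-start
over the acrophase) is retained; the two agree to high precision on clean
input and the iterative path allows an optional robust (Huber) loss.

The fitted curve is dichotomized by treating the lower 18% of its range as
the nocturnal period — chosen because the proportion of sleep in an ageing
population is about 20% — and the rest as diurnal; the state transitions
are rough estimates of the sleep/wake onset times.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ContractError, DegenerateRhythmError, FitError
from .io import ActigraphySeries

DEFAULT_INIT = (500.0, 550.0, 227.0)


class Direction(str, enum.Enum):
    TO_SLEEP = "to_sleep"
    TO_WAKE = "to_wake"


@dataclass(frozen=True)
class CosinorFit:
    mes: float
    amp: float
    phi: float  # acrophase, minutes, normalized into [0, T)
    T: float
    sse: float
    fitted: np.ndarray

    @property
    def params(self):
        return (self.mes, self.amp, self.phi)


@dataclass(frozen=True)
class RoughCycle:
    """Dichotomized cosinor curve: per-epoch state and its transitions.

    ``nocturnal[t]`` is True where the fitted curve lies strictly below the
    threshold; ``transitions`` lists ``(index, direction)`` pairs where
    ``index`` is the first epoch of the new state.
    """

    nocturnal: np.ndarray
    transitions: tuple
    threshold_value: float


def _curve(params, t, T):
    mes, amp, phi = params
    return mes + amp * np.cos((t - phi) * 2.0 * np.pi / T)


def _normalize(mes, amp, phi, T):
    if amp < 0:
        amp = -amp
        phi = phi + T / 2.0
    return float(mes), float(amp), float(phi % T)


def _fit_linear(t, y, T):
    w = 2.0 * np.pi / T
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mes, a, b = beta
    amp = float(np.hypot(a, b))
    phi = float(np.arctan2(b, a) / w)
    return _normalize(mes, amp, phi, T)


def _fit_iterative(t, y, T, init, loss, max_nfev):
    w = 2.0 * np.pi / T
    mes0, amp0, phi0 = init
    # acrophase multi-start: the SSE is non-convex in phi and a single
    # initializer can land in the wrong basin
    starts = [(mes0, amp0, phi0)]
    data_mes = float(np.mean(y))
    data_amp = float(np.ptp(y)) / 2.0 or 1.0
    starts += [(data_mes, data_amp, p) for p in (0.0, T / 4, T / 2, 3 * T / 4)]

    def resid(p):
        return _curve(p, t, T) - y

    def jac(p):
        _, amp, phi = p
        arg = (t - phi) * w
        return np.column_stack(
            [np.ones_like(t), np.cos(arg), amp * w * np.sin(arg)]
        )

    best = None
    last = None
    for p0 in starts:
        try:
            sol = least_squares(
                resid, p0, jac=jac, loss=loss,
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev,
            )
        except Exception:
            continue
        last = sol
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(
            "cosinor fit did not converge from any start",
            last_iterate=None if last is None else tuple(last.x),
        )
    return _normalize(*best.x, T)


def fit_cosinor(
    series: ActigraphySeries,
    T: float = 1440.0,
    init: tuple = DEFAULT_INIT,
    solver: str = "linear",
    loss: str = "linear",
    max_nfev: int = 2000,
) -> CosinorFit:
    """Least-squares cosinor fit of a 60 s epoch series.

    Parameters
    ----------
    solver : {"linear", "iterative"}
        "linear" solves the equivalent linear model exactly (default);
        "iterative" runs nonlinear least squares from ``init`` plus an
        acrophase multi-start.
    loss : str
        Loss for the iterative solver ("linear" = plain least squares,
        "huber" for a robust alternative); ignored by the linear solver.
    """
    if series.epoch_s != 60:
        raise ContractError("cosinor fitting expects 60 s epochs")
    if series.n < 3:
        raise ContractError("need at least 3 epochs to fit 3 parameters")
    t = np.arange(series.n, dtype=float)
    y = series.values
    if solver == "linear":
        mes, amp, phi = _fit_linear(t, y, T)
    elif solver == "iterative":
        mes, amp, phi = _fit_iterative(t, y, T, init, loss, max_nfev)
    else:
        raise ContractError(f"unknown solver {solver!r}")
    fitted = _curve((mes, amp, phi), t, T)
    sse = float(np.sum((fitted - y) ** 2))
    return CosinorFit(mes=mes, amp=amp, phi=phi, T=float(T), sse=sse, fitted=fitted)


def dichotomize(fit: CosinorFit, lower_fraction: float = 0.18) -> RoughCycle:
    """Split the fitted curve into nocturnal/diurnal states.

    The threshold sits at ``min + lower_fraction * range`` of the fitted
    curve; epochs strictly below it are nocturnal (ties count as diurnal).
    The threshold depends only on the curve's range, so it is invariant to
    additive shifts of the curve.
    """
    if not (0.0 < lower_fraction < 1.0):
        raise ContractError("lower_fraction must lie in (0, 1)")
    f = fit.fitted
    lo, hi = float(np.min(f)), float(np.max(f))
    if hi - lo <= 1e-8 * max(1.0, abs(hi)):
        raise DegenerateRhythmError(
            "fitted curve is flat (amp ~ 0); no day/night split exists"
        )
    threshold = lo + lower_fraction * (hi - lo)
    nocturnal = f < threshold
    change = np.flatnonzero(np.diff(nocturnal.astype(np.int8)))
    transitions = tuple(
        (int(i) + 1, Direction.TO_SLEEP if nocturnal[i + 1] else Direction.TO_WAKE)
        for i in change
    )
    return RoughCycle(
        nocturnal=nocturnal, transitions=transitions, threshold_value=threshold
    )
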