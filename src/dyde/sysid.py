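"""First-order continuous-time SISO identification between gene pairs.

The link model is ``dy/dt = a*u(t) - b*y(t) + c`` with initial state
``x0``: ``a`` is the input gain, ``b`` the decay rate (1/h; the model is
stable iff b > 0) and ``c`` a constant offset.  Simulation uses the exact
per-interval solution of the linear ODE under first-order-hold (linear
interpolation) of the input; zero-order-hold is available by config.

Fitting minimizes the simulation-error sum of squares with a bounded
trust-region least-squares solver, started from a forward-difference
(Euler) regression plus seeded random restarts.  Goodness of fit is the
NRMSE percentage ``100*(1 - ||y - yhat|| / ||y - ybar||)``; the squared
(un-rooted) variant is exposed via a switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from dyde.data_model import AnalysisConfig, _check_uniform_grid

__all__ = [
    "FirstOrderModel",
    "InitialGuess",
    "simulate",
    "initialize_params",
    "fit_first_order",
    "fitness",
]

_Y_CLIP = 1e150


@dataclass(frozen=True)
class FirstOrderModel:
    """Fitted first-order link ``dy/dt = a*u - b*y + c`` with state ``x0``.

    The transfer function is ``P(s) = a/(s + b)``; ``c`` and ``x0`` are
    affine/initial terms excluded from ``P``.
    """

    a: float
    b: float
    c: float
    x0: float
    fitness_pct: float | None = None

    @property
    def stable(self) -> bool:
        return self.b > 0

    def to_dict(self, source: str | None = None, target: str | None = None) -> dict:
        d = {"a": self.a, "b": self.b, "c": self.c, "x0": self.x0,
             "fitness_pct": self.fitness_pct, "stable": self.stable}
        if source is not None:
            d["source"] = source
        if target is not None:
            d["target"] = target
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FirstOrderModel":
        return cls(a=float(d["a"]), b=float(d["b"]), c=float(d["c"]),
                   x0=float(d["x0"]), fitness_pct=d.get("fitness_pct"))


@dataclass(frozen=True)
class InitialGuess:
    a: float
    b: float
    c: float
    x0: float
    degenerate: bool = False


def _step_coefficients(b: float, h: float) -> tuple[float, float, float]:
    """(E, I1, I2) for one integration step of length h.

    E = exp(-b h); I1 = int_0^h exp(-b (h - tau)) dtau;
    I2 = int_0^h exp(-b (h - tau)) tau dtau.  Small-|b h| branches use
    Taylor expansions to stay accurate through b = 0.
    """
    bh = b * h
    if abs(bh) < 1e-8:
        E = math.exp(-bh)
        I1 = h * (1.0 - bh / 2.0 + bh * bh / 6.0)
        J = h * h * (0.5 - bh / 3.0 + bh * bh / 8.0)
    else:
        bh_c = max(min(bh, 700.0), -700.0)  # overflow guard for wildly unstable trials
        E = math.exp(-bh_c)
        I1 = -math.expm1(-bh_c) / b
        J = (1.0 - E * (1.0 + bh)) / (b * b)
    I2 = h * I1 - J
    return E, I1, I2


def simulate(model: FirstOrderModel, u: np.ndarray, times: np.ndarray,
             hold: str = "foh") -> np.ndarray:
    """Integrate the link ODE from ``y(times[0]) = x0`` over a uniform grid.

    ``hold`` selects how the input is interpolated between samples:
    ``"foh"`` (linear, exact piecewise-affine solution) or ``"zoh"``
    (piecewise constant).
    """
    times = np.asarray(times, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.size != times.size:
        raise ValueError("u and times must have equal length")
    h = _check_uniform_grid(times)
    if hold not in ("foh", "zoh"):
        raise ValueError("hold must be 'foh' or 'zoh'")
    E, I1, I2 = _step_coefficients(model.b, h)
    y = np.empty(times.size)
    y[0] = model.x0
    a, c = model.a, model.c
    if hold == "foh":
        slopes = np.diff(u) / h
        for k in range(times.size - 1):
            yk = E * y[k] + (a * u[k] + c) * I1 + a * slopes[k] * I2
            y[k + 1] = min(max(yk, -_Y_CLIP), _Y_CLIP)
    else:
        for k in range(times.size - 1):
            yk = E * y[k] + (a * u[k] + c) * I1
            y[k + 1] = min(max(yk, -_Y_CLIP), _Y_CLIP)
    return y


def initialize_params(u: np.ndarray, y: np.ndarray, times: np.ndarray) -> InitialGuess:
    """Euler-regression initial guess for (a, b, c, x0).

    Ordinary least squares on the forward difference
    ``(y[k+1]-y[k])/dt = a*u[k] - b*y[k] + c``; ``x0 = y[0]``.  A
    rank-deficient regressor (e.g. constant u and y) yields the degenerate
    fallback (a=0, small positive b, c = mean rate).
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    if y.size < 4:
        raise ValueError("need >=4 points to initialize")
    h = _check_uniform_grid(times)
    dy = np.diff(y) / h
    # b is unidentifiable when y has no variation (its column is collinear
    # with the intercept); a zero/constant u merely zeroes out a via the
    # min-norm least-squares solution
    if np.std(y[:-1]) < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        return InitialGuess(a=0.0, b=0.1, c=float(dy.mean()), x0=float(y[0]), degenerate=True)
    X = np.column_stack([u[:-1], -y[:-1], np.ones(y.size - 1)])
    coef, *_ = np.linalg.lstsq(X, dy, rcond=1e-10)
    return InitialGuess(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                        x0=float(y[0]), degenerate=False)


def fitness(y: np.ndarray, yhat: np.ndarray, sqrt_form: bool = True) -> float:
    """Goodness-of-fit percentage; 100 is a perfect reproduction.

    NRMSE form (default): ``100*(1 - ||y-yhat||_2 / ||y-ybar||_2)``.  With
    ``sqrt_form=False`` the ratio of sums of squares is used instead.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size or y.size < 2:
        raise ValueError("series must have equal length >= 2")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom <= 0.0:
        raise ValueError("fitness undefined for a constant observed series")
    num = float(np.sum((y - yhat) ** 2))
    ratio = num / denom
    if sqrt_form:
        ratio = math.sqrt(ratio)
    return 100.0 * (1.0 - ratio)


def _bounds(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    yscale = max(float(np.max(np.abs(y))), 1e-6)
    lo = np.array([-100.0, -100.0, -10.0 * yscale, -10.0 * yscale])
    hi = np.array([100.0, 100.0, 10.0 * yscale, 10.0 * yscale])
    return lo, hi


def fit_first_order(u: np.ndarray, y: np.ndarray, times: np.ndarray,
                    cfg: AnalysisConfig | None = None,
                    seed: int | None = None) -> FirstOrderModel:
    """Fit (a, b, c, x0) by simulation-error minimization.

    A bounded trust-region least-squares solve is run from the Euler
    regression guess plus ``cfg.n_restarts`` seeded random starts; the best
    solution over all starts is returned with its fitness attached.
    Deterministic for a fixed seed.
    """
    cfg = cfg or AnalysisConfig()
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    if u.size != y.size or y.size != times.size:
        raise ValueError("u, y and times must share one grid")
    if y.size < 6:
        raise ValueError(f"need >=6 points to fit, got {y.size}")
    _check_uniform_grid(times)
    hold = cfg.input_hold
    lo, hi = _bounds(y)

    def residuals(p: np.ndarray) -> np.ndarray:
        m = FirstOrderModel(a=p[0], b=p[1], c=p[2], x0=p[3])
        r = simulate(m, u, times, hold=hold) - y
        return np.where(np.isfinite(r), r, 1e100)

    guess = initialize_params(u, y, times)
    starts = [np.clip(np.array([guess.a, guess.b, guess.c, guess.x0]), lo, hi)]
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    yscale = max(float(np.max(np.abs(y))), 1e-6)
    uscale = max(float(np.max(np.abs(u))), 1e-6)
    for _ in range(cfg.n_restarts):
        starts.append(np.clip(np.array([
            rng.uniform(-2.0, 2.0) * yscale / uscale,
            rng.uniform(0.01, 2.0),
            rng.uniform(-1.0, 1.0) * yscale,
            y[0] + rng.normal(scale=0.1 * yscale),
        ]), lo, hi))

    best_p = None
    best_sse = np.inf
    failures = 0
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception:  # noqa: BLE001 - keep best-so-far across starts
            failures += 1
            continue
        sse = float(np.sum(sol.fun ** 2))
        if sse < best_sse - 1e-15:
            best_sse = sse
            best_p = sol.x
    if best_p is None:
        raise RuntimeError(f"optimizer failed on all {len(starts)} starts ({failures} exceptions)")
    model = FirstOrderModel(a=float(best_p[0]), b=float(best_p[1]),
                            c=float(best_p[2]), x0=float(best_p[3]))
    yhat = simulate(model, u, times, hold=hold)
    fit = fitness(y, yhat, sqrt_form=cfg.fitness_sqrt)
    return FirstOrderModel(a=model.a, b=model.b, c=model.c, x0=model.x0, fitness_pct=fit)
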