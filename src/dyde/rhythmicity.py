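"""Rhythmicity detection: pseudo-sinusoidal fitting and logistic classification.

A *pseudo-sinusoid* joins half-cycles of two sinusoids with full periods
``p1`` and ``p2``; its overall period is ``P = (p1 + p2)/2``.  Writing the
waveform as ``A * sin(theta(t) + phi1)`` with a piecewise-linear phase
profile ``theta`` makes the least-squares fit over amplitude and phase a
closed-form 2-parameter linear solve per ``(p1, p2)`` grid point, so the
exhaustive period search stays cheap.

Eight spectral/fit features are computed from the replicate-mean signal and
the best single replicate; a ridge-stabilized logistic regression maps the
features to a rhythmic-vs-arrhythmic probability with a 0.5 decision cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dyde.data_model import AnalysisConfig, ExpressionDataset, detrend

__all__ = [
    "PseudoSine",
    "PseudoSineFit",
    "RhythmFeatures",
    "LogisticModel",
    "RhythmCall",
    "pseudo_sine_eval",
    "fit_pseudo_sine",
    "periodogram",
    "compute_features",
    "compute_features_with_fit",
    "train_classifier",
    "classify",
    "rhythm_screen",
    "summarize_screen",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PseudoSine:
    """Parameters of a pseudo-sinusoidal waveform.

    ``A`` is a non-negative amplitude, ``phi1`` the phase in radians, and
    ``p1``/``p2`` the full periods (hours) of the sinusoids forming the
    first and second half-cycle.  The overall period is ``(p1 + p2)/2``.
    """

    A: float
    phi1: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0:
            raise ValueError("p1 and p2 must be positive")
        if self.A < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def period(self) -> float:
        return (self.p1 + self.p2) / 2.0


@dataclass(frozen=True)
class PseudoSineFit:
    """A fitted pseudo-sinusoid plus the 2-norm of the residual."""

    params: PseudoSine
    l2_error: float


@dataclass(frozen=True)
class RhythmFeatures:
    """The 8-feature vector used by the rhythmicity classifier.

    (x1, x2): rhythm-band spectral power ratio of signal A (replicate mean)
    and signal B (best single replicate); (x3, x4): pseudo-sine fit L2
    errors; (x5, x6): variance of the power spectrum; (x7, x8): fitted
    pseudo-sine amplitudes.
    """

    x1: float
    x2: float
    x3: float
    x4: float
    x5: float
    x6: float
    x7: float
    x8: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4,
                         self.x5, self.x6, self.x7, self.x8])


@dataclass(frozen=True)
class LogisticModel:
    """Trained logistic classifier with feature standardization statistics."""

    intercept: float
    weights: np.ndarray  # shape (n_features,)
    feat_mean: np.ndarray
    feat_sd: np.ndarray

    def decision(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.weights.size:
            raise ValueError(
                f"feature dimension mismatch: model has {self.weights.size}, got {x.shape[-1]}"
            )
        z = (x - self.feat_mean) / self.feat_sd
        return float(self.intercept + z @ self.weights)

    def probability(self, x: np.ndarray) -> float:
        return float(1.0 / (1.0 + np.exp(-self.decision(x))))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "intercept": self.intercept,
            "weights": self.weights.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        d = json.loads(Path(path).read_text())
        return cls(float(d["intercept"]), np.array(d["weights"], float),
                   np.array(d["feat_mean"], float), np.array(d["feat_sd"], float))


@dataclass(frozen=True)
class RhythmCall:
    """Classification outcome for one gene."""

    probability: float
    is_rhythmic: bool
    period: float
    phase: float
    amplitude: float


# ---------------------------------------------------------------------------
# Pseudo-sine waveform


def _phase_profile(times: np.ndarray, p1: float, p2: float) -> np.ndarray:
    """Piecewise-linear phase theta(t) of the unit pseudo-sine.

    First half-cycle (t mod P in [0, p1/2)): theta = 2*pi/p1 * t'; second
    half-cycle: theta = 2*pi/p2 * (t' - p1/2 + p2/2).  Continuous at the
    junction (both give pi) and periodic with P = (p1 + p2)/2.
    """
    P = (p1 + p2) / 2.0
    tm = np.mod(times, P)
    first = tm < p1 / 2.0
    theta = np.where(first, TWO_PI / p1 * tm, TWO_PI / p2 * (tm - p1 / 2.0 + p2 / 2.0))
    return theta


def pseudo_sine_eval(params: PseudoSine, times: np.ndarray) -> np.ndarray:
    """Evaluate the pseudo-sinusoid at the given times (hours)."""
    times = np.asarray(times, dtype=float)
    theta = _phase_profile(times, params.p1, params.p2)
    return params.A * np.sin(theta + params.phi1)


# ---------------------------------------------------------------------------
# Grid fit

_GRID_CACHE: dict = {}


def _period_grid(cfg: AnalysisConfig) -> np.ndarray:
    p_min, p_max = cfg.period_range
    n = int(np.floor((p_max - p_min) / cfg.grid_step_hours + 1e-9)) + 1
    return p_min + cfg.grid_step_hours * np.arange(n)


def _fit_basis(times: tuple, cfg_key: tuple, cfg: AnalysisConfig):
    """Precomputed regression basis for every (p1, p2) grid combination.

    Per combination the design is [sin(theta), cos(theta), 1, t]: the
    waveform's sin/cos pair plus an affine trend, so amplitude, phase and
    the best straight line are solved jointly in closed form.  Cached per
    (times, grid) since it is independent of the series being fitted.
    """
    key = (times, cfg_key)
    hit = _GRID_CACHE.get(key)
    if hit is not None:
        return hit
    t = np.asarray(times, dtype=float)
    ps = _period_grid(cfg)
    p1g, p2g = np.meshgrid(ps, ps, indexing="ij")
    p1f, p2f = p1g.ravel(), p2g.ravel()  # lexicographic (p1, then p2)
    P = (p1f + p2f) / 2.0
    tm = np.mod(t[None, :], P[:, None])
    first = tm < (p1f[:, None] / 2.0)
    theta = np.where(first,
                     TWO_PI / p1f[:, None] * tm,
                     TWO_PI / p2f[:, None] * (tm - p1f[:, None] / 2.0 + p2f[:, None] / 2.0))
    n_combo = p1f.size
    # scale the trend columns to the data range for conditioning
    tn = (t - t.mean()) / max(t.max() - t.min(), 1.0)
    B = np.empty((n_combo, 4, t.size))
    B[:, 0] = np.sin(theta)
    B[:, 1] = np.cos(theta)
    B[:, 2] = 1.0
    B[:, 3] = tn
    M = np.einsum("cit,cjt->cij", B, B)
    M += 1e-10 * np.eye(4)  # jitter for degenerate combos (basis collinearity)
    Minv = np.linalg.inv(M)
    entry = (p1f, p2f, B, Minv)
    _GRID_CACHE[key] = entry
    return entry


def fit_pseudo_sine(series: np.ndarray, times: np.ndarray, cfg: AnalysisConfig | None = None) -> PseudoSineFit:
    """Least-squares pseudo-sine fit by exhaustive (p1, p2) grid search.

    For each ``(p1, p2)`` on the configured grid the optimal amplitude,
    phase and affine trend are obtained in closed form by projection onto
    the sin/cos/trend basis — exact over a continuous phase, hence at
    least as good as any discrete phase grid, and invariant to whether the
    caller detrended first.  Ties break toward the smallest ``(p1, p2)``.
    ``l2_error`` is the 2-norm of the residual after trend removal.
    """
    cfg = cfg or AnalysisConfig()
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size < 6:
        raise ValueError(f"need >=6 points for a pseudo-sine fit, got {series.size}")
    cfg_key = (cfg.period_range, cfg.grid_step_hours)
    p1f, p2f, B, Minv = _fit_basis(tuple(times.tolist()), cfg_key, cfg)

    rhs = B @ series  # (n_combo, 4)
    coef = np.einsum("cij,cj->ci", Minv, rhs)
    ss = float(series @ series)
    res2 = np.maximum(ss - np.einsum("ci,ci->c", coef, rhs), 0.0)
    best = int(np.argmin(res2))  # first occurrence -> smallest (p1, p2)
    # exact residual of the winning combo (the batched form carries the jitter bias)
    resid = series - coef[best] @ B[best]
    res2[best] = float(resid @ resid)
    alpha, beta = coef[best, 0], coef[best, 1]
    A = float(np.hypot(alpha, beta))
    phi = float(np.mod(np.arctan2(beta, alpha), TWO_PI)) if A > 0 else 0.0
    params = PseudoSine(A=A, phi1=phi, p1=float(p1f[best]), p2=float(p2f[best]))
    return PseudoSineFit(params=params, l2_error=float(np.sqrt(res2[best])))


# ---------------------------------------------------------------------------
# Features


def periodogram(series: np.ndarray, dt: float, n_fft: int) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded FFT power spectrum, DC excluded.

    Returns (frequencies cycles/h, power ordinates) for bins 1..n_fft//2.
    """
    series = np.asarray(series, dtype=float)
    spec = np.fft.rfft(series, n=n_fft)
    power = np.abs(spec[1:]) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=dt)[1:]
    return freqs, power


def _band_ratio_and_var(series: np.ndarray, dt: float, cfg: AnalysisConfig) -> tuple[float, float]:
    freqs, power = periodogram(series, dt, cfg.n_fft)
    total = float(power.sum())
    if total <= 0.0:
        return 0.0, 0.0
    lo, hi = cfg.rhythm_band
    periods = 1.0 / freqs
    in_band = (periods >= lo) & (periods <= hi)
    return float(power[in_band].sum() / total), float(np.var(power))


def compute_features_with_fit(
    replicates: np.ndarray, times: np.ndarray, cfg: AnalysisConfig | None = None
) -> tuple[RhythmFeatures, PseudoSineFit, int]:
    """Features plus the signal-A pseudo-sine fit and the chosen B replicate.

    Signal A is the detrended replicate mean; signal B is the single
    replicate whose best pseudo-sine fit has the lowest L2 error (ties to
    the lowest replicate index).
    """
    cfg = cfg or AnalysisConfig()
    replicates = np.atleast_2d(np.asarray(replicates, dtype=float))
    times = np.asarray(times, dtype=float)
    dt = float(times[1] - times[0])

    sig_a = detrend(replicates.mean(axis=0), times)
    fit_a = fit_pseudo_sine(sig_a, times, cfg)

    rep_fits = [fit_pseudo_sine(detrend(r, times), times, cfg) for r in replicates]
    b_idx = int(np.argmin([f.l2_error for f in rep_fits]))
    sig_b = detrend(replicates[b_idx], times)
    fit_b = rep_fits[b_idx]

    x1, x5 = _band_ratio_and_var(sig_a, dt, cfg)
    x2, x6 = _band_ratio_and_var(sig_b, dt, cfg)
    feats = RhythmFeatures(
        x1=x1, x2=x2,
        x3=fit_a.l2_error, x4=fit_b.l2_error,
        x5=x5, x6=x6,
        x7=fit_a.params.A, x8=fit_b.params.A,
    )
    return feats, fit_a, b_idx


def compute_features(replicates: np.ndarray, times: np.ndarray,
                     cfg: AnalysisConfig | None = None) -> RhythmFeatures:
    """The 8 classifier features for one gene's replicate series."""
    return compute_features_with_fit(replicates, times, cfg)[0]


# ---------------------------------------------------------------------------
# Logistic classifier


def train_classifier(features: Sequence[RhythmFeatures] | np.ndarray,
                     labels: Sequence[bool]) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    Features are standardized internally; a small L2 ridge (1e-6) on the
    weights keeps the solve well-posed under perfect separation.  Converges
    when the largest coefficient change drops below 1e-8 (at most 100
    iterations).
    """
    if len(features) and isinstance(features[0], RhythmFeatures):
        X = np.vstack([f.as_array() for f in features])
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features/labels shape mismatch")
    classes = set(np.unique(y))
    if classes != {0.0, 1.0}:
        raise ValueError("training requires both rhythmic and arrhythmic examples")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = np.column_stack([np.ones(X.shape[0]), (X - mean) / sd])

    ridge = 1e-6
    penalty = np.ones(Z.shape[1]) * ridge
    penalty[0] = 0.0  # intercept unpenalized
    beta = np.zeros(Z.shape[1])
    for _ in range(100):
        eta = np.clip(Z @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = (Z * w[:, None]).T @ Z + np.diag(penalty)
        grad = Z.T @ (y - p) - penalty * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return LogisticModel(intercept=float(beta[0]), weights=beta[1:],
                         feat_mean=mean, feat_sd=sd)


def classify(model: LogisticModel, feats: RhythmFeatures, fit_a: PseudoSineFit) -> RhythmCall:
    """Probability + binary call; strictly greater than 0.5 means rhythmic."""
    sigma = model.probability(feats.as_array())
    return RhythmCall(
        probability=sigma,
        is_rhythmic=sigma > 0.5,
        period=fit_a.params.period,
        phase=fit_a.params.phi1,
        amplitude=fit_a.params.A,
    )


# ---------------------------------------------------------------------------
# Screen


def rhythm_screen(ds: ExpressionDataset, model: LogisticModel,
                  cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Classify every gene in a dataset; per-gene failures are flagged rows.

    Returns a table with columns gene, prob, is_rhythmic, period_h,
    phase_rad, amplitude, amplitude_norm, l2_error, error.  The normalized
    amplitude is the fitted amplitude divided by the standard deviation of
    the detrended replicate-mean signal.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    for gene in ds.gene_ids:
        try:
            reps = ds.replicates(gene)
            feats, fit_a, _ = compute_features_with_fit(reps, ds.times, cfg)
            call = classify(model, feats, fit_a)
            sig_sd = float(np.std(detrend(reps.mean(axis=0), ds.times)))
            rows.append({
                "gene": gene,
                "prob": call.probability,
                "is_rhythmic": call.is_rhythmic,
                "period_h": call.period,
                "phase_rad": call.phase,
                "amplitude": call.amplitude,
                "amplitude_norm": call.amplitude / sig_sd if sig_sd > 0 else 0.0,
                "l2_error": fit_a.l2_error,
                "error": "",
            })
        except Exception as exc:  # noqa: BLE001 - the screen must not abort
            rows.append({
                "gene": gene, "prob": np.nan, "is_rhythmic": False,
                "period_h": np.nan, "phase_rad": np.nan, "amplitude": np.nan,
                "amplitude_norm": np.nan, "l2_error": np.nan, "error": str(exc),
            })
    columns = ["gene", "prob", "is_rhythmic", "period_h", "phase_rad",
               "amplitude", "amplitude_norm", "l2_error", "error"]
    return pd.DataFrame(rows, columns=columns)


def summarize_screen(calls: pd.DataFrame) -> dict:
    """Summary statistics over the rhythmic genes of a screen table."""
    rhythmic = calls[calls["is_rhythmic"].astype(bool)]
    return {
        "n_genes": int(len(calls)),
        "n_rhythmic": int(len(rhythmic)),
        "period_mean_h": float(rhythmic["period_h"].mean()) if len(rhythmic) else float("nan"),
        "period_sd_h": float(rhythmic["period_h"].std(ddof=0)) if len(rhythmic) else float("nan"),
        "amplitude_norm_mean": float(rhythmic["amplitude_norm"].mean()) if len(rhythmic) else float("nan"),
    }
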