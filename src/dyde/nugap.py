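"""Nu-gap distance between first-order models, global or band-restricted.

The pointwise kernel is the chordal (Riemann-sphere) distance between the
two frequency responses ``P(jw) = a/(jw + b)``.  The global nu-gap is the
supremum of the chordal distance over frequency when a winding-number
condition holds, and 1 otherwise.  For band-limited signals (circadian
data) the *local* gap — the supremum restricted to the band of interest,
without the winding test — is the default comparison.

Offsets ``c`` and initial states ``x0`` are operating-point terms and are
excluded from the transfer function being compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from dyde.data_model import AnalysisConfig
from dyde.sysid import FirstOrderModel

__all__ = [
    "FrequencyBand",
    "NuGapResult",
    "WindingIndeterminateError",
    "freq_response",
    "chordal_distance",
    "winding_condition",
    "nu_gap",
]

TWO_PI = 2.0 * np.pi


class WindingIndeterminateError(RuntimeError):
    """Phase accumulation stayed ambiguous after maximal grid refinement."""


@dataclass(frozen=True)
class FrequencyBand:
    """A frequency interval [w_lo, w_hi] in rad/h."""

    w_lo: float
    w_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.w_lo < self.w_hi:
            raise ValueError("need 0 < w_lo < w_hi")

    @classmethod
    def from_periods(cls, p_lo: float, p_hi: float) -> "FrequencyBand":
        """Band for periods [p_lo, p_hi] hours: w in [2*pi/p_hi, 2*pi/p_lo]."""
        if not 0.0 < p_lo < p_hi:
            raise ValueError("need 0 < p_lo < p_hi")
        return cls(w_lo=TWO_PI / p_hi, w_hi=TWO_PI / p_lo)


@dataclass(frozen=True)
class NuGapResult:
    value: float
    band: FrequencyBand | str  # a FrequencyBand or the literal "global"
    winding_ok: bool
    argmax_freq: float


def freq_response(model: FirstOrderModel, w: float | np.ndarray) -> complex | np.ndarray:
    """Evaluate P(jw) = a/(jw + b)."""
    w = np.asarray(w, dtype=float)
    denom = 1j * w + model.b
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(denom == 0, np.inf + 0j, model.a / np.where(denom == 0, 1.0, denom))
    if w.ndim == 0:
        return complex(g)
    return g


def chordal_distance(g1: complex, g2: complex) -> float:
    """Riemann-sphere distance |g1-g2| / (sqrt(1+|g1|^2) sqrt(1+|g2|^2)).

    Infinite gains are the sphere's north pole: the distance from a finite
    g to infinity is 1/sqrt(1+|g|^2); between two infinities it is 0.
    """
    f1 = np.isfinite(g1.real) and np.isfinite(g1.imag)
    f2 = np.isfinite(g2.real) and np.isfinite(g2.imag)
    if f1 and f2:
        return float(abs(g1 - g2) / (np.sqrt(1.0 + abs(g1) ** 2) * np.sqrt(1.0 + abs(g2) ** 2)))
    if f1 and not f2:
        return float(1.0 / np.sqrt(1.0 + abs(g1) ** 2))
    if f2 and not f1:
        return float(1.0 / np.sqrt(1.0 + abs(g2) ** 2))
    return 0.0


def _kappa_grid(m1: FirstOrderModel, m2: FirstOrderModel, w: np.ndarray) -> np.ndarray:
    """Vectorized chordal distance of the two responses on a frequency grid."""
    g1 = freq_response(m1, w)
    g2 = freq_response(m2, w)
    a1 = np.abs(g1)
    a2 = np.abs(g2)
    finite1 = np.isfinite(a1)
    finite2 = np.isfinite(a2)
    out = np.empty(w.shape)
    both = finite1 & finite2
    out[both] = np.abs(g1[both] - g2[both]) / (
        np.sqrt(1.0 + a1[both] ** 2) * np.sqrt(1.0 + a2[both] ** 2))
    only1 = finite1 & ~finite2
    out[only1] = 1.0 / np.sqrt(1.0 + a1[only1] ** 2)
    only2 = finite2 & ~finite1
    out[only2] = 1.0 / np.sqrt(1.0 + a2[only2] ** 2)
    out[~finite1 & ~finite2] = 0.0
    return out


def _rhp_poles(m: FirstOrderModel) -> int:
    """Strictly right-half-plane pole count of a/(s+b): 1 iff b < 0."""
    return 1 if m.b < 0 else 0


def winding_condition(m1: FirstOrderModel, m2: FirstOrderModel,
                      n_grid: int = 4096, max_refine: int = 10) -> bool:
    """Homotopy condition under which sup-kappa equals the nu-gap.

    Checks that ``f(w) = 1 + conj(P2(jw)) P1(jw)`` stays away from zero on
    a dense symmetric grid (plus the w -> inf limit, where f -> 1) and that
    the winding number of f, accumulated over w from -inf to +inf, plus
    eta(P1) - eta(P2) vanishes (eta = strictly-RHP pole count).  The phase
    accumulation is refined up to ``max_refine`` times when consecutive
    phase jumps exceed pi/2; if still ambiguous an error is raised.
    """
    refine = 1
    for _ in range(max_refine + 1):
        mag = np.logspace(-6, 6, n_grid * refine)
        w = np.concatenate([-mag[::-1], [0.0], mag])
        with np.errstate(invalid="ignore", over="ignore"):
            f = 1.0 + np.conj(freq_response(m2, w)) * freq_response(m1, w)
        bad = ~np.isfinite(f)
        if np.any(bad):
            # pole on the axis (b == 0 at w == 0): perturb the node slightly
            eps = 1e-12
            f[bad] = 1.0 + np.conj(freq_response(m2, w[bad] + eps)) * freq_response(m1, w[bad] + eps)
        if np.min(np.abs(f)) < 1e-9:
            return False
        dphi = np.angle(f[1:] / f[:-1])
        if np.max(np.abs(dphi)) < 0.5 * np.pi:
            total = float(np.sum(dphi))
            wno = int(round(total / TWO_PI))
            return wno + _rhp_poles(m1) - _rhp_poles(m2) == 0
        refine *= 2
    raise WindingIndeterminateError("phase accumulation ambiguous after maximal refinement")


def _sup_kappa(m1: FirstOrderModel, m2: FirstOrderModel, w: np.ndarray,
               extra: list[tuple[float, float]] | None = None) -> tuple[float, float]:
    """Max chordal distance over a grid, refined around local maxima.

    ``extra`` holds (value, frequency) candidates evaluated analytically
    (grid endpoints / limits).  Returns (value, argmax frequency).
    """
    kappa = _kappa_grid(m1, m2, w)
    candidates: list[tuple[float, float]] = list(extra or [])
    interior = np.where((kappa[1:-1] >= kappa[:-2]) & (kappa[1:-1] >= kappa[2:]))[0] + 1
    order = interior[np.argsort(kappa[interior])[::-1][:3]] if interior.size else np.array([], int)
    for i in list(order) + [0, len(w) - 1]:
        lo = w[max(i - 1, 0)]
        hi = w[min(i + 1, len(w) - 1)]
        candidates.append((float(kappa[i]), float(w[i])))
        if hi > lo:
            res = minimize_scalar(lambda x: -_kappa_grid(m1, m2, np.array([x]))[0],
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-12})
            candidates.append((float(-res.fun), float(res.x)))
    best_val, best_w = max(candidates, key=lambda vw: vw[0])
    return min(best_val, 1.0), best_w


def nu_gap(m1: FirstOrderModel, m2: FirstOrderModel,
           band: FrequencyBand | str | None = None,
           cfg: AnalysisConfig | None = None) -> NuGapResult:
    """Nu-gap between two first-order models.

    With a :class:`FrequencyBand` (the default, derived from
    ``cfg.local_band`` periods) the *local* gap is returned: the supremum
    of the chordal distance over the band only, with no winding test.
    With ``band="global"`` the full-axis supremum is computed, forced to 1
    when the winding condition fails.
    """
    cfg = cfg or AnalysisConfig()
    if band is None:
        band = FrequencyBand.from_periods(*cfg.local_band)

    if band == "global":
        try:
            ok = winding_condition(m1, m2)
        except WindingIndeterminateError:
            raise
        if not ok:
            return NuGapResult(value=1.0, band="global", winding_ok=False, argmax_freq=np.nan)
        w = np.logspace(-4, 3, cfg.freq_grid_size)
        # analytic limits: w=0 (DC gains, infinite if b=0) and w->inf (both 0)
        g1_0 = complex(np.inf) if m1.b == 0 else m1.a / m1.b
        g2_0 = complex(np.inf) if m2.b == 0 else m2.a / m2.b
        extra = [(chordal_distance(g1_0, g2_0), 0.0), (0.0, np.inf)]
        value, w_star = _sup_kappa(m1, m2, w, extra=extra)
        return NuGapResult(value=value, band="global", winding_ok=True, argmax_freq=w_star)

    if not isinstance(band, FrequencyBand):
        raise ValueError(f"band must be a FrequencyBand or 'global', got {band!r}")
    w = np.linspace(band.w_lo, band.w_hi, cfg.freq_grid_size)
    value, w_star = _sup_kappa(m1, m2, w)
    return NuGapResult(value=value, band=band, winding_ok=True, argmax_freq=w_star)
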