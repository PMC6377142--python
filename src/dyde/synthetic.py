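"""Synthetic two-condition fixtures with known link dynamics.

The generator wires oscillatory driver genes into a cascade (a DAG where
every non-driver gene has exactly one regulator) with first-order link
kinetics, replaces one link's parameters in the perturbed condition, and
adds independent Gaussian measurement noise per replicate.  Downstream
trajectories are produced by the same exact first-order-hold integrator
used for identification, so ground truth is recoverable from a noiseless
draw.  A labeled rhythmic/arrhythmic series generator supports classifier
training and benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dyde.data_model import AnalysisConfig, ExpressionDataset
from dyde.rhythmicity import PseudoSine, pseudo_sine_eval
from dyde.sysid import FirstOrderModel, simulate

__all__ = ["DriverSpec", "SyntheticSpec", "simulate_pair", "make_labeled_series"]


@dataclass(frozen=True)
class DriverSpec:
    """Oscillatory waveform of a root gene: mean + pseudo-sine (p1 == p2
    gives a plain sinusoid)."""

    A: float = 1.0
    phi1: float = 0.0
    p1: float = 24.0
    p2: float = 24.0
    mean: float = 5.0

    def waveform(self, times: np.ndarray) -> np.ndarray:
        return self.mean + pseudo_sine_eval(PseudoSine(self.A, self.phi1, self.p1, self.p2), times)


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint for a two-condition synthetic experiment.

    ``adjacency`` maps (source, target) to link parameters (a, b, c);
    every non-driver gene must have exactly one regulator and the graph
    must be acyclic from the drivers.  ``perturbed_link`` names the one
    link whose parameters are replaced by ``perturbed_params`` in the
    second condition.  ``noise_sd`` is a fraction of each gene's noiseless
    signal standard deviation.
    """

    drivers: dict[str, DriverSpec]
    adjacency: dict[tuple[str, str], tuple[float, float, float]]
    perturbed_link: tuple[str, str] | None = None
    perturbed_params: tuple[float, float, float] | None = None
    perturbed_drivers: dict[str, DriverSpec] = field(default_factory=dict)
    noise_sd: float = 0.0
    n_replicates: int = 2
    duration_h: float = 48.0
    dt_h: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.perturbed_link is not None:
            if self.perturbed_link not in self.adjacency:
                raise ValueError(f"perturbed link {self.perturbed_link} not in adjacency")
            if self.perturbed_params is None:
                raise ValueError("perturbed_params required with perturbed_link")
        targets = [t for _, t in self.adjacency]
        if len(set(targets)) != len(targets):
            raise ValueError("each non-driver gene must have exactly one regulator")
        for s, t in self.adjacency:
            if t in self.drivers:
                raise ValueError(f"driver {t} cannot be a regulation target")

    @property
    def genes(self) -> list[str]:
        ordered = list(self.drivers)
        for _, t in self.topological_links():
            if t not in ordered:
                ordered.append(t)
        return ordered

    def topological_links(self) -> list[tuple[str, str]]:
        """Adjacency keys sorted so every source precedes its target."""
        resolved = set(self.drivers)
        pending = dict(self.adjacency)
        order: list[tuple[str, str]] = []
        while pending:
            ready = sorted(k for k in pending if k[0] in resolved)
            if not ready:
                raise ValueError(f"cyclic or driverless adjacency: {sorted(pending)}")
            for k in ready:
                order.append(k)
                resolved.add(k[1])
                del pending[k]
        return order

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration_h / self.dt_h + 1e-9)) + 1
        return self.dt_h * np.arange(n)


def _trajectories(spec: SyntheticSpec, perturbed: bool) -> dict[str, np.ndarray]:
    times = spec.times
    drivers = dict(spec.drivers)
    if perturbed:
        drivers.update(spec.perturbed_drivers)
    traj = {g: d.waveform(times) for g, d in drivers.items()}
    for key in spec.topological_links():
        a, b, c = spec.adjacency[key]
        if perturbed and key == spec.perturbed_link:
            a, b, c = spec.perturbed_params
        src, tgt = key
        u = traj[src]
        x0 = (a * u[0] + c) / b if b > 0 else 0.0
        traj[tgt] = simulate(FirstOrderModel(a=a, b=b, c=c, x0=x0), u, times)
    return traj


def simulate_pair(spec: SyntheticSpec) -> tuple[ExpressionDataset, ExpressionDataset, set]:
    """Generate (baseline, perturbed) datasets plus the true adjacency.

    Deterministic for a fixed spec (same seed gives bit-identical output).
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times
    genes = spec.genes
    datasets = []
    for condition, perturbed in (("baseline", False), ("perturbed", True)):
        traj = _trajectories(spec, perturbed)
        values = np.empty((len(genes), spec.n_replicates, times.size))
        for i, g in enumerate(genes):
            clean = traj[g]
            sd = spec.noise_sd * float(np.std(clean))
            for r in range(spec.n_replicates):
                noise = rng.normal(scale=sd, size=times.size) if sd > 0 else 0.0
                values[i, r] = clean + noise
        datasets.append(ExpressionDataset(tuple(genes), times, values, condition=condition))
    truth = set(spec.adjacency)
    return datasets[0], datasets[1], truth


# ---------------------------------------------------------------------------
# Labeled rhythmic / arrhythmic series

# Dominant waveform classes: symmetric, front-loaded and back-loaded
# half-cycles (full-period offsets around the overall period).
_PROFILE_OFFSETS = (0.0, 3.8, -7.3)


def make_labeled_series(n_rhythmic: int, n_arrhythmic: int,
                        cfg: AnalysisConfig | None = None,
                        seed: int = 0,
                        noise_sd: float = 0.1,
                        n_replicates: int = 2,
                        duration_h: float = 44.0,
                        dt_h: float = 4.0) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Labeled training/benchmark series for the rhythmicity classifier.

    Rhythmic series are pseudo-sines drawn from the three dominant profile
    classes ((p, p), (p+3.8, p-3.8), (p-7.3, p+7.3), overall period p in
    [20, 28] h) plus Gaussian noise; arrhythmic series are white noise or
    noisy linear trends.  Returns (series list of shape
    (n_replicates, n_times), boolean labels, times).
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed)
    n_t = int(np.floor(duration_h / dt_h + 1e-9)) + 1
    times = dt_h * np.arange(n_t)
    series: list[np.ndarray] = []
    labels: list[bool] = []
    for _ in range(n_rhythmic):
        p = rng.uniform(20.0, 28.0)
        off = _PROFILE_OFFSETS[rng.integers(3)]
        params = PseudoSine(A=rng.uniform(0.5, 2.0), phi1=rng.uniform(0, 2 * np.pi),
                            p1=p + off, p2=p - off)
        clean = rng.uniform(4.0, 10.0) + pseudo_sine_eval(params, times)
        reps = clean[None, :] + rng.normal(scale=noise_sd, size=(n_replicates, n_t))
        series.append(reps)
        labels.append(True)
    for _ in range(n_arrhythmic):
        base = rng.uniform(4.0, 10.0)
        if rng.random() < 0.5:
            clean = base + np.zeros(n_t)
        else:
            clean = base + rng.uniform(-0.05, 0.05) * times
        sd = rng.uniform(0.3, 1.0)
        reps = clean[None, :] + rng.normal(scale=sd, size=(n_replicates, n_t))
        series.append(reps)
        labels.append(False)
    return series, np.array(labels, dtype=bool), times
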