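"""Ground-truth-labelled synthetic smFRET trajectories and EMSA titrations.

The trajectory generator emulates TIRF recordings of surface-immobilized
molecules drawn from a small number of *static, non-interconverting*
FRET states: per molecule a state is drawn from the configured mixture,
both fluorophores photobleach after exponentially distributed lifetimes,
and Gaussian camera noise is added independently per channel. Before any
bleach the expected channel intensities are I_A = E*T and I_D = (1-E)*T
(T the total emission, E the state's FRET mean); after acceptor bleach
the donor recovers the full intensity (energy transfer lost); after
donor bleach both channels drop to a zero-mean background. Negative
noise samples are retained; clipping would bias downstream FRET
estimates.

The titration generator draws fraction-bound values from the Hill
binding isotherm with additive Gaussian noise, truncated to [0, 1.2] to
mimic gel-integration overshoot.

With per-channel noise sigma s and total intensity T, first-order
propagation gives a per-frame FRET sd of s * sqrt(E^2 + (1-E)^2) / T;
the default s = 6.5 at T = 100 yields a FRET sd of ~0.05 for states in
the 0.2-0.5 range, so peaks 0.1 apart remain separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binding import HillParameters, TitrationSeries, hill_fraction_bound
from .traces import IntensityTrace

__all__ = [
    "ConfigurationError",
    "TraceSimConfig",
    "TitrationSimConfig",
    "TraceGroundTruth",
    "TitrationGroundTruth",
    "simulate_trace",
    "simulate_ensemble",
    "simulate_titration",
    "traces_to_frame",
    "frame_to_traces",
    "write_traces",
    "read_traces",
    "write_titrations",
    "read_titrations",
]


class ConfigurationError(ValueError):
    """Raised when a simulation config violates one of its invariants."""


@dataclass(frozen=True)
class TraceSimConfig:
    """Configuration of a static-state trajectory ensemble.

    ``states`` lists (fret_mean, weight) pairs; weights must sum to 1.
    Lifetimes are exponential means in frames. ``scale_noise`` enables an
    optional mode in which the channel sigma scales with the square root
    of the expected signal (shot-noise-like); the default is constant
    sigma per channel.
    """

    n_molecules: int = 100
    frame_interval: float = 0.1
    n_frames: int = 1000
    states: Tuple[Tuple[float, float], ...] = ((0.2, 0.44), (0.3, 0.45), (0.4, 0.11))
    total_intensity: float = 100.0
    noise_sigma: float = 6.5
    donor_bleach_lifetime: float = 300.0
    acceptor_bleach_lifetime: float = 450.0
    interconversion: bool = False
    scale_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")
        if self.n_frames < 10:
            raise ConfigurationError("n_frames must be >= 10")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        if len(self.states) < 1:
            raise ConfigurationError("at least one FRET state is required")
        weights = np.array([w for _, w in self.states], dtype=float)
        means = np.array([m for m, _ in self.states], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("state weights must sum to 1 within 1e-9")
        if np.any(weights < 0):
            raise ConfigurationError("state weights must be non-negative")
        if np.any((means < 0) | (means > 1)):
            raise ConfigurationError("state fret_means must lie in [0, 1]")
        if self.donor_bleach_lifetime <= 0 or self.acceptor_bleach_lifetime <= 0:
            raise ConfigurationError("bleach lifetimes must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.interconversion:
            raise ConfigurationError(
                "interconversion is not modelled: states are static and "
                "non-interconverting"
            )

    @property
    def fret_means(self) -> np.ndarray:
        return np.array([m for m, _ in self.states], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.states], dtype=float)

    @classmethod
    def from_dict(cls, d: dict) -> "TraceSimConfig":
        d = dict(d)
        if "states" in d:
            d["states"] = tuple((float(m), float(w)) for m, w in d["states"])
        return cls(**d)


@dataclass(frozen=True)
class TitrationSimConfig:
    """Configuration of simulated EMSA fraction-bound titrations."""

    hill_params: HillParameters = field(
        default_factory=lambda: HillParameters(k_d_app=17e-9, n=1.0, a=1.0, b=0.0)
    )
    concentrations: Tuple[float, ...] = tuple(np.geomspace(1e-12, 2.5e-6, 20))
    noise_sigma: float = 0.05
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) < 2:
            raise ConfigurationError("at least two concentrations are required")
        if np.any(conc <= 0):
            raise ConfigurationError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ConfigurationError("concentrations must be strictly increasing")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "TitrationSimConfig":
        d = dict(d)
        if "hill_params" in d:
            d["hill_params"] = HillParameters(**d["hill_params"])
        if "concentrations" in d:
            d["concentrations"] = tuple(float(c) for c in d["concentrations"])
        return cls(**d)


@dataclass
class TraceGroundTruth:
    """Per-molecule simulation truth: state labels and bleach frames.

    Bleach frames are the index of the first bleached frame; ``inf``
    when the fluorophore survives the recording window.
    """

    state_index: np.ndarray
    donor_bleach_frame: np.ndarray
    acceptor_bleach_frame: np.ndarray
    fret_means: np.ndarray

    def realized_proportions(self) -> np.ndarray:
        counts = np.bincount(self.state_index, minlength=len(self.fret_means))
        return counts / counts.sum()


@dataclass
class TitrationGroundTruth:
    params: HillParameters
    noise_sigma: float


def _simulate_channels(
    config: TraceSimConfig, fret_mean: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, float]:
    n = config.n_frames
    T = config.total_intensity
    td = rng.exponential(config.donor_bleach_lifetime)
    ta = rng.exponential(config.acceptor_bleach_lifetime)
    donor_frame = np.floor(td) if td < n else np.inf
    acceptor_frame = np.floor(ta) if ta < n else np.inf

    t = np.arange(n)
    donor = np.where(t < donor_frame, (1.0 - fret_mean) * T, 0.0)
    acceptor = np.where(t < min(donor_frame, acceptor_frame), fret_mean * T, 0.0)
    # Acceptor gone but donor alive: transfer is lost, donor emits fully.
    donor = np.where((t >= acceptor_frame) & (t < donor_frame), T, donor)

    if config.noise_sigma > 0:
        if config.scale_noise:
            sd_d = config.noise_sigma * np.sqrt(np.clip(donor, 0, None) / T + 1e-12)
            sd_a = config.noise_sigma * np.sqrt(np.clip(acceptor, 0, None) / T + 1e-12)
        else:
            sd_d = sd_a = config.noise_sigma
        donor = donor + rng.normal(0.0, 1.0, n) * sd_d
        acceptor = acceptor + rng.normal(0.0, 1.0, n) * sd_a
    return donor, acceptor, donor_frame, acceptor_frame


def simulate_trace(
    config: TraceSimConfig, state_index: int
) -> tuple[IntensityTrace, TraceGroundTruth]:
    """Simulate one molecule in the given state (seeded from the config)."""
    if not 0 <= state_index < len(config.states):
        raise ConfigurationError("state_index out of range")
    rng = np.random.default_rng(config.seed)
    fret_mean = config.states[state_index][0]
    donor, acceptor, td, ta = _simulate_channels(config, fret_mean, rng)
    time = np.arange(config.n_frames) * config.frame_interval
    trace = IntensityTrace("mol0000", time=time, donor=donor, acceptor=acceptor)
    gt = TraceGroundTruth(
        state_index=np.array([state_index]),
        donor_bleach_frame=np.array([td]),
        acceptor_bleach_frame=np.array([ta]),
        fret_means=config.fret_means,
    )
    return trace, gt


def simulate_ensemble(
    config: TraceSimConfig,
) -> tuple[list[IntensityTrace], TraceGroundTruth]:
    """Simulate an ensemble; states assigned by a multinomial draw.

    Deterministic under a fixed ``config.seed``: the state assignment and
    every molecule's noise stream flow from a single generator.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.states)
    state_idx = rng.choice(k, size=config.n_molecules, p=config.weights)
    time = np.arange(config.n_frames) * config.frame_interval
    traces: list[IntensityTrace] = []
    td = np.empty(config.n_molecules)
    ta = np.empty(config.n_molecules)
    for i, si in enumerate(state_idx):
        donor, acceptor, td[i], ta[i] = _simulate_channels(
            config, config.states[si][0], rng
        )
        traces.append(
            IntensityTrace(f"mol{i:04d}", time=time, donor=donor, acceptor=acceptor)
        )
    gt = TraceGroundTruth(
        state_index=state_idx.astype(int),
        donor_bleach_frame=td,
        acceptor_bleach_frame=ta,
        fret_means=config.fret_means,
    )
    return traces, gt


def simulate_titration(
    config: TitrationSimConfig,
) -> tuple[list[TitrationSeries], TitrationGroundTruth]:
    """Simulate replicate fraction-bound titrations from the Hill isotherm."""
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations, dtype=float)
    p = config.hill_params
    theta0 = hill_fraction_bound(conc, p.k_d_app, p.n, p.a, p.b)
    series = []
    for r in range(config.n_replicates):
        theta = theta0 + rng.normal(0.0, config.noise_sigma, len(conc)) \
            if config.noise_sigma > 0 else theta0.copy()
        theta = np.clip(theta, 0.0, 1.2)
        series.append(
            TitrationSeries(
                replicate_id=f"rep{r}", concentration=conc, fraction_bound=theta
            )
        )
    return series, TitrationGroundTruth(params=p, noise_sigma=config.noise_sigma)


# ---------------------------------------------------------------------------
# Tidy-table I/O


def traces_to_frame(traces: Sequence[IntensityTrace]) -> pd.DataFrame:
    """Stack traces into a tidy table (molecule_id, frame, time_s, I_D, I_A)."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(len(tr)),
                    "time_s": tr.time,
                    "I_D": tr.donor,
                    "I_A": tr.acceptor,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[IntensityTrace]:
    traces = []
    for mol, sub in df.groupby("molecule_id", sort=True):
        sub = sub.sort_values("frame")
        traces.append(
            IntensityTrace(
                str(mol),
                time=sub["time_s"].to_numpy(),
                donor=sub["I_D"].to_numpy(),
                acceptor=sub["I_A"].to_numpy(),
            )
        )
    return traces


def write_traces(
    traces: Sequence[IntensityTrace],
    out_dir: str | Path,
    ground_truth: Optional[TraceGroundTruth] = None,
) -> Path:
    """Write traces as CSV (plus a ground-truth JSON sidecar when given)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "traces.csv"
    traces_to_frame(traces).to_csv(csv_path, index=False)
    if ground_truth is not None:
        gt = {
            "state_index": ground_truth.state_index.tolist(),
            "donor_bleach_frame": ground_truth.donor_bleach_frame.tolist(),
            "acceptor_bleach_frame": ground_truth.acceptor_bleach_frame.tolist(),
            "fret_means": ground_truth.fret_means.tolist(),
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return csv_path


def read_traces(path: str | Path) -> list[IntensityTrace]:
    path = Path(path)
    if path.is_dir():
        path = path / "traces.csv"
    return frame_to_traces(pd.read_csv(path))


def write_titrations(series: Sequence[TitrationSeries], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parts = [
        pd.DataFrame(
            {
                "replicate_id": s.replicate_id,
                "concentration_M": s.concentration,
                "fraction_bound": s.fraction_bound,
            }
        )
        for s in series
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    return path


def read_titrations(path: str | Path) -> list[TitrationSeries]:
    df = pd.read_csv(path)
    if {"bound_signal", "unbound_signal"}.issubset(df.columns):
        from .binding import compute_fraction_bound

        df = df.assign(
            fraction_bound=compute_fraction_bound(
                df["bound_signal"].to_numpy(), df["unbound_signal"].to_numpy()
            )
        )
        if "replicate_id" not in df.columns:
            df["replicate_id"] = "rep0"
    out = []
    for rep, sub in df.groupby("replicate_id", sort=True):
        sub = sub.sort_values("concentration_M")
        out.append(
            TitrationSeries(
                replicate_id=str(rep),
                concentration=sub["concentration_M"].to_numpy(),
                fraction_bound=sub["fraction_bound"].to_numpy(),
            )
        )
    return out
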