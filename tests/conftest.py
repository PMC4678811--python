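from __future__ import annotations

import numpy as np
import pytest

from trifret.synthetic import TraceSimConfig, simulate_ensemble
from trifret.traces import FretTrace, IntensityTrace, qc_select


def make_constant_trace(
    fret: float,
    total: float = 100.0,
    n_frames: int = 20,
    molecule_id: str = "m0",
) -> IntensityTrace:
    """Noiseless trace at a fixed FRET level with no bleaching."""
    time = 0.1 * np.arange(n_frames)
    return IntensityTrace(
        molecule_id,
        time=time,
        donor=np.full(n_frames, (1.0 - fret) * total),
        acceptor=np.full(n_frames, fret * total),
    )


def make_fret_trace(
    values: np.ndarray, molecule_id: str = "m0", qc_pass: bool = True
) -> FretTrace:
    """Directly assemble a QC-passed FretTrace from FRET values."""
    values = np.asarray(values, dtype=float)
    ft = FretTrace(
        molecule_id,
        fret=values,
        total=np.full(len(values), 100.0),
        valid=np.ones(len(values), dtype=bool),
        qc_pass=qc_pass,
        qc_reason="pass" if qc_pass else "synthetic_fail",
        is_static=True,
    )
    ft.mean_fret = float(values.mean())
    ft.bleach_frame = len(values)
    return ft


def sample_fret_traces(
    rng: np.random.Generator,
    means: list[float],
    counts: list[int],
    sigma: float = 0.05,
    n_frames: int = 200,
) -> list[FretTrace]:
    """FretTraces whose frames are Gaussian draws around given state means."""
    out = []
    i = 0
    for mean, count in zip(means, counts):
        for _ in range(count):
            vals = rng.normal(mean, sigma, n_frames)
            out.append(make_fret_trace(vals, molecule_id=f"m{i:04d}"))
            i += 1
    return out


@pytest.fixture(scope="session")
def small_ensemble():
    """A 40-molecule three-state ensemble with its QC output (seed 42)."""
    config = TraceSimConfig(n_molecules=40, seed=42)
    traces, gt = simulate_ensemble(config)
    fret_traces = qc_select(traces)
    return config, traces, gt, fret_traces
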