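"""Equilibrium binding analysis of EMSA titrations.

Fits the Hill isotherm

    theta = (a - b) / (1 + (K_d,app / [protein])^n) + b

to fraction-bound titration data, where theta is the fraction of RNA
bound, K_d,app the apparent dissociation constant, n the Hill
coefficient and a/b the upper/lower baselines. Replicate fits are
combined as an inverse-variance weighted mean with a weighted standard
deviation.

``REFERENCE_AFFINITIES`` holds the published apparent affinities for the
step-wise assembly of the yeast U4/U6 di-snRNP (15 titrations); rows
whose Hill coefficient is reported as exactly 1 with no uncertainty are
treated as fits with n fixed at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "HillParameters",
    "TitrationSeries",
    "HillFitResult",
    "CombinedAffinity",
    "REFERENCE_AFFINITIES",
    "hill_fraction_bound",
    "compute_fraction_bound",
    "fit_hill",
    "combine_replicates",
    "reference_table",
]


def hill_fraction_bound(
    concentration: np.ndarray | float,
    k_d_app: float,
    n: float,
    a: float = 1.0,
    b: float = 0.0,
) -> np.ndarray | float:
    """Hill isotherm: fraction bound at the given protein concentration."""
    concentration = np.asarray(concentration, dtype=float)
    return (a - b) / (1.0 + (k_d_app / concentration) ** n) + b


@dataclass(frozen=True)
class HillParameters:
    """Hill-fit parameter set. Concentrations are molar."""

    k_d_app: float
    n: float
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.k_d_app <= 0:
            raise ValueError("k_d_app must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")
        if self.a <= self.b:
            raise ValueError("upper baseline a must exceed lower baseline b")


@dataclass
class TitrationSeries:
    """One replicate titration: fraction bound versus protein concentration."""

    replicate_id: str
    concentration: np.ndarray
    fraction_bound: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if len(self.concentration) != len(self.fraction_bound):
            raise ValueError("concentration and fraction_bound length mismatch")
        if len(self.concentration) < 6:
            raise ValueError("a titration needs at least 6 points")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(self.fraction_bound)):
            raise ValueError("fraction_bound must be finite")


@dataclass
class HillFitResult:
    params: HillParameters
    stderr: dict
    rss: float
    n_fixed: bool
    flags: tuple = ()


@dataclass
class CombinedAffinity:
    k_d_app_mean: float
    k_d_app_sd: float
    n_mean: Optional[float]
    n_sd: Optional[float]
    n_replicates: int
    flags: tuple = ()


def compute_fraction_bound(bound_signal, unbound_signal):
    """theta = bound / (bound + unbound) from integrated gel-band signals.

    Signals must be non-negative; where both are zero the fraction is
    undefined and NaN is returned (with a warning) rather than raising.
    """
    bound = np.asarray(bound_signal, dtype=float)
    unbound = np.asarray(unbound_signal, dtype=float)
    if np.any(bound < 0) or np.any(unbound < 0):
        raise ValueError("band signals must be non-negative")
    total = bound + unbound
    undefined = total == 0
    if np.any(undefined):
        warnings.warn("fraction bound undefined where both band signals are zero")
    theta = np.full(bound.shape, np.nan)
    np.divide(bound, total, out=theta, where=~undefined)
    if theta.ndim == 0:
        return float(theta)
    return theta


def _hill_model() -> lmfit.Model:
    return lmfit.Model(
        lambda conc, kd, n, a, b: (a - b) / (1.0 + (kd / conc) ** n) + b,
        independent_vars=["conc"],
    )


def fit_hill(
    series: TitrationSeries,
    fix_n: Optional[float] = None,
    n_starts: int = 5,
) -> HillFitResult:
    """Fit the Hill isotherm to one titration by bounded least squares.

    Free parameters are bounded (K_d,app > 0, n in (0.3, 6), a in
    (0.5, 1.5), b in (-0.2, 0.5)); when ``fix_n`` is given the Hill
    coefficient is held at that value. The fit is multi-started from
    ``n_starts`` log-spaced K_d seeds spanning the titration range and
    the lowest-residual solution wins. A K_d landing more than 10x
    outside the titrated range is flagged, not rejected.
    """
    conc = series.concentration
    theta = series.fraction_bound
    model = _hill_model()
    best = None
    for kd0 in np.geomspace(conc.min(), conc.max(), n_starts):
        params = model.make_params(kd=kd0, n=1.0 if fix_n is None else fix_n,
                                   a=1.0, b=0.0)
        params["kd"].set(min=conc.min() * 1e-4, max=conc.max() * 1e4)
        if fix_n is None:
            params["n"].set(min=0.3, max=6.0)
        else:
            params["n"].set(value=fix_n, vary=False)
        params["a"].set(min=0.5, max=1.5)
        params["b"].set(min=-0.2, max=0.5)
        try:
            res = model.fit(theta, params, conc=conc)
        except Exception:  # a start may fail; others can still succeed
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("Hill fit failed to converge from every start")

    p = best.params
    stderr = {
        name: (float(p[name].stderr) if p[name].stderr is not None else np.nan)
        for name in ("kd", "n", "a", "b")
    }
    flags = []
    if p["kd"].value > conc.max() * 10 or p["kd"].value < conc.min() / 10:
        flags.append("kd_outside_titration_range")
    return HillFitResult(
        params=HillParameters(
            k_d_app=float(p["kd"].value),
            n=float(p["n"].value),
            a=float(p["a"].value),
            b=float(p["b"].value),
        ),
        stderr=stderr,
        rss=float(best.chisqr),
        n_fixed=fix_n is not None,
        flags=tuple(flags),
    )


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    mean = float(np.sum(weights * values) / wsum)
    sd = float(np.sqrt(np.sum(weights * (values - mean) ** 2) / wsum))
    return mean, sd


def combine_replicates(fits: Sequence[HillFitResult]) -> CombinedAffinity:
    """Inverse-variance weighted combination of replicate Hill fits.

    The reported uncertainty is the weighted standard deviation of the
    replicate estimates about the weighted mean (one sd). Fits with a
    zero or undefined standard error trigger a flagged fall-back to the
    unweighted mean.
    """
    if len(fits) < 2:
        raise ValueError("combine_replicates requires at least two fits")
    kd = np.array([f.params.k_d_app for f in fits])
    se = np.array([f.stderr.get("kd", np.nan) for f in fits])
    flags = []
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        weights = np.ones_like(kd)
        flags.append("unweighted_fallback")
    else:
        weights = 1.0 / se**2
    kd_mean, kd_sd = _weighted_mean_sd(kd, weights)

    free = [f for f in fits if not f.n_fixed]
    n_mean = n_sd = None
    if free:
        nv = np.array([f.params.n for f in free])
        nse = np.array([f.stderr.get("n", np.nan) for f in free])
        if np.any(~np.isfinite(nse)) or np.any(nse <= 0):
            nw = np.ones_like(nv)
        else:
            nw = 1.0 / nse**2
        n_mean, n_sd = _weighted_mean_sd(nv, nw)
    return CombinedAffinity(
        k_d_app_mean=kd_mean,
        k_d_app_sd=kd_sd,
        n_mean=n_mean,
        n_sd=n_sd,
        n_replicates=len(fits),
        flags=tuple(flags),
    )


# Published step-wise assembly affinities (EMSA, yeast U4/U6 di-snRNP).
# hill_sd None means the Hill coefficient was reported as exactly 1,
# i.e. held fixed during fitting. K_d values in nM.
REFERENCE_AFFINITIES: tuple[dict, ...] = (
    {"complex": "U4/U6", "titrant": "Snu13", "kd_nM": 17.0, "kd_sd_nM": 1.0, "hill": 1.0, "hill_sd": None},
    {"complex": "U4/U6", "titrant": "Prp31", "kd_nM": 243.0, "kd_sd_nM": 16.0, "hill": 1.9, "hill_sd": 0.2},
    {"complex": "U4/U6", "titrant": "Sm", "kd_nM": 89.0, "kd_sd_nM": 4.0, "hill": 3.5, "hill_sd": 0.4},
    {"complex": "U4/U6", "titrant": "LSm", "kd_nM": 5.0, "kd_sd_nM": 0.2, "hill": 1.7, "hill_sd": 0.1},
    {"complex": "U4/U6", "titrant": "Prp3/4", "kd_nM": 57.0, "kd_sd_nM": 2.0, "hill": 2.6, "hill_sd": 0.3},
    {"complex": "U4/U6/Snu13", "titrant": "Prp31", "kd_nM": 50.0, "kd_sd_nM": 4.0, "hill": 2.9, "hill_sd": 0.5},
    {"complex": "U4/U6/Snu13", "titrant": "Sm", "kd_nM": 92.0, "kd_sd_nM": 9.0, "hill": 2.2, "hill_sd": 0.4},
    {"complex": "U4/U6/Snu13", "titrant": "LSm", "kd_nM": 26.0, "kd_sd_nM": 1.0, "hill": 3.3, "hill_sd": 0.3},
    {"complex": "U4/U6/Snu13", "titrant": "Prp3/4", "kd_nM": 88.0, "kd_sd_nM": 8.0, "hill": 3.4, "hill_sd": 1.0},
    {"complex": "U4/U6/Snu13/Prp31", "titrant": "Sm", "kd_nM": 108.0, "kd_sd_nM": 9.0, "hill": 2.3, "hill_sd": 0.4},
    {"complex": "U4/U6/Snu13/Prp31", "titrant": "LSm", "kd_nM": 98.0, "kd_sd_nM": 34.0, "hill": 1.0, "hill_sd": None},
    {"complex": "U4/U6/Snu13/Prp31", "titrant": "Prp3/4", "kd_nM": 417.0, "kd_sd_nM": 43.0, "hill": 1.5, "hill_sd": 0.2},
    {"complex": "U4/U6/Snu13/Prp31/Sm", "titrant": "LSm", "kd_nM": 154.0, "kd_sd_nM": 15.0, "hill": 1.0, "hill_sd": None},
    {"complex": "U4/U6/Snu13/Prp31/Sm", "titrant": "Prp3/4", "kd_nM": 557.0, "kd_sd_nM": 75.0, "hill": 1.0, "hill_sd": None},
    {"complex": "U4/U6/Snu13/Prp31/Sm/LSm", "titrant": "Prp3/4", "kd_nM": 20.0, "kd_sd_nM": 1.0, "hill": 1.6, "hill_sd": 0.1},
)


def reference_table() -> pd.DataFrame:
    """The published affinity table as a DataFrame (K_d in nM)."""
    return pd.DataFrame(list(REFERENCE_AFFINITIES))
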