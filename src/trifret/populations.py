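"""Ensemble FRET histograms, Gaussian population fitting and comparison.

Pre-bleach frames of QC-passed molecules are pooled into a time-binned
FRET histogram; a sum of Gaussians is fit to the bin densities by
nonlinear least squares (mirroring histogram-level fitting rather than
frame-level EM); molecules are then assigned to the component whose
Gaussian density is highest at their pre-bleach mean FRET, giving
per-condition population fractions with bootstrap uncertainties.
Conditions are compared component-wise with Welch's t-test on replicate
fraction estimates.

The two-stage procedure used by :func:`two_stage_fit` first separates
molecules by FRET value (exact 1-D k-means), fits a single Gaussian to
each sub-population's histogram, and uses those means to seed the fit of
the overall histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy import stats

from .traces import FretTrace

__all__ = [
    "FretHistogram",
    "GaussianComponent",
    "MixtureModel",
    "PopulationSummary",
    "ConditionComparison",
    "MixtureFitError",
    "build_histogram",
    "fit_mixture",
    "two_stage_fit",
    "kmeans_1d",
    "assign_molecules",
    "compare_conditions",
]

DEFAULT_BIN_WIDTH = 0.02
DEFAULT_RANGE = (-0.2, 1.2)


class MixtureFitError(RuntimeError):
    """Mixture fit failed to converge; carries residual and parameters."""

    def __init__(self, message: str, residual: float, params: dict):
        super().__init__(message)
        self.residual = residual
        self.params = params


@dataclass
class FretHistogram:
    """Density-normalized histogram of pooled pre-bleach FRET frames."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_molecules: int
    n_frames: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        mass = float(np.sum(self.density * np.diff(self.bin_edges)))
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"histogram mass {mass} != 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")

    def density(self, x: np.ndarray | float) -> np.ndarray | float:
        z = (np.asarray(x, dtype=float) - self.mean) / self.sigma
        return np.exp(-0.5 * z * z) / (self.sigma * np.sqrt(2.0 * np.pi))


@dataclass
class MixtureModel:
    """Gaussian components sorted by ascending mean; weights sum to 1."""

    components: tuple[GaussianComponent, ...]
    fit_residual: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        comps = sorted(self.components, key=lambda c: c.mean)
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("component weights must sum to 1 within 1e-6")
        self.components = tuple(comps)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return sum(c.weight * c.density(x) for c in self.components)


@dataclass
class PopulationSummary:
    """Per-condition component fractions (sum to 1 over assigned molecules)."""

    condition: str
    fractions: np.ndarray
    errors: np.ndarray
    counts: np.ndarray
    n_molecules: int
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1 within 1e-6")


@dataclass
class ConditionComparison:
    condition_a: str
    condition_b: str
    component_index: int
    t_statistic: float
    p_value: float
    stars: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def build_histogram(
    traces: Sequence[FretTrace],
    bin_width: float = DEFAULT_BIN_WIDTH,
    fret_range: tuple[float, float] = DEFAULT_RANGE,
    per_molecule: bool = False,
) -> FretHistogram:
    """Pool pre-bleach FRET frames of QC-passed traces into a histogram.

    With ``per_molecule=True`` the histogram is built from per-molecule
    mean FRET values instead of pooled frames.
    """
    passed = [t for t in traces if t.qc_pass]
    if not passed:
        raise ValueError("no QC-passed traces to histogram")
    if per_molecule:
        values = np.array([t.mean_fret for t in passed])
    else:
        values = np.concatenate([t.prebleach_fret for t in passed])
    lo, hi = fret_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    return FretHistogram(
        bin_edges=edges,
        density=density,
        n_molecules=len(passed),
        n_frames=len(values),
    )


def _gaussian_sum_model(k: int) -> lmfit.Model:
    model = None
    for i in range(k):
        g = lmfit.models.GaussianModel(prefix=f"g{i}_")
        model = g if model is None else model + g
    return model


def fit_mixture(
    hist: FretHistogram,
    k: int,
    init_means: Optional[Sequence[float]] = None,
    init_sigmas: Optional[Sequence[float]] = None,
    fix_means: bool = False,
) -> MixtureModel:
    """Least-squares fit of a k-Gaussian sum to histogram bin densities.

    ``init_means`` seed (but do not constrain) the component centers;
    without them, centers start at evenly spaced quantiles of the binned
    distribution. With ``fix_means=True`` the centers are held at
    ``init_means`` and only widths and areas are fit — the second stage
    of the two-stage procedure, where per-population means determined
    separately are used to fit the peaks of the overall histogram
    (free-center fits of overlapping peaks are weakly identified).
    Component weights are the Gaussian areas normalized to unit sum;
    components are returned in ascending order of mean. A fit where two
    means coincide (closer than one bin) or a weight falls below 0.05 is
    flagged ``degenerate`` (over-fitting sentinel).
    """
    if fix_means and init_means is None:
        raise ValueError("fix_means requires init_means")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = hist.bin_centers
    y = hist.density
    nonempty = int(np.sum(y > 0))
    if nonempty < 5 * (3 * k) // 3:
        import warnings

        warnings.warn(
            f"only {nonempty} non-empty bins for a {k}-component fit",
            stacklevel=2,
        )
    if init_means is None:
        cdf = np.cumsum(y)
        cdf = cdf / cdf[-1]
        qs = (np.arange(k) + 0.5) / k
        init_means = np.interp(qs, cdf, x)
    init_means = np.asarray(init_means, dtype=float)
    if init_sigmas is None:
        init_sigmas = np.full(k, 0.05)
    init_sigmas = np.asarray(init_sigmas, dtype=float)
    order0 = np.argsort(init_means)
    init_means, init_sigmas = init_means[order0], init_sigmas[order0]
    model = _gaussian_sum_model(k)
    params = model.make_params()
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    peak = y.max()
    for i in range(k):
        if fix_means:
            params[f"g{i}_center"].set(value=float(init_means[i]), vary=False)
        else:
            params[f"g{i}_center"].set(value=float(init_means[i]), min=lo, max=hi)
        params[f"g{i}_sigma"].set(
            value=float(init_sigmas[i]), min=hist.bin_width / 4, max=0.5
        )
        params[f"g{i}_amplitude"].set(
            value=max(peak * 0.05 * np.sqrt(2 * np.pi) / k, 1e-6), min=0.0
        )
    result = model.fit(y, params, x=x)
    if not result.success:
        raise MixtureFitError(
            "mixture fit did not converge",
            residual=float(result.chisqr),
            params={n: float(p.value) for n, p in result.params.items()},
        )
    areas = np.array([result.params[f"g{i}_amplitude"].value for i in range(k)])
    means = np.array([result.params[f"g{i}_center"].value for i in range(k)])
    sigmas = np.array([result.params[f"g{i}_sigma"].value for i in range(k)])
    total = areas.sum()
    if total <= 0:
        raise MixtureFitError(
            "mixture fit collapsed to zero mass",
            residual=float(result.chisqr),
            params={n: float(p.value) for n, p in result.params.items()},
        )
    weights = areas / total
    order = np.argsort(means)
    comps = tuple(
        GaussianComponent(float(means[i]), float(sigmas[i]), float(weights[i]))
        for i in order
    )
    degenerate = bool(
        np.any(np.diff(means[order]) < hist.bin_width) or np.any(weights < 0.05)
    )
    return MixtureModel(
        components=comps,
        fit_residual=float(np.sqrt(result.chisqr / len(x))),
        degenerate=degenerate,
    )


def kmeans_1d(values: Sequence[float], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D k-means by dynamic programming over the sorted values.

    Returns (labels aligned with the input order, cluster centers in
    ascending order). Deterministic; O(k n^2).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= n")
    order = np.argsort(v, kind="stable")
    s = v[order]
    cum = np.concatenate([[0.0], np.cumsum(s)])
    cum2 = np.concatenate([[0.0], np.cumsum(s * s)])

    def sse(i: int, j: int) -> float:  # cost of s[i:j]
        m = j - i
        return cum2[j] - cum2[i] - (cum[j] - cum[i]) ** 2 / m

    INF = np.inf
    D = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                c = D[m - 1, i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            D[m, j] = best
            split[m, j] = arg
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = split[m, j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for c, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        labels_sorted[a:b] = c
        centers[c] = s[a:b].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centers


def two_stage_fit(
    traces: Sequence[FretTrace],
    k: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    fret_range: tuple[float, float] = DEFAULT_RANGE,
) -> MixtureModel:
    """Two-stage ensemble fit: per-population means first, then overall.

    Molecules are separated by pre-bleach mean FRET (exact 1-D k-means);
    a single Gaussian is fit to each sub-population's pooled-frame
    histogram, and those per-population means are then used — held
    fixed — to fit the peak widths and areas of the overall histogram.
    """
    passed = [t for t in traces if t.qc_pass]
    if len(passed) < k:
        raise ValueError("fewer QC-passed molecules than components")
    means = np.array([t.mean_fret for t in passed])
    labels, centers = kmeans_1d(means, k)
    init_means, init_sigmas = [], []
    for c in range(k):
        group = [t for t, lab in zip(passed, labels) if lab == c]
        try:
            sub = build_histogram(group, bin_width=bin_width, fret_range=fret_range)
            comp = fit_mixture(sub, 1).components[0]
            init_means.append(comp.mean)
            init_sigmas.append(comp.sigma)
        except (ValueError, MixtureFitError):
            init_means.append(float(centers[c]))
            init_sigmas.append(0.05)
    overall = build_histogram(passed, bin_width=bin_width, fret_range=fret_range)
    return fit_mixture(
        overall, k, init_means=init_means, init_sigmas=init_sigmas, fix_means=True
    )


def assign_molecules(
    traces: Sequence[FretTrace],
    model: MixtureModel,
    condition: str = "",
    n_boot: int = 1000,
    seed: int = 0,
    max_n_sigma: float = 3.0,
) -> PopulationSummary:
    """Assign molecules to mixture components and estimate fractions.

    Each QC-passed static molecule goes to the component with the
    highest Gaussian density at its pre-bleach mean FRET (ties to the
    lower mean); molecules farther than ``max_n_sigma`` sigmas from
    every component are counted as unassigned. Fractions are over
    assigned molecules; uncertainties come from a bootstrap over
    molecules (fixed seed, order-independent).
    """
    usable = [t for t in traces if t.qc_pass and t.is_static is not False]
    if not usable:
        raise ValueError("no usable (QC-passed, non-dynamic) molecules")
    x = np.array([t.mean_fret for t in usable])
    k = len(model.components)
    z = np.abs(
        (x[:, None] - model.means[None, :])
        / np.array([c.sigma for c in model.components])[None, :]
    )
    logdens = -np.log([c.sigma for c in model.components])[None, :] - 0.5 * z**2
    labels = np.argmin(
        np.where(
            logdens == logdens.max(axis=1, keepdims=True), np.arange(k)[None, :], k
        ),
        axis=1,
    )  # argmax with ties resolved to the lower-mean component
    unassigned = z.min(axis=1) > max_n_sigma
    labels_assigned = np.sort(labels[~unassigned])
    n_assigned = len(labels_assigned)
    if n_assigned == 0:
        raise ValueError("every molecule fell outside all components")
    counts = np.bincount(labels_assigned, minlength=k)
    fractions = counts / n_assigned

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, k))
    for b in range(n_boot):
        resampled = labels_assigned[rng.integers(0, n_assigned, n_assigned)]
        boot[b] = np.bincount(resampled, minlength=k) / n_assigned
    errors = boot.std(axis=0, ddof=1)
    return PopulationSummary(
        condition=condition,
        fractions=fractions,
        errors=errors,
        counts=counts,
        n_molecules=n_assigned,
        n_unassigned=int(unassigned.sum()),
    )


_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def compare_conditions(
    fractions_a: Sequence[float],
    fractions_b: Sequence[float],
    component_index: int = 0,
    condition_a: str = "a",
    condition_b: str = "b",
) -> ConditionComparison:
    """Welch two-sample t-test on replicate fraction estimates.

    Significance stars follow the 0.05 / 0.01 / 0.001 convention.
    Identical degenerate samples (zero variance, equal means) give
    t = 0, p = 1.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            "need >= 2 replicate fraction estimates per condition; "
            "generate bootstrap or pseudo-replicates first"
        )
    tiny = 1e-24  # float-roundoff variance on identical replicate sets
    if a.var() <= tiny and b.var() <= tiny:
        if abs(a.mean() - b.mean()) <= 1e-12:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf, 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    stars = "ns"
    for thresh, symbol in _STAR_THRESHOLDS:
        if p < thresh:
            stars = symbol
            break
    return ConditionComparison(
        condition_a=condition_a,
        condition_b=condition_b,
        component_index=component_index,
        t_statistic=float(t_stat),
        p_value=float(p),
        stars=stars,
    )
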