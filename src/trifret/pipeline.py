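"""End-to-end orchestration and reproduction fixtures.

Wires the stages together (simulate -> trace QC -> population fit ->
geometry; simulate -> titration -> Hill fit) and bundles the synthetic
fixtures that emulate the published experiments: the stem I/stem II
coaxial-stacking construct (single 0.2-FRET state, 108 molecules), the
two three-state junction constructs (102 and 105 molecules) with their
protein-shifted conformer populations, and the 15-row affinity table.

All randomness flows from a single seed; per-replicate sub-seeds are
drawn from one generator so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .binding import REFERENCE_AFFINITIES, HillParameters, fit_hill
from .geometry import (
    ForsterParams,
    HelixArm,
    estimate_distances,
    fret_to_distance,
    rank_stacking_models,
)
from .populations import (
    MixtureModel,
    PopulationSummary,
    assign_molecules,
    two_stage_fit,
)
from .synthetic import (
    TitrationSimConfig,
    TraceSimConfig,
    simulate_ensemble,
    simulate_titration,
)
from .traces import QCPolicy, classify_static, qc_select

__all__ = [
    "EnsemblePreset",
    "STEM1_STEM2_PRESET",
    "STEM2_LOOP_CONDITIONS",
    "STEM1_LOOP_CONDITIONS",
    "JUNCTION_ARMS",
    "ConditionResult",
    "RunReport",
    "analyze_ensemble",
    "run_condition",
    "replicate_population_fractions",
    "run_pipeline",
    "repro",
]


@dataclass(frozen=True)
class EnsemblePreset:
    """A synthetic ensemble emulating one published smFRET condition.

    ``reference_pct`` maps component index (ascending FRET mean) to the
    published (percentage, uncertainty) where one was printed;
    ``population_one_index`` is the component corresponding to the
    conformer with the U4 5' stem-loop nearer stem I under that
    construct's labelling.
    """

    name: str
    n_molecules: int
    states: tuple[tuple[float, float], ...]
    population_one_index: Optional[int]
    reference_pct: dict = field(default_factory=dict)


#: Stem I / stem II labelled construct: one static state at 0.2 FRET.
STEM1_STEM2_PRESET = EnsemblePreset(
    name="stemI-stemII naked",
    n_molecules=108,
    states=((0.2, 1.0),),
    population_one_index=None,
    reference_pct={0: (100.0, 0.0)},
)

#: Stem II / 5' stem-loop labelled construct (states 0.2 / 0.3 / 0.4).
#: Population 1 (loop nearer stem I, i.e. farther from the stem II
#: label) is the lowest-FRET component; the minor 0.4 population stays
#: at ~11% under every condition.
STEM2_LOOP_CONDITIONS: dict[str, EnsemblePreset] = {
    "naked": EnsemblePreset(
        "stemII-loop naked", 102,
        ((0.2, 0.44), (0.3, 0.45), (0.4, 0.11)), 0,
        {0: (44.0, 7.0), 1: (45.0, 7.0), 2: (11.0, 3.0)},
    ),
    "+Snu13": EnsemblePreset(
        "stemII-loop +Snu13", 106,
        ((0.2, 0.44), (0.3, 0.45), (0.4, 0.11)), 0,
        {0: (44.0, 7.0)},
    ),
    "+Prp31": EnsemblePreset(
        "stemII-loop +Prp31", 107,
        ((0.2, 0.28), (0.3, 0.61), (0.4, 0.11)), 0,
        {0: (28.0, 5.0)},
    ),
    "+Prp3/4": EnsemblePreset(
        "stemII-loop +Prp3/4", 105,
        ((0.2, 0.58), (0.3, 0.31), (0.4, 0.11)), 0,
        {0: (58.0, 7.0)},
    ),
    "+Snu13+Prp31": EnsemblePreset(
        "stemII-loop +Snu13+Prp31", 103,
        ((0.2, 0.32), (0.3, 0.57), (0.4, 0.11)), 0,
        {0: (32.0, 6.0)},
    ),
}

#: Stem I / 5' stem-loop labelled construct (states 0.3 / 0.4 / 0.5).
#: Population 1 (loop nearer stem I) is the dominant 0.4 component.
STEM1_LOOP_CONDITIONS: dict[str, EnsemblePreset] = {
    "naked": EnsemblePreset(
        "stemI-loop naked", 105,
        ((0.3, 0.41), (0.4, 0.51), (0.5, 0.08)), 1,
        {0: (41.0, 6.0), 1: (51.0, 6.0), 2: (8.0, 3.0)},
    ),
}

#: Arm lengths of the junction, as ideal A-form duplexes.
JUNCTION_ARMS = (
    HelixArm("stem I", 10),
    HelixArm("stem II", 17),
    HelixArm("5' stem-loop", 9),
)


@dataclass
class ConditionResult:
    """Full-pipeline output for one simulated condition."""

    preset: EnsemblePreset
    summary: PopulationSummary
    model: MixtureModel
    true_proportions: np.ndarray
    n_simulated: int
    n_qc_passed: int
    n_static: int
    seed: int

    def fractions_pct(self) -> np.ndarray:
        return 100.0 * self.summary.fractions


def make_trace_config(preset: EnsemblePreset, seed: int, **overrides) -> TraceSimConfig:
    kwargs = dict(
        n_molecules=preset.n_molecules, states=preset.states, seed=seed
    )
    kwargs.update(overrides)
    return TraceSimConfig(**kwargs)


def analyze_ensemble(
    traces,
    k: int,
    policy: Optional[QCPolicy] = None,
    condition: str = "",
    seed: int = 0,
):
    """QC + static classification + two-stage mixture fit + assignment."""
    policy = policy or QCPolicy()
    fret_traces = qc_select(traces, policy)
    for ft in fret_traces:
        if ft.qc_pass:
            classify_static(
                ft,
                min_dwell=policy.min_dwell,
                delta=policy.static_delta,
                penalty_scale=policy.penalty_scale,
            )
    static = [ft for ft in fret_traces if ft.qc_pass and ft.is_static]
    model = two_stage_fit(static, k)
    summary = assign_molecules(static, model, condition=condition, seed=seed)
    return summary, model, fret_traces


def run_condition(
    preset: EnsemblePreset,
    seed: int,
    policy: Optional[QCPolicy] = None,
    **config_overrides,
) -> ConditionResult:
    """Simulate a preset condition and analyze it end to end."""
    config = make_trace_config(preset, seed, **config_overrides)
    traces, gt = simulate_ensemble(config)
    summary, model, fret_traces = analyze_ensemble(
        traces, k=len(preset.states), policy=policy,
        condition=preset.name, seed=seed,
    )
    return ConditionResult(
        preset=preset,
        summary=summary,
        model=model,
        true_proportions=gt.realized_proportions(),
        n_simulated=len(traces),
        n_qc_passed=sum(ft.qc_pass for ft in fret_traces),
        n_static=sum(bool(ft.qc_pass and ft.is_static) for ft in fret_traces),
        seed=seed,
    )


def replicate_population_fractions(
    preset: EnsemblePreset,
    n_replicates: int,
    seed: int,
    component_index: Optional[int] = None,
    policy: Optional[QCPolicy] = None,
) -> np.ndarray:
    """Population fractions across independently simulated replicates.

    Each pseudo-replicate is a fresh ensemble at the preset's molecule
    count, analyzed end to end; sub-seeds derive from ``seed``.
    """
    if component_index is None:
        component_index = preset.population_one_index or 0
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    out = np.empty(n_replicates)
    for i, s in enumerate(sub_seeds):
        result = run_condition(preset, int(s), policy=policy)
        out[i] = result.summary.fractions[component_index]
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration and reporting


@dataclass
class PipelineConfig:
    """One-document configuration of a full run (all defaults embedded)."""

    seed: int = 0
    out_dir: Optional[str] = None
    trace_config: Optional[TraceSimConfig] = None
    n_components: int = 3
    qc_policy: QCPolicy = field(default_factory=QCPolicy)
    forster: ForsterParams = field(default_factory=ForsterParams)
    arms: tuple[HelixArm, ...] = JUNCTION_ARMS
    titration_config: Optional[TitrationSimConfig] = None
    fix_hill_n: Optional[float] = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        kwargs: dict = {k: d[k] for k in ("seed", "out_dir", "n_components", "fix_hill_n") if k in d}
        if "trace_config" in d:
            kwargs["trace_config"] = TraceSimConfig.from_dict(d["trace_config"])
        if "titration_config" in d:
            kwargs["titration_config"] = TitrationSimConfig.from_dict(d["titration_config"])
        if "qc_policy" in d:
            kwargs["qc_policy"] = QCPolicy(**d["qc_policy"])
        if "forster" in d:
            kwargs["forster"] = ForsterParams(**d["forster"])
        if "arms" in d:
            kwargs["arms"] = tuple(HelixArm(**a) for a in d["arms"])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Summary tables and provenance of a pipeline run."""

    seed: int
    version: str
    tables: dict[str, pd.DataFrame]
    manifests: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            self.manifests[name] = str(path)
        meta = {"seed": self.seed, "version": self.version,
                "outputs": self.manifests}
        (out / "run_report.json").write_text(json.dumps(meta, indent=1))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    The smFRET branch runs when ``trace_config`` is set (simulate ->
    QC -> mixture fit -> assignment -> distances); the EMSA branch runs
    when ``titration_config`` is set (simulate -> Hill fit). Stage
    failures propagate with the failing stage named.
    """
    tables: dict[str, pd.DataFrame] = {}
    if config.trace_config is None and config.titration_config is None:
        raise ValueError("config enables no stage: set trace_config and/or titration_config")

    if config.trace_config is not None:
        try:
            traces, gt = simulate_ensemble(config.trace_config)
            summary, model, fret_traces = analyze_ensemble(
                traces, k=config.n_components, policy=config.qc_policy,
                seed=config.seed,
            )
        except Exception as exc:
            raise RuntimeError(f"smFRET trace stage failed: {exc}") from exc
        tables["populations"] = pd.DataFrame(
            {
                "component": np.arange(len(summary.fractions)),
                "mean_fret": model.means,
                "fraction": summary.fractions,
                "fraction_se": summary.errors,
                "true_proportion": gt.realized_proportions(),
            }
        )
        mean_se = summary.errors / np.sqrt(max(summary.n_molecules, 1))
        tables["distances"] = estimate_distances(model, config.forster, mean_se)
        qc_rows = [
            {
                "molecule_id": ft.molecule_id,
                "qc_pass": ft.qc_pass,
                "qc_reason": ft.qc_reason,
                "is_static": ft.is_static,
                "bleach_frame": ft.bleach_frame,
                "mean_fret": ft.mean_fret,
            }
            for ft in fret_traces
        ]
        tables["qc"] = pd.DataFrame(qc_rows)

    if config.titration_config is not None:
        try:
            series, tgt = simulate_titration(config.titration_config)
            fits = [fit_hill(s, fix_n=config.fix_hill_n) for s in series]
        except Exception as exc:
            raise RuntimeError(f"EMSA titration stage failed: {exc}") from exc
        tables["affinities"] = pd.DataFrame(
            {
                "replicate_id": [s.replicate_id for s in series],
                "kd_app_M": [f.params.k_d_app for f in fits],
                "kd_se_M": [f.stderr["kd"] for f in fits],
                "hill_n": [f.params.n for f in fits],
                "true_kd_M": tgt.params.k_d_app,
                "true_n": tgt.params.n,
            }
        )

    report = RunReport(seed=config.seed, version=__version__, tables=tables)
    if config.out_dir:
        report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# One-command reproduction fixtures

REPRO_CASES = ("figure2", "figure3", "figure4", "table1")


def repro(case: str, seed: int = 0, out_dir: Optional[str] = None) -> RunReport:
    """Run a published-figure fixture and tabulate recovered vs printed.

    ``figure2``: stem I/II construct; reports the fitted FRET peak, the
    Förster distance and the coaxial-stacking ranking. ``figure3`` /
    ``figure4``: conformer-population recovery for the two junction
    constructs across protein conditions. ``table1``: noiseless
    round-trip of all published affinity rows.
    """
    if case not in REPRO_CASES:
        raise ValueError(f"unknown case {case!r}; choose from {REPRO_CASES}")
    tables: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed)

    if case == "figure2":
        result = run_condition(STEM1_STEM2_PRESET, seed)
        mean_fret = result.model.means[0]
        distance = fret_to_distance(mean_fret)
        ranked = rank_stacking_models(
            JUNCTION_ARMS, [(("stem I", "stem II"), distance)]
        )
        tables["summary"] = pd.DataFrame(
            [
                {
                    "measured_fret": mean_fret,
                    "published_fret": 0.2,
                    "distance_A": distance,
                    "published_distance_A": 76.0,
                    "best_stacked_pair": " / ".join(ranked[0].stacked_pair),
                    "best_family": ranked[0].family,
                    "best_residual_A": ranked[0].residual,
                }
            ]
        )
        tables["hypotheses"] = pd.DataFrame(
            [
                {
                    "stacked_pair": " / ".join(h.stacked_pair),
                    "family": h.family,
                    "predicted_A": h.predicted_label_distance,
                    "residual_A": h.residual,
                }
                for h in ranked
            ]
        )
    elif case in ("figure3", "figure4"):
        conditions = STEM2_LOOP_CONDITIONS if case == "figure3" else STEM1_LOOP_CONDITIONS
        rows = []
        for cond_name, preset in conditions.items():
            sub_seed = int(rng.integers(0, 2**31 - 1))
            result = run_condition(preset, sub_seed)
            pct = result.fractions_pct()
            for i in range(len(preset.states)):
                ref = preset.reference_pct.get(i)
                rows.append(
                    {
                        "condition": cond_name,
                        "component": i,
                        "state_fret": preset.states[i][0],
                        "recovered_pct": pct[i],
                        "true_pct": 100 * result.true_proportions[i],
                        "published_pct": ref[0] if ref else np.nan,
                        "published_err": ref[1] if ref else np.nan,
                    }
                )
        tables["fractions"] = pd.DataFrame(rows)
    elif case == "table1":
        rows = []
        for row in REFERENCE_AFFINITIES:
            params = HillParameters(
                k_d_app=row["kd_nM"] * 1e-9, n=row["hill"], a=1.0, b=0.0
            )
            cfg = TitrationSimConfig(
                hill_params=params, noise_sigma=0.0, n_replicates=1,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            series, _ = simulate_titration(cfg)
            fix_n = 1.0 if row["hill_sd"] is None else None
            fit = fit_hill(series[0], fix_n=fix_n)
            rows.append(
                {
                    "complex": row["complex"],
                    "titrant": row["titrant"],
                    "published_kd_nM": row["kd_nM"],
                    "recovered_kd_nM": fit.params.k_d_app * 1e9,
                    "published_hill": row["hill"],
                    "recovered_hill": fit.params.n,
                    "n_fixed": fix_n is not None,
                }
            )
        tables["affinities"] = pd.DataFrame(rows)

    report = RunReport(seed=seed, version=__version__, tables=tables)
    if out_dir:
        report.write(out_dir)
    return report
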