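import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trifret.synthetic import TraceSimConfig, simulate_ensemble
from trifret.traces import (
    IntensityTrace,
    classify_static,
    compute_fret,
    detect_steps,
    qc_select,
)

from _oracles import exhaustive_segmentation
from conftest import make_constant_trace, make_fret_trace


class TestComputeFret:
    @pytest.mark.parametrize("fret", [0.5, 0.2, 0.8])
    def test_constant_trace_values(self, fret):
        ft = compute_fret(make_constant_trace(fret))
        assert np.allclose(ft.fret, fret)
        assert ft.valid.all()

    def test_noiseless_simulated_state_round_trip(self):
        config = TraceSimConfig(
            n_molecules=5,
            states=((0.3, 1.0),),
            noise_sigma=0.0,
            donor_bleach_lifetime=1e9,
            acceptor_bleach_lifetime=1e9,
            seed=3,
        )
        traces, _ = simulate_ensemble(config)
        for tr in traces:
            ft = compute_fret(tr)
            assert np.allclose(ft.fret[ft.valid], 0.3)

    def test_invalid_frames_flagged_not_dropped(self):
        tr = make_constant_trace(0.5, n_frames=20)
        tr.donor[10:] = 0.0
        tr.acceptor[10:] = 0.0
        ft = compute_fret(tr, min_total=1.0)
        assert len(ft.fret) == 20
        assert not ft.valid[10:].any()
        assert np.isnan(ft.fret[10:]).all()

    def test_all_invalid_is_qc_record_not_exception(self):
        tr = IntensityTrace(
            "m", time=np.arange(10.0), donor=np.zeros(10), acceptor=np.zeros(10)
        )
        ft = compute_fret(tr, min_total=1.0)
        assert not ft.qc_pass
        assert ft.qc_reason == "all_frames_invalid"

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=1e6),
                st.floats(min_value=0.0, max_value=1e6),
            ),
            min_size=10,
            max_size=40,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_fret_bounded_for_nonnegative_channels(self, pairs):
        donor = np.array([p[0] for p in pairs])
        acceptor = np.array([p[1] for p in pairs])
        tr = IntensityTrace("m", np.arange(len(pairs), dtype=float), donor, acceptor)
        ft = compute_fret(tr, min_total=0.0)
        defined = ft.fret[ft.valid]
        assert np.all((defined >= 0.0) & (defined <= 1.0))


class TestDetectSteps:
    def test_constant_signal_no_change_points(self):
        fit = detect_steps(np.full(100, 100.0))
        assert fit.n_steps == 0
        assert fit.segment_means[0] == pytest.approx(100.0)

    def test_clean_step_found_exactly(self):
        y = np.concatenate([np.full(500, 100.0), np.zeros(500)])
        fit = detect_steps(y)
        assert list(fit.change_points) == [500]
        assert fit.segment_means == pytest.approx([100.0, 0.0])

    def test_noisy_staircase_two_steps(self):
        rng = np.random.default_rng(11)
        y = np.concatenate(
            [
                rng.normal(100, 5, 300),
                rng.normal(60, 5, 300),
                rng.normal(0, 5, 400),
            ]
        )
        fit = detect_steps(y)
        assert fit.n_steps == 2
        assert abs(fit.change_points[0] - 300) <= 2
        assert abs(fit.change_points[1] - 600) <= 2
        # the exhaustive two-step oracle lands on the same frames
        _, oracle_cps = exhaustive_segmentation(y[:200], fit.penalty, max_steps=2)
        fit_short = detect_steps(y[:200], penalty=fit.penalty)
        assert tuple(fit_short.change_points) == oracle_cps

    @pytest.mark.parametrize("case", range(12))
    def test_matches_exhaustive_oracle_on_small_instances(self, case):
        """Optimal-partitioning result equals brute-force enumeration."""
        rng = np.random.default_rng(100 + case)
        n = int(rng.integers(30, 120))
        k_true = int(rng.integers(0, 3))
        cps_true = np.sort(rng.choice(np.arange(5, n - 5), size=k_true, replace=False))
        levels = rng.uniform(0, 100, k_true + 1)
        y = np.empty(n)
        edges = np.concatenate([[0], cps_true, [n]]).astype(int)
        for lvl, (a, b) in zip(levels, zip(edges[:-1], edges[1:])):
            y[a:b] = lvl
        y += rng.normal(0, 3.0, n)
        fit = detect_steps(y)
        assert fit.n_steps <= 2
        oracle_cost, oracle_cps = exhaustive_segmentation(y, fit.penalty, max_steps=2)
        assert tuple(fit.change_points) == oracle_cps


class TestQCSelection:
    def _clean_trace(self, i, bleach_frame=500, fret=0.3, n=1000, sigma=3.0):
        rng = np.random.default_rng(1000 + i)
        donor = np.where(np.arange(n) < bleach_frame, (1 - fret) * 100, 0.0)
        acceptor = np.where(np.arange(n) < bleach_frame, fret * 100, 0.0)
        return IntensityTrace(
            f"c{i}",
            time=0.1 * np.arange(n),
            donor=donor + rng.normal(0, sigma, n),
            acceptor=acceptor + rng.normal(0, sigma, n),
        )

    def test_clean_single_bleach_ensemble_all_pass(self):
        traces = [self._clean_trace(i) for i in range(100)]
        fts = qc_select(traces)
        assert sum(ft.qc_pass for ft in fts) == 100
        assert all(ft.bleach_frame == 500 for ft in fts)

    def test_no_bleach_fails(self):
        tr = make_constant_trace(0.4, n_frames=200)
        ft = qc_select([tr])[0]
        assert not ft.qc_pass
        assert ft.qc_reason == "no_bleach_in_window"

    def test_acceptor_first_trace_truncated_at_acceptor_step(self):
        n = 1000
        rng = np.random.default_rng(5)
        t = np.arange(n)
        donor = np.select([t < 400, t < 800], [70.0, 100.0], 0.0)
        acceptor = np.where(t < 400, 30.0, 0.0)
        tr = IntensityTrace(
            "a", 0.1 * np.arange(n),
            donor + rng.normal(0, 3, n), acceptor + rng.normal(0, 3, n),
        )
        ft = qc_select([tr])[0]
        assert ft.qc_pass
        assert ft.bleach_frame == 400
        assert ft.mean_fret == pytest.approx(0.3, abs=0.01)

    def test_aggregates_rejected(self):
        """Two-molecule aggregates (double intensity, two donor steps)."""
        config = TraceSimConfig(n_molecules=100, states=((0.3, 1.0),), seed=21)
        traces, _ = simulate_ensemble(config)
        aggregates = []
        for i in range(0, 100, 2):
            a, b = traces[i], traces[i + 1]
            aggregates.append(
                IntensityTrace(
                    f"agg{i}", a.time, a.donor + b.donor, a.acceptor + b.acceptor
                )
            )
        fts = qc_select(aggregates)
        rejected = sum(not ft.qc_pass for ft in fts)
        assert rejected >= 0.9 * len(aggregates)

    def test_truncation_ignores_post_bleach_frames(self):
        base = self._clean_trace(0, bleach_frame=500, sigma=3.0)
        modified = IntensityTrace(
            "c0b", base.time, base.donor.copy(), base.acceptor.copy()
        )
        # perturb the post-bleach region (still at background); the
        # pre-bleach mean must not move
        modified.donor[500:] += 5.0
        ft_a = qc_select([base])[0]
        ft_b = qc_select([modified])[0]
        assert ft_a.qc_pass
        assert ft_a.mean_fret == ft_b.mean_fret

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qc_select([])


class TestClassifyStatic:
    def test_constant_state_is_static(self):
        rng = np.random.default_rng(2)
        ft = make_fret_trace(rng.normal(0.3, 0.05, 400))
        assert classify_static(ft) is True

    def test_alternating_states_are_dynamic(self):
        rng = np.random.default_rng(3)
        means = np.tile(np.repeat([0.2, 0.6], 100), 3)
        ft = make_fret_trace(rng.normal(means, 0.05))
        assert classify_static(ft) is False

    def test_short_prebleach_indeterminate(self):
        ft = make_fret_trace(np.full(15, 0.3))
        assert classify_static(ft, min_dwell=10) is None
        assert ft.is_static is None

    def test_requires_qc_pass(self):
        ft = make_fret_trace(np.full(50, 0.3), qc_pass=False)
        with pytest.raises(ValueError):
            classify_static(ft)

    def test_naked_duplex_fixture_mostly_static(self):
        """In a static-state ensemble >=95% of QC survivors classify static."""
        config = TraceSimConfig(n_molecules=80, states=((0.2, 1.0),), seed=9)
        traces, _ = simulate_ensemble(config)
        fts = qc_select(traces)
        passed = [ft for ft in fts if ft.qc_pass]
        labels = [classify_static(ft) for ft in passed]
        determinate = [s for s in labels if s is not None]
        assert sum(determinate) >= 0.95 * len(determinate)


class TestIntensityTraceValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            IntensityTrace("m", np.arange(10.0), np.zeros(10), np.zeros(9))

    def test_too_short(self):
        with pytest.raises(ValueError, match="10 frames"):
            IntensityTrace("m", np.arange(5.0), np.zeros(5), np.zeros(5))

    def test_nonmonotonic_time(self):
        t = np.arange(10.0)
        t[5] = 0.0
        with pytest.raises(ValueError, match="increasing"):
            IntensityTrace("m", t, np.zeros(10), np.zeros(10))
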