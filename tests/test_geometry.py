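import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trifret.geometry import (
    DEFAULT_FAMILY_MAP,
    ForsterParams,
    HelixArm,
    distance_to_fret,
    estimate_distances,
    fret_to_distance,
    helix_contour_length,
    rank_stacking_models,
)
from trifret.populations import GaussianComponent, MixtureModel

from _oracles import planar_junction_distances, rank_by_grid_search

R0_60 = ForsterParams(60.0)


class TestForsterRelation:
    @pytest.mark.parametrize(
        "efficiency, expected",
        [(0.5, 60.0), (0.2, 75.595263)],
    )
    def test_fret_to_distance(self, efficiency, expected):
        assert fret_to_distance(efficiency, R0_60) == pytest.approx(expected, abs=1e-4)

    def test_distance_0p2_reported_as_76(self):
        # The 0.2-FRET peak corresponds to ~76 A at R0 = 60 A.
        assert round(fret_to_distance(0.2, R0_60)) == 76

    @pytest.mark.parametrize(
        "distance, expected", [(60.0, 0.5), (76.0, 0.2), (1e6, 0.0)]
    )
    def test_distance_to_fret(self, distance, expected):
        assert distance_to_fret(distance, R0_60) == pytest.approx(expected, abs=0.05)

    def test_distance_76_rounds_to_0p2(self):
        assert round(distance_to_fret(76.0, R0_60), 1) == 0.2

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_efficiency_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fret_to_distance(bad, R0_60)

    def test_distance_domain_error(self):
        with pytest.raises(ValueError):
            distance_to_fret(0.0, R0_60)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, derandomize=True)
    def test_mutual_inverses(self, e):
        assert distance_to_fret(fret_to_distance(e, R0_60), R0_60) == pytest.approx(
            e, rel=1e-9
        )

    def test_monotone_decreasing(self):
        es = np.linspace(0.01, 0.99, 200)
        rs = np.array([fret_to_distance(e, R0_60) for e in es])
        assert np.all(np.diff(rs) < 0)
        ds = np.linspace(10, 200, 200)
        fs = np.array([distance_to_fret(d, R0_60) for d in ds])
        assert np.all(np.diff(fs) < 0)


class TestHelixGeometry:
    @pytest.mark.parametrize(
        "bp, expected", [(10, 28.0), (17, 47.6), (0, 0.0)]
    )
    def test_contour_length_default_rise(self, bp, expected):
        assert helix_contour_length(HelixArm("arm", bp)) == pytest.approx(expected)

    def test_seventeen_bp_near_48(self):
        assert helix_contour_length(HelixArm("stem II", 17)) == pytest.approx(48, abs=1)

    def test_invalid_rise(self):
        with pytest.raises(ValueError):
            HelixArm("arm", 10, rise_per_bp=4.0)


ARMS = (
    HelixArm("stem I", 10),
    HelixArm("stem II", 17),
    HelixArm("5' stem-loop", 9),
)


class TestStackingModels:
    def test_collinear_hypothesis_ranks_first_at_76(self):
        ranked = rank_stacking_models(ARMS, [(("stem I", "stem II"), 76.0)])
        best = ranked[0]
        assert set(best.stacked_pair) == {"stem I", "stem II"}
        assert best.predicted_label_distance == pytest.approx(75.6, abs=0.01)
        assert best.residual < 0.5
        assert best.family == "A"

    def test_short_measurement_prefers_bent_alternative(self):
        # A measured distance of half the summed contour lengths is
        # inconsistent with collinear stacking of that pair.
        d = 0.5 * (28.0 + 47.6)
        ranked = rank_stacking_models(ARMS, [(("stem I", "stem II"), d)])
        assert set(ranked[0].stacked_pair) != {"stem I", "stem II"}
        collinear = next(
            h for h in ranked if set(h.stacked_pair) == {"stem I", "stem II"}
        )
        assert collinear.residual > ranked[0].residual

    @pytest.mark.parametrize("true_pair", [("stem I", "stem II"),
                                           ("stem I", "5' stem-loop"),
                                           ("stem II", "5' stem-loop")])
    @pytest.mark.parametrize("angle", [40.0, 90.0, 135.0])
    def test_recovers_generating_geometry(self, true_pair, angle):
        lengths = {a.name: helix_contour_length(a) for a in ARMS}
        dists = planar_junction_distances(lengths, true_pair, angle)
        measurements = [
            ((tuple(sorted(k))[0], tuple(sorted(k))[1]), v) for k, v in dists.items()
        ]
        ranked = rank_stacking_models(ARMS, measurements)
        assert set(ranked[0].stacked_pair) == set(true_pair)
        assert ranked[0].residual == pytest.approx(0.0, abs=0.1)
        oracle = rank_by_grid_search(lengths, measurements)
        assert [set(p) for _, p in oracle] == [set(h.stacked_pair) for h in ranked]

    def test_ordering_invariant_to_input_order(self):
        lengths = {a.name: helix_contour_length(a) for a in ARMS}
        dists = planar_junction_distances(lengths, ("stem I", "stem II"), 70.0)
        meas = [(tuple(sorted(k)), v) for k, v in dists.items()]
        ranked_fwd = rank_stacking_models(ARMS, meas)
        ranked_rev = rank_stacking_models(tuple(reversed(ARMS)), list(reversed(meas)))
        assert [h.stacked_pair for h in ranked_fwd] == [
            h.stacked_pair for h in ranked_rev
        ]
        assert [h.residual for h in ranked_fwd] == pytest.approx(
            [h.residual for h in ranked_rev], abs=1e-9
        )

    def test_unknown_arm_errors(self):
        with pytest.raises(ValueError, match="unknown arm"):
            rank_stacking_models(ARMS, [(("stem I", "stem IX"), 50.0)])


class TestDistanceEstimates:
    def _model(self, mean, sigma=0.05):
        return MixtureModel(components=(GaussianComponent(mean, sigma, 1.0),))

    def test_zero_error_midpoint(self):
        df = estimate_distances(self._model(0.5), R0_60, mean_errors=[0.0])
        assert df.distance_A[0] == pytest.approx(60.0)
        assert df.se_distance_A[0] == 0.0

    def test_propagation_at_0p2(self):
        df = estimate_distances(self._model(0.2), R0_60, mean_errors=[0.01])
        assert df.distance_A[0] == pytest.approx(75.6, abs=0.01)
        assert np.isfinite(df.se_distance_A[0]) and df.se_distance_A[0] > 0
        # finite-difference check of the derivative used in propagation
        h = 1e-6
        drde = (fret_to_distance(0.2 + h, R0_60) - fret_to_distance(0.2 - h, R0_60)) / (
            2 * h
        )
        assert df.se_distance_A[0] == pytest.approx(abs(drde) * 0.01, rel=1e-4)

    def test_propagation_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        mean, se = 0.3, 0.012
        draws = rng.normal(mean, se, 10_000)
        draws = draws[(draws > 0) & (draws < 1)]
        mc_sd = np.std([fret_to_distance(e, R0_60) for e in draws])
        df = estimate_distances(self._model(mean), R0_60, mean_errors=[se])
        assert df.se_distance_A[0] == pytest.approx(mc_sd, rel=0.05)

    def test_out_of_range_mean_flagged(self):
        model = MixtureModel(
            components=(
                GaussianComponent(-0.1, 0.05, 0.5),
                GaussianComponent(0.3, 0.05, 0.5),
            )
        )
        df = estimate_distances(model, R0_60, mean_errors=[0.01, 0.01])
        assert bool(df.flagged[0]) and np.isnan(df.distance_A[0])
        assert not bool(df.flagged[1])

    def test_default_family_map_covers_all_pairs(self):
        names = [a.name for a in ARMS]
        for i in range(3):
            for j in range(i + 1, 3):
                assert frozenset({names[i], names[j]}) in DEFAULT_FAMILY_MAP
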