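"""Standard-curve fitting, band sizing and group assignment."""

import math

import numpy as np
import pytest

from smybpc import (
    BandObservation,
    LadderLane,
    assign_bands,
    default_ladder,
    estimate_mass,
    fit_standard_curve,
    rf_for_mass,
)
from smybpc.gel import (
    ExtrapolationWarning,
    InsufficientCalibrationError,
    LadderDataError,
    groups_per_lane,
)


@pytest.fixture(scope="module")
def curve():
    return fit_standard_curve(default_ladder())


class TestFitStandardCurve:
    def test_noiseless_ladder_fits_perfectly(self, curve):
        ladder = default_ladder()
        assert curve.fit_r2 == pytest.approx(1.0, abs=1e-12)
        for mass, rf in ladder.markers:
            assert estimate_mass(curve, rf) == pytest.approx(mass, rel=1e-9)

    def test_perturbed_marker_matches_independent_ols(self):
        ladder = default_ladder()
        markers = list(ladder.markers)[:5]
        masses = np.array([m for m, _ in markers])
        rfs = np.array([r for _, r in markers])
        rfs[2] += 0.01
        fit = fit_standard_curve(LadderLane(tuple(zip(masses, rfs))))
        # independent OLS oracle
        slope, intercept = np.polyfit(rfs, np.log10(masses), 1)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.fit_r2 < 1.0
        assert np.argmax(np.abs(fit.residuals)) == 2

    def test_two_marker_ladder_rejected(self):
        with pytest.raises(InsufficientCalibrationError):
            fit_standard_curve(LadderLane(((250.0, 0.0), (50.0, 1.0))))

    def test_non_monotone_ladder_rejected(self):
        with pytest.raises(LadderDataError):
            fit_standard_curve(
                LadderLane(((250.0, 0.0), (150.0, 0.5), (100.0, 0.4)))
            )


class TestEstimateMass:
    def test_midpoint_rf_gives_geometric_mean(self):
        # two markers plus a third on the same exact line
        lo, hi = 125.0, 135.0
        ladder = LadderLane(
            (
                (hi, 0.2),
                (lo, 0.6),
                (math.sqrt(lo * hi), 0.4),
            )
        )
        curve = fit_standard_curve(ladder)
        assert estimate_mass(curve, 0.4) == pytest.approx(math.sqrt(lo * hi))

    def test_rf_zero_returns_intercept_mass(self, curve):
        assert estimate_mass(curve, 0.0) == pytest.approx(10**curve.intercept)
        assert 10**curve.intercept == pytest.approx(250.0)

    def test_strictly_decreasing_in_rf(self, curve):
        rfs = np.linspace(0, 1, 101)
        masses = [estimate_mass(curve, rf) for rf in rfs]
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_extrapolation_warns(self, curve):
        with pytest.warns(ExtrapolationWarning):
            estimate_mass(curve, curve.rf_max + 0.1)

    def test_inverse_round_trip(self, curve):
        for mass in (131.5, 126.0, 115.5):
            assert estimate_mass(curve, rf_for_mass(curve, mass)) == pytest.approx(mass)


class TestAssignBands:
    def test_single_band_at_131_is_group_1(self, curve, groups):
        band = BandObservation("fiber1", rf_for_mass(curve, 131.0))
        (result,) = assign_bands([band], curve, groups)
        assert result.group_index == 1
        assert result.candidate_variants == ("h-v1", "h-v5", "h-v202")

    def test_dominant_soleus_lane_maps_to_groups_1_and_6(self, curve, groups):
        bands = [
            BandObservation("lane", rf_for_mass(curve, 131.0)),
            BandObservation("lane", rf_for_mass(curve, 115.5)),
        ]
        results = assign_bands(bands, curve, groups)
        assert groups_per_lane(results) == {"lane": frozenset({1, 6})}

    def test_empty_input_gives_empty_result(self, curve, groups):
        assert assign_bands([], curve, groups) == []

    def test_results_sorted_by_mass_descending_within_lane(self, curve, groups):
        bands = [
            BandObservation("lane", rf_for_mass(curve, m))
            for m in (115.5, 131.3, 128.0)
        ]
        results = assign_bands(bands, curve, groups)
        masses = [r.band.estimated_mass for r in results]
        assert masses == sorted(masses, reverse=True)

    def test_nearby_bands_merged_to_one(self, curve, groups):
        bands = [
            BandObservation("lane", rf_for_mass(curve, 128.00)),
            BandObservation("lane", rf_for_mass(curve, 128.10)),
        ]
        results = assign_bands(bands, curve, groups)
        assert len(results) == 1
        assert results[0].group_index == 3

    def test_duplicate_group_hits_collapsed(self, curve, groups):
        bands = [
            BandObservation("lane", rf_for_mass(curve, 131.5)),
            BandObservation("lane", rf_for_mass(curve, 130.9)),
        ]
        results = assign_bands(bands, curve, groups)
        assert [r.group_index for r in results] == [1]


class TestStochasticRecovery:
    def test_noiseless_sizing_and_assignment_exact(self, curve, groups):
        centers = {g.index: g.center for g in groups}
        bands = [
            BandObservation(f"lane{i}", rf_for_mass(curve, c))
            for i, c in centers.items()
        ]
        results = assign_bands(bands, curve, groups)
        for r in results:
            true_index = int(r.band.lane_id.removeprefix("lane"))
            assert abs(r.band.estimated_mass - centers[true_index]) < 0.01
            assert r.group_index == true_index

    def test_at_default_noise_95pct_of_bands_recover_their_group(self, groups):
        """Gaussian Rf noise (sd 0.002) on bands drawn from the group centers:
        at least 95% of 1,000 bands recover the generating group, counting an
        ambiguous call whose runner-up is the generating group."""
        curve = fit_standard_curve(default_ladder())
        rng = np.random.default_rng(2013)
        centers = {g.index: g.center for g in groups}
        # weight groups as the soleus band population does
        weights = {1: 25, 2: 12, 3: 7, 4: 4, 5: 5, 6: 36}
        indices = rng.choice(
            list(weights), size=1000, p=np.array(list(weights.values())) / 89
        )
        correct = 0
        for i, g in enumerate(indices):
            rf = rf_for_mass(curve, centers[g]) + rng.normal(0, 0.002)
            (result,) = assign_bands(
                [BandObservation(f"b{i}", rf)], curve, groups
            )
            if result.group_index == g or (
                result.ambiguous and result.runner_up_index == g
            ):
                correct += 1
        assert correct / 1000 >= 0.95
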