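"""Comparison metrics: land overlap, sample-size curves, AUC protocol, shape ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import phre
from phre.evaluation import (
    _disk_union_sampler,
    auc_evaluation,
    available_habitat,
    land_overlap,
    rank_auc,
    sample_size_analysis,
    shape_analysis,
)
from phre.home_range import HomeRange


class TestLandOverlap:
    def test_half_square_on_half_plane(self, half_plane_land):
        hr = HomeRange(box(-500, -500, 500, 500), 0.9, 1.0, 0.9)
        assert land_overlap(hr, half_plane_land) == pytest.approx(50.0)

    def test_fully_on_land(self, half_plane_land):
        hr = HomeRange(box(0, 100, 1000, 1100), 0.9, 1.0, 0.9)
        assert land_overlap(hr, half_plane_land) == pytest.approx(100.0)

    def test_fully_in_water(self, half_plane_land):
        hr = HomeRange(box(0, -2000, 1000, -1000), 0.9, 1.0, 0.9)
        assert land_overlap(hr, half_plane_land) == 0.0

    def test_zero_area_errors(self, half_plane_land):
        hr = HomeRange(box(0, 0, 0, 0), 0.9, 0.0, 0.9)
        with pytest.raises(ValueError):
            land_overlap(hr, half_plane_land)


class TestRankAuc:
    def test_perfect_separation(self):
        assert rank_auc([2.0, 3.0], [0.0, 1.0, 1.5]) == 1.0

    def test_all_ties_give_chance(self):
        assert rank_auc(np.ones(100), np.ones(1000)) == 0.5

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        pos, neg = rng.normal(0.5, 1, 100), rng.normal(0, 1, 1000)
        y = np.r_[np.ones(100), np.zeros(1000)]
        s = np.r_[pos, neg]
        assert rank_auc(pos, neg) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        pos, neg = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        a = rank_auc(pos, neg)
        f = lambda x: np.arctan(5 * x) + 7  # noqa: E731
        assert rank_auc(f(pos), f(neg)) == pytest.approx(a, abs=1e-12)


class _ConstantAreaEstimator:
    """Returns the same home range regardless of the sample."""

    def __init__(self, area=2.0):
        self._hr = HomeRange(box(0, -2000, 2000, 0), 0.9, area, 0.9)

    def fit(self, pts):
        return self

    def home_range(self, level=0.9):
        return self._hr


class _ConvergingEstimator:
    """Area converges (deterministically) once N exceeds a built-in N*."""

    def __init__(self, n_star=100, rng=None):
        self.n_star = n_star
        self.rng = rng or np.random.default_rng(0)

    def fit(self, pts):
        self._n = len(pts)
        return self

    def home_range(self, level=0.9):
        n = self._n
        bias = max(0.0, (self.n_star - n) / self.n_star) * 5.0
        noise = self.rng.normal(0, 0.05)
        return HomeRange(box(0, 0, 1, 1), level, 10.0 - bias + noise, level)


class TestSampleSizeAnalysis:
    def test_constant_area_needs_minimum_n(self, rng):
        pts = rng.uniform(size=(300, 2))
        curve = sample_size_analysis(pts, _ConstantAreaEstimator(), seed=1)
        assert curve.min_N_area == 10
        assert curve.min_N_cv == 10

    def test_converging_generator_detected_near_n_star(self, rng):
        pts = rng.uniform(size=(300, 2))
        curve = sample_size_analysis(
            pts, _ConvergingEstimator(n_star=100, rng=np.random.default_rng(5)), seed=2
        )
        assert curve.min_N_area is not None
        assert curve.min_N_area <= 120
        assert curve.min_N_area >= 50  # areas are clearly biased below N* / 2

    def test_reproducible_bit_for_bit(self, rng):
        pts = rng.uniform(size=(300, 2))
        mk = lambda: _ConvergingEstimator(80, np.random.default_rng(9))  # noqa: E731
        c1 = sample_size_analysis(pts, mk(), seed=3)
        c2 = sample_size_analysis(pts, mk(), seed=3)
        pd.testing.assert_frame_equal(c1.areas, c2.areas)
        assert c1.min_N_area == c2.min_N_area and c1.min_N_cv == c2.min_N_cv

    def test_needs_enough_sightings(self, rng):
        with pytest.raises(ValueError):
            sample_size_analysis(rng.uniform(size=(100, 2)), _ConstantAreaEstimator())


class TestAucProtocol:
    def test_pseudo_absences_within_radius(self, rng):
        pts = rng.uniform(0, 5000, size=(40, 2))
        sample = _disk_union_sampler(pts, 1000.0, rng, 500)
        d = np.min(
            np.linalg.norm(sample[:, None, :] - pts[None, :, :], axis=2), axis=1
        )
        assert (d <= 1000.0 + 1e-6).all()

    def test_random_scores_give_chance(self, rng):
        pts = rng.uniform(0, 10_000, size=(300, 2))
        rep = auc_evaluation(
            pts, None, seed=11,
            score_surface=lambda p, r: r.uniform(size=len(p)),
        )
        assert rep.mean == pytest.approx(0.5, abs=0.03)
        assert len(rep.aucs) == 10

    def test_informative_surface_beats_chance(self, straight_scenario,
                                              straight_sightings):
        sightings, _, _ = straight_sightings
        pts = sightings[["x", "y"]].to_numpy()
        est = phre.PHREEstimator(straight_scenario.line, straight_scenario.land,
                                 pad=3000)
        rep = auc_evaluation(pts, est, seed=4, n_iterations=2)
        assert rep.mean > 0.7

    def test_too_few_sightings_rejected(self, rng):
        with pytest.raises(ValueError):
            auc_evaluation(rng.uniform(size=(250, 2)), None, score_surface=lambda p, r: p[:, 0])


class TestShapeAnalysis:
    @staticmethod
    def simulate_sites(slope_a, slope_b, n=30, sigma=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for site, slope in (("A", slope_a), ("B", slope_b)):
            log_area = rng.uniform(0.0, 2.5, n)
            log_len = 0.3 + slope * log_area + rng.normal(0, sigma, n)
            rows += [(site, np.exp(a), np.exp(l)) for a, l in zip(log_area, log_len)]
        return pd.DataFrame(rows, columns=["site", "area_km2", "length_km"])

    def test_collinear_single_slope_recovered_exactly(self):
        df = self.simulate_sites(0.5, 0.5, n=10, sigma=0.0, seed=1)
        rep = shape_analysis(df)
        assert rep.slopes["A"] == pytest.approx(0.5, abs=1e-10)
        assert rep.slopes["B"] == pytest.approx(0.5, abs=1e-10)
        assert rep.slope_difference == pytest.approx(0.0, abs=1e-10)

    def test_known_slope_difference_recovered(self):
        df = self.simulate_sites(0.5, 0.74, seed=2)
        rep = shape_analysis(df)
        assert abs(rep.slope_difference - 0.24) <= 2 * rep.slope_difference_se

    def test_interaction_p_matches_t_distribution_shape(self):
        # under the null, p is far from systematically small for one dataset
        df = self.simulate_sites(0.5, 0.5, seed=3)
        rep = shape_analysis(df)
        assert 0.0 <= rep.interaction_p <= 1.0

    def test_input_validation(self):
        df = self.simulate_sites(0.5, 0.5, n=2)
        with pytest.raises(ValueError, match=">= 3"):
            shape_analysis(df)
        bad = self.simulate_sites(0.5, 0.5)
        bad.loc[0, "area_km2"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            shape_analysis(bad)


class TestAvailableHabitat:
    def test_uniform_shelf_arithmetic(self):
        # -20 m shelf, 1-km-wide, along an 8.6-km stretch: 86 x 10 cells of 0.01 km²
        xs, ys = np.meshgrid(np.arange(86), np.arange(10))
        hab = pd.DataFrame({
            "coastal_position": xs.ravel() * 0.2,  # 100 m = 0.2 index units
            "depth_m": np.full(xs.size, -20.0),
        })
        area = available_habitat(hab, (0.0, 17.2))
        assert area == pytest.approx(8.6 * 1.0)

    def test_too_deep_everywhere_is_zero(self):
        hab = pd.DataFrame({"coastal_position": [1.0, 2.0], "depth_m": [-50.0, -60.0]})
        with pytest.warns(UserWarning):
            assert available_habitat(hab, (0.0, 3.0)) == 0.0

    def test_matches_counting_oracle(self, rng):
        hab = pd.DataFrame({
            "coastal_position": rng.uniform(0, 100, 5000),
            "depth_m": rng.uniform(-80, 5, 5000),
        })
        sel = (hab["coastal_position"].between(20, 60)
               & hab["depth_m"].between(-39, 0))
        assert available_habitat(hab, (20, 60)) == pytest.approx(sel.sum() * 0.01)


def test_phre_overlap_never_exceeds_geographic_kde(straight_scenario,
                                                   straight_sightings):
    """On a coastal fixture the masked estimator cannot overlap land more than
    the unmasked one (PHRE is exactly 0)."""
    sightings, _, _ = straight_sightings
    pts = sightings[["x", "y"]].to_numpy()
    phre_hr = phre.PHREEstimator(
        straight_scenario.line, straight_scenario.land, pad=3000
    ).fit(pts).home_range(0.90)
    kde_hr = phre.GeographicKDE(
        straight_scenario.land, h_b=500.0, pad=3000
    ).fit(pts).home_range(0.90)
    o_phre = land_overlap(phre_hr, straight_scenario.land)
    o_kde = land_overlap(kde_hr, straight_scenario.land)
    assert o_phre == 0.0
    assert o_kde >= o_phre
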