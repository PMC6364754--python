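"""Ordinary kriging of binary responses, checked against a brute-force oracle.

The oracle below builds and solves the full ordinary-kriging system with
explicit loops, independently of the package's vectorized implementation.
"""

import math

import numpy as np
import pytest

import gazeperim as gp
from gazeperim.errors import KrigingError


# -- independent oracle --------------------------------------------------------

def oracle_gamma(h, model, rng_deg, sill, nugget):
    if h <= 0:
        return 0.0
    if model == "exponential":
        structured = sill * (1.0 - math.exp(-h / rng_deg))
    elif model == "gaussian":
        structured = sill * (1.0 - math.exp(-((h / rng_deg) ** 2)))
    elif model == "spherical":
        hr = min(h / rng_deg, 1.0)
        structured = sill * (1.5 * hr - 0.5 * hr ** 3)
    else:
        raise ValueError(model)
    return nugget + structured


def oracle_krige(sites, values, point, model, rng_deg, sill, nugget):
    """Solve the ordinary-kriging system from scratch for one point."""
    n = len(sites)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            h = math.dist(sites[i], sites[j])
            A[i, j] = oracle_gamma(h, model, rng_deg, sill, nugget)
        A[i, n] = A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = oracle_gamma(math.dist(sites[i], point), model, rng_deg, sill, nugget)
    b[n] = 1.0
    w = np.linalg.solve(A, b)[:n]
    return float(np.dot(w, values))


def random_config(rng, n_sites):
    """Distinct lattice-ish sites with mixed binary responses."""
    while True:
        sites = rng.integers(-10, 11, size=(n_sites, 2)).astype(float)
        sites += rng.uniform(-0.2, 0.2, size=sites.shape)
        if len(np.unique(np.round(sites, 1), axis=0)) == n_sites:
            break
    values = rng.integers(0, 2, size=n_sites).astype(float)
    if values.min() == values.max():
        values[0] = 1.0 - values[0]
    return sites, values


class TestAgainstOracle:
    @pytest.mark.parametrize("model", ["exponential", "spherical", "gaussian"])
    @pytest.mark.parametrize("n_sites", [4, 8, 12])
    def test_predictions_match_direct_solve(self, model, n_sites, rng):
        sites, values = random_config(rng, n_sites)
        est = gp.OrdinaryKrigingPoS(model=model, range_deg=6.0, sill=0.25,
                                    nugget=0.05, merge_radius_deg=0.0)
        est.fit(sites, values)
        points = rng.uniform(-9, 9, size=(12, 2))
        got = est.predict(points)
        for p, g in zip(points, got):
            expect = oracle_krige(sites, values, p, model, 6.0, 0.25, 0.05)
            assert g == pytest.approx(min(max(expect, 0.0), 1.0), abs=1e-8)

    def test_zero_nugget_interpolates_exactly_at_sites(self, rng):
        sites, values = random_config(rng, 8)
        est = gp.OrdinaryKrigingPoS(nugget=0.0, sill=0.25, merge_radius_deg=0.0)
        est.fit(sites, values)
        assert est.predict(sites) == pytest.approx(values, abs=1e-8)

    def test_positive_nugget_smooths_at_sites(self, rng):
        sites, values = random_config(rng, 8)
        est = gp.OrdinaryKrigingPoS(nugget=0.2, sill=0.25, merge_radius_deg=0.0)
        est.fit(sites, values)
        assert not np.allclose(est.predict(sites), values, atol=1e-3)


class TestDegenerateAndBoundaryBehavior:
    def test_constant_responses_give_constant_surface(self):
        sites = np.array([[0, 0], [6, 0], [0, 6], [6, 6], [3, 9], [9, 3]], float)
        est = gp.OrdinaryKrigingPoS().fit(sites, np.ones(6))
        surface = est.surface(resolution_deg=1.0)
        assert np.nanmin(surface.values) == np.nanmax(surface.values) == 1.0

    def test_predictions_clamped_to_unit_interval(self, rng):
        for trial in range(5):
            sites, values = random_config(rng, 10)
            est = gp.OrdinaryKrigingPoS(nugget=0.0, sill=0.5).fit(sites, values)
            pred = est.predict(rng.uniform(-12, 12, size=(50, 2)))
            assert np.all(pred >= 0.0) and np.all(pred <= 1.0)

    def test_hemifield_split_predicts_above_half_in_seeing_half(self):
        # Upper-hemifield hits, lower misses, on a 6-site toy layout.
        sites = np.array([[-6, 6], [0, 6], [6, 6], [-6, -6], [0, -6], [6, -6]],
                         dtype=float)
        values = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        est = gp.OrdinaryKrigingPoS(range_deg=6.0).fit(sites, values)
        xs = np.linspace(-5, 5, 9)
        upper = est.predict(np.column_stack([xs, np.full(9, 4.0)]))
        lower = est.predict(np.column_stack([xs, np.full(9, -4.0)]))
        assert np.all(upper > 0.5)
        assert np.all(lower < 0.5)

    def test_colocated_sites_merged_to_mean(self):
        sites = np.array([[0, 0], [0.1, 0.1], [6, 0], [0, 6]], float)
        values = np.array([1.0, 0.0, 1.0, 0.0])
        est = gp.OrdinaryKrigingPoS(merge_radius_deg=0.25).fit(sites, values)
        assert len(est.sites_) == 3
        merged = est.values_[np.all(np.isclose(est.sites_, [0.05, 0.05]), axis=1)]
        assert merged == pytest.approx([0.5])

    def test_too_few_sites_rejected(self):
        with pytest.raises(KrigingError):
            gp.OrdinaryKrigingPoS().fit(np.array([[0.0, 0.0]]), np.array([1.0]))

    def test_out_of_range_responses_rejected(self):
        with pytest.raises(KrigingError):
            gp.OrdinaryKrigingPoS().fit(np.array([[0, 0], [1, 1]], float),
                                        np.array([0.5, 1.5]))

    def test_monotone_response_to_flipping_a_miss_to_a_hit(self, rng):
        """Numerical check on seeded small configurations: upgrading one miss
        to a hit never lowers the (clamped) surface anywhere on the lattice."""
        for trial in range(10):
            sites, values = random_config(rng, 6)
            flip = int(np.flatnonzero(values == 0.0)[0])
            grid = np.array([[x, y] for x in range(-10, 11, 2)
                             for y in range(-10, 11, 2)], float)
            base = gp.OrdinaryKrigingPoS().fit(sites, values).predict(grid)
            values2 = values.copy()
            values2[flip] = 1.0
            bumped = gp.OrdinaryKrigingPoS().fit(sites, values2).predict(grid)
            assert np.all(bumped >= base - 1e-9)


class TestSurfaceAndSummary:
    def test_support_mask_matches_convex_hull(self):
        sites = np.array([[-6, -6], [6, -6], [0, 6], [0, 0]], float)
        est = gp.OrdinaryKrigingPoS().fit(sites, np.array([1, 0, 1, 0.0]))
        assert est.in_support([[0.0, -2.0]])[0]
        assert not est.in_support([[6.0, 6.0]])[0]
        surface = est.surface(resolution_deg=1.0)
        assert np.isnan(surface.values[~surface.support_mask]).all()

    def test_mean_hit_rate_of_constant_surfaces(self):
        sites = np.array([[x, y] for x in (-9, 9) for y in (-9, 9)], float)
        for const in (0.0, 1.0):
            est = gp.OrdinaryKrigingPoS().fit(sites, np.full(4, const))
            mhr, n = gp.mean_hit_rate(est.surface(), gp.build_24_2("right"))
            assert mhr == const
            assert n > 0

    def test_mean_hit_rate_is_plain_average_at_included_sites(self):
        # Four 24-2 locations as sites with nugget-free kriging: the values at
        # those exact points are the observations {1, 1, 0, 0} -> mean 0.5.
        pts = [(-3.0, 3.0), (3.0, 3.0), (-3.0, -3.0), (3.0, -3.0)]
        est = gp.OrdinaryKrigingPoS(nugget=0.0).fit(np.array(pts),
                                                    np.array([1.0, 1, 0, 0]))
        mhr, n = gp.mean_hit_rate(est.surface(), pts)
        assert n == 4
        assert mhr == pytest.approx(0.5, abs=1e-8)

    def test_no_reference_location_in_support_raises(self):
        sites = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        est = gp.OrdinaryKrigingPoS().fit(sites, np.array([1, 0, 1, 0.0]))
        with pytest.raises(KrigingError):
            gp.mean_hit_rate(est.surface(), [(30.0, 30.0)])


class TestFitFromTrials:
    def test_surface_from_session_and_order_invariance(self, healthy_session, rng):
        session = healthy_session.session
        corrected = gp.correct_session(session.trials, session.gaze)
        surf = gp.fit_pos_surface(corrected)
        pts = np.array([[0.0, 5.0], [-9.0, 3.0], [9.0, -3.0]])
        base = surf.evaluate(pts)
        shuffled = list(corrected)
        rng.shuffle(shuffled)
        again = gp.fit_pos_surface(shuffled).evaluate(pts)
        assert again == pytest.approx(base, abs=1e-9)
        vals = surf.values[surf.support_mask]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_too_few_corrected_trials_rejected(self, healthy_session):
        session = healthy_session.session
        corrected = gp.correct_session(session.trials, session.gaze)[:5]
        with pytest.raises(KrigingError):
            gp.fit_pos_surface(corrected)
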