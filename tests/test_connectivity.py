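"""Toroidal geometry and Gaussian fixed-in-degree wiring."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from msping import connectivity as conn


class TestTorusDistance:
    def test_wraparound_neighbors(self):
        # columns 0 and 39 on a 40-wide torus are neighbours
        a = np.array([0.0, 5.0])
        b = np.array([39.0, 5.0])
        assert conn.torus_distance(a, b, 40.0) == pytest.approx(1.0)

    def test_maximal_distance_is_half_period_per_axis(self):
        a = np.array([0.0, 0.0])
        b = np.array([20.0, 20.0])
        assert conn.torus_distance(a, b, 40.0) == pytest.approx(20.0 * np.sqrt(2))

    @settings(max_examples=50, deadline=None)
    @given(
        st.tuples(st.floats(0, 40), st.floats(0, 40)),
        st.tuples(st.floats(0, 40), st.floats(0, 40)),
        st.tuples(st.floats(0, 40), st.floats(0, 40)),
    )
    def test_metric_properties(self, p, q, r):
        p, q, r = map(np.array, (p, q, r))
        dpq = conn.torus_distance(p, q, 40.0)
        assert dpq == pytest.approx(conn.torus_distance(q, p, 40.0))
        assert dpq <= 20.0 * np.sqrt(2) + 1e-9
        assert dpq + conn.torus_distance(q, r, 40.0) >= conn.torus_distance(p, r, 40.0) - 1e-9


class TestGridGeometry:
    def test_populations(self, geometry):
        assert geometry.n_exc == 1600
        assert geometry.n_inh == 400

    def test_i_grid_spans_same_extent(self, geometry):
        pos_i = geometry.i_positions()
        assert pos_i.max() == pytest.approx(38.0)  # stride-2 registration
        assert pos_i.min() == 0.0


class TestSampling:
    def test_fixed_in_degree_conservation(self, small_v1_graph, geometry):
        w = small_v1_graph.weights
        n_e = geometry.n_exc
        blocks = {
            "EE": (slice(0, n_e), slice(0, n_e)),
            "EI": (slice(n_e, None), slice(0, n_e)),
            "IE": (slice(0, n_e), slice(n_e, None)),
            "II": (slice(n_e, None), slice(n_e, None)),
        }
        for name, (rows, cols) in blocks.items():
            p = small_v1_graph.projections[name]
            in_w = np.asarray(w[rows, cols].sum(axis=1)).ravel()
            assert np.allclose(in_w, p.n_s * p.g_s), name

    def test_no_self_edges(self, small_v1_graph):
        assert small_v1_graph.weights.diagonal().max() == 0.0

    def test_reproducible_under_seed(self, geometry):
        a = conn.build_v1_network(geometry, rng=np.random.default_rng(11))
        b = conn.build_v1_network(geometry, rng=np.random.default_rng(11))
        assert (a.weights != b.weights).nnz == 0

    def test_excitatory_reach_exceeds_inhibitory(self, small_v1_graph, geometry):
        coo = small_v1_graph.weights.tocoo()
        pos = small_v1_graph.positions
        d = conn.torus_distance(pos[coo.row], pos[coo.col], geometry.extent)
        is_ee = (coo.row < geometry.n_exc) & (coo.col < geometry.n_exc)
        is_ii = (coo.row >= geometry.n_exc) & (coo.col >= geometry.n_exc)
        assert d[is_ee].mean() > d[is_ii].mean()

    def test_distance_histogram_matches_gaussian(self, geometry):
        # empirical connection-count histogram vs the normalised Gaussian
        # footprint, chi-square on ~1e5 draws pooled over receivers
        rng = np.random.default_rng(21)
        pos = geometry.e_positions()
        sigma = 3.0
        pre, post, mult = conn.sample_gaussian_connections(
            pos[:500], pos, n_s=200, sigma_s=sigma, extent=40.0, rng=rng,
            self_pairs=(np.arange(500), np.arange(500)),
        )
        d = conn.torus_distance(pos[post], pos[pre], 40.0)
        edges = np.array([0.5, 1.5, 2.5, 3.5, 5.0, 7.0])
        obs, _ = np.histogram(d, bins=edges, weights=mult)
        # expected mass per bin from the exact footprint of one receiver
        d_all = conn.torus_distance(pos[0], pos, 40.0)
        p_all = np.exp(-(d_all**2) / (2 * sigma**2))
        p_all[0] = 0.0
        exp_mass, _ = np.histogram(d_all, bins=edges, weights=p_all)
        sel = exp_mass > 0
        expected = exp_mass[sel] / p_all.sum() * 500 * 200
        chi2 = ((obs[sel] - expected) ** 2 / expected).sum()
        dof = sel.sum() - 1
        assert chi2 < scipy.stats.chi2.ppf(0.999, dof)

    def test_sigma_to_zero_collapses_to_nearest_neighbors(self, geometry):
        rng = np.random.default_rng(5)
        pos = geometry.e_positions()
        pre, post, _ = conn.sample_gaussian_connections(
            pos[:20], pos, n_s=10, sigma_s=0.12, extent=40.0, rng=rng,
            self_pairs=(np.arange(20), np.arange(20)),
        )
        d = conn.torus_distance(pos[post], pos[pre], 40.0)
        assert d.max() == pytest.approx(1.0)

    def test_empty_candidates_rejected(self, geometry):
        with pytest.raises(ValueError):
            conn.sample_gaussian_connections(
                geometry.e_positions()[:2], np.empty((0, 2)), 5, 1.0, 40.0,
                np.random.default_rng(0),
            )


class TestAnisotropy:
    def test_center_footprint_orientation(self, small_v1_graph, geometry):
        rng = np.random.default_rng(3)
        g = conn.apply_anisotropy(small_v1_graph, "horizontal", rng=rng)
        center = geometry.center_e_index()
        out = g.weights[:, center].tocoo()
        targets = out.row[out.row < geometry.n_exc]
        delta = conn.torus_delta(
            small_v1_graph.positions[center], small_v1_graph.positions[targets], 40.0
        )
        assert np.var(delta[:, 0]) > np.var(delta[:, 1])

    def test_vertical_is_rotated_horizontal(self, small_v1_graph, geometry):
        rng = np.random.default_rng(3)
        h = conn.apply_anisotropy(small_v1_graph, "horizontal", rng=np.random.default_rng(9))
        v = conn.apply_anisotropy(small_v1_graph, "vertical", rng=np.random.default_rng(9))
        center = geometry.center_e_index()
        for g, long_axis in ((h, 0), (v, 1)):
            out = g.weights[:, center].tocoo()
            targets = out.row[out.row < geometry.n_exc]
            delta = conn.torus_delta(
                g.positions[center], g.positions[targets], 40.0
            )
            assert np.var(delta[:, long_axis]) > np.var(delta[:, 1 - long_axis])

    def test_only_center_keeps_ee_and_strength_scaled(self, small_v1_graph, geometry):
        g = conn.apply_anisotropy(
            small_v1_graph, "horizontal", rng=np.random.default_rng(4)
        )
        n_e = geometry.n_exc
        center = geometry.center_e_index()
        ee = g.weights[:n_e, :n_e].tocoo()
        assert set(ee.col) <= {center}
        # multiples of 3 x g_EE
        g_ee = small_v1_graph.projections["EE"].g_s
        assert np.allclose(ee.data / (3 * g_ee) % 1.0, 0.0)

    def test_non_ee_projections_untouched(self, small_v1_graph, geometry):
        g = conn.apply_anisotropy(
            small_v1_graph, "horizontal", rng=np.random.default_rng(4)
        )
        n_e = geometry.n_exc
        diff_ei = g.weights[n_e:, :n_e] - small_v1_graph.weights[n_e:, :n_e]
        diff_ie = g.weights[:n_e, n_e:] - small_v1_graph.weights[:n_e, n_e:]
        assert abs(diff_ei).max() == 0.0
        assert abs(diff_ie).max() == 0.0


@pytest.fixture(scope="module")
def two_area(small_v1_graph):
    return conn.build_v1_v2_network(small_v1_graph, rng=np.random.default_rng(13))


class TestV1V2:

    def test_no_feedback_edges(self, two_area):
        v1 = np.flatnonzero(two_area.area == 0)
        v2 = np.flatnonzero(two_area.area == 1)
        feedback = two_area.weights[v1][:, v2]
        assert feedback.nnz == 0

    def test_feedforward_in_weight_fixed(self, two_area, small_v1_graph):
        v2 = np.flatnonzero(two_area.area == 1)
        v1e = two_area.v1_exc_indices()
        ff = two_area.weights[v2][:, v1e]
        spec = two_area.projections["FF"]
        in_w = np.asarray(ff.sum(axis=1)).ravel()
        expected = np.where(
            two_area.is_exc[v2], spec.n_s * spec.g_s, spec.n_s * spec.g_s * 0.5
        )
        assert np.allclose(in_w, expected)

    def test_membership_matrix_bounds(self, two_area):
        s = conn.membership_matrix(two_area)
        row_sums = np.asarray(s.sum(axis=1)).ravel()
        assert row_sums.max() <= two_area.projections["FF"].n_s
        assert row_sums.min() > 0

    def test_gaussian_footprint_more_central_than_uniform(self, small_v1_graph):
        gauss = conn.build_v1_v2_network(
            small_v1_graph,
            conn.FeedforwardSpec(footprint="gaussian", sigma=6.0),
            rng=np.random.default_rng(17),
        )
        unif = conn.build_v1_v2_network(
            small_v1_graph,
            conn.FeedforwardSpec(footprint="uniform"),
            rng=np.random.default_rng(17),
        )
        center = np.array([20.0, 20.0])

        def mean_input_distance(g):
            v2 = np.flatnonzero(g.area == 1)
            ff = g.weights[v2][:, g.v1_exc_indices()].tocoo()
            d = conn.torus_distance(g.positions[ff.col], center[None, :], 40.0)
            return (d * ff.data).sum() / ff.data.sum()

        assert mean_input_distance(gauss) < mean_input_distance(unif)
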