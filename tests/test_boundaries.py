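"""Lagrangian landscapes and level-set boundary extraction."""

import numpy as np
import pytest

from dfclust import (
    MixtureDensity,
    ScalarField,
    assign_labels,
    bounds_from_data,
    cluster_boundaries,
    fit_mixture_em,
    gen_gaussian_case,
    ldf_landscape,
)
from dfclust.boundaries import merge_level, points_in_polygon
from dfclust.errors import (
    DegenerateCentersError,
    InvalidParameterError,
)


@pytest.fixture(scope="module")
def lone_gaussian_field():
    model = MixtureDensity(weights=[1.0], means=[[0.0, 0.0]], covariances=[np.eye(2)])
    return model, ldf_landscape(model, [[-5, 5], [-5, 5]], 128)


@pytest.fixture(scope="module")
def pair_field():
    model = MixtureDensity(
        weights=[0.5, 0.5], means=[[0, 0], [10, 0]], covariances=[np.eye(2)] * 2
    )
    return model, ldf_landscape(model, [[-5, 15], [-6, 6]], 128)


class TestLdfLandscape:
    def test_radial_symmetry_of_lone_gaussian(self, lone_gaussian_field):
        _, field = lone_gaussian_field
        v = field.values
        np.testing.assert_allclose(v, v[::-1, :], atol=1e-6)
        np.testing.assert_allclose(v, v[:, ::-1], atol=1e-6)
        np.testing.assert_allclose(v, v.T, atol=1e-6)

    def test_gamma_converges_under_grid_doubling(self):
        model = MixtureDensity(
            weights=[0.5, 0.5], means=[[0, 0], [5, 0]], covariances=[np.eye(2)] * 2
        )
        g128 = ldf_landscape(model, [[-4, 9], [-4, 4]], 128).gamma
        g256 = ldf_landscape(model, [[-4, 9], [-4, 4]], 256).gamma
        assert abs(g256 - g128) / g128 < 0.01

    def test_case2_landscape_has_three_summit_regions(self, case2_bundle):
        """Each cluster is an elevated region of L separated by valleys: at
        the inter-cluster barrier level the superlevel set splits into (at
        least) three components holding one center each."""
        from skimage import measure

        model = fit_mixture_em(case2_bundle.data, 3, seed=1)
        field = ldf_landscape(model, bounds_from_data(case2_bundle.data), 128)
        cells = np.rint(field.to_index(model.means)).astype(int)
        barrier = max(
            merge_level(
                field.values,
                tuple(cells[k]),
                [tuple(c) for i, c in enumerate(cells) if i != k],
            )
            for k in range(3)
        )
        lbl = measure.label(field.values >= barrier, connectivity=2)
        comp_ids = {lbl[tuple(c)] for c in cells}
        assert len(comp_ids) == 3 and 0 not in comp_ids

    def test_zero_volume_bounds_rejected(self, lone_gaussian_field):
        model, _ = lone_gaussian_field
        with pytest.raises(InvalidParameterError):
            ldf_landscape(model, [[-1, -1], [0, 1]], 32)


class TestClusterBoundaries:
    def test_lone_gaussian_ring_encircles_mean(self, lone_gaussian_field):
        model, field = lone_gaussian_field
        sol = cluster_boundaries(field, model.means)
        assert len(sol.boundaries[0]) == 1
        poly = sol.boundaries[0][0]
        assert np.allclose(poly[0], poly[-1])
        assert points_in_polygon([[0.0, 0.0]], poly)[0]

    def test_ring_level_matches_ray_minima_within_one_cell(self, lone_gaussian_field):
        model, field = lone_gaussian_field
        sol = cluster_boundaries(field, model.means)
        poly = sol.boundaries[0][0]
        radii = np.hypot(poly[:, 0], poly[:, 1])
        ray_min = []
        for th in np.linspace(0, 2 * np.pi, 24, endpoint=False):
            tt = np.linspace(0.05, 4.5, 300)
            idx = np.clip(
                np.rint(field.to_index(np.outer(tt, [np.cos(th), np.sin(th)]))).astype(int),
                0,
                127,
            )
            vals = field.values[idx[:, 0], idx[:, 1]]
            ray_min.append(tt[np.argmin(vals)])
        assert abs(radii.mean() - np.mean(ray_min)) < field.spacing.max()

    def test_two_separated_gaussians_disjoint_contours(self, pair_field):
        model, field = pair_field
        sol = cluster_boundaries(field, model.means)
        for k in range(2):
            poly = sol.boundaries[k][0]
            assert np.allclose(poly[0], poly[-1])
            for j in range(2):
                inside = points_in_polygon([model.means[j]], poly)[0]
                assert inside == (j == k)

    def test_boundaries_do_not_cross(self, pair_field):
        model, field = pair_field
        sol = cluster_boundaries(field, model.means)
        a, b = sol.boundaries[0][0], sol.boundaries[1][0]
        assert not _polylines_intersect(a, b)

    def test_merge_level_monotone_in_competitor_set(self, case2_bundle):
        """Removing a competing center can only lower the pre-spill level."""
        model = fit_mixture_em(case2_bundle.data, 3, seed=1)
        field = ldf_landscape(model, bounds_from_data(case2_bundle.data), 96)
        cells = [tuple(c) for c in np.rint(field.to_index(model.means)).astype(int)]
        lam_full = merge_level(field.values, cells[0], [cells[1], cells[2]])
        lam_sub = merge_level(field.values, cells[0], [cells[1]])
        assert lam_sub <= lam_full + 1e-12

    def test_case2_mahalanobis_consistency(self):
        b = gen_gaussian_case(2, n_points=3000, seed=7)
        model = fit_mixture_em(b.data, 3, seed=1)
        field = ldf_landscape(model, bounds_from_data(b.data), 128)
        sol = cluster_boundaries(field, model.means, model=model)
        inv = [np.linalg.inv(c) for c in model.covariances]
        agree = total = 0
        for k, polys in enumerate(sol.boundaries):
            pts = b.data[points_in_polygon(b.data, polys[0])]
            d2 = np.stack(
                [
                    np.einsum("ij,jk,ik->i", pts - model.means[j], inv[j], pts - model.means[j])
                    for j in range(3)
                ],
                axis=1,
            )
            agree += int((np.argmin(d2, axis=1) == k).sum())
            total += len(pts)
        assert total > 0 and agree / total >= 0.95

    def test_center_off_grid_rejected(self, lone_gaussian_field):
        _, field = lone_gaussian_field
        with pytest.raises(InvalidParameterError):
            cluster_boundaries(field, [[40.0, 0.0]])

    def test_coincident_centers_rejected(self, lone_gaussian_field):
        _, field = lone_gaussian_field
        with pytest.raises(DegenerateCentersError):
            cluster_boundaries(field, [[0.0, 0.0], [0.001, 0.001]])


class TestAssignLabels:
    def test_point_at_center_gets_that_label(self, pair_field):
        model, field = pair_field
        sol = cluster_boundaries(field, model.means, model=model)
        labels = assign_labels(model.means, sol, model=model)
        np.testing.assert_array_equal(labels, [0, 1])

    def test_perfect_recovery_on_separated_fixture(self):
        from sklearn.metrics import adjusted_rand_score

        b = gen_gaussian_case(3, seed=5)
        model = fit_mixture_em(b.data, 3, seed=2)
        field = ldf_landscape(model, bounds_from_data(b.data), 128)
        sol = cluster_boundaries(field, model.means, model=model)
        labels = assign_labels(b.data, sol, model=model)
        assert adjusted_rand_score(b.truth["labels"], labels) == 1.0

    def test_equidistant_tie_breaks_to_lower_index(self):
        model = MixtureDensity(
            weights=[0.5, 0.5], means=[[-3.0, 0.0], [3.0, 0.0]], covariances=[np.eye(2)] * 2
        )
        sol = cluster_boundaries(
            ldf_landscape(model, [[-7, 7], [-4, 4]], 96), model.means, model=model
        )
        labels = assign_labels(np.array([[0.0, 0.0]]), sol, model=model)
        assert labels[0] == 0

    def test_every_point_assigned(self, case2_bundle):
        model = fit_mixture_em(case2_bundle.data, 3, seed=1)
        field = ldf_landscape(model, bounds_from_data(case2_bundle.data), 96)
        sol = cluster_boundaries(field, model.means, model=model)
        labels = assign_labels(case2_bundle.data, sol, model=model)
        assert labels.shape == (len(case2_bundle.data),)
        assert np.all((labels >= 0) & (labels < 3))


class TestScalarField:
    def test_index_feature_round_trip(self):
        f = ScalarField([1.0, -2.0], [0.5, 0.25], np.zeros((4, 8)), name="rho")
        pts = np.array([[1.5, -1.0], [2.0, 0.0]])
        np.testing.assert_allclose(f.to_feature(f.to_index(pts)), pts)

    def test_bad_name_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScalarField([0.0], [1.0], np.zeros(4), name="Q")


def _polylines_intersect(a, b):
    """Any proper crossing between segments of two closed polylines."""
    p, q = a[:-1], a[1:]
    r, s = b[:-1], b[1:]

    def cross(o, u, v):
        return (u[..., 0] - o[..., 0]) * (v[..., 1] - o[..., 1]) - (
            u[..., 1] - o[..., 1]
        ) * (v[..., 0] - o[..., 0])

    p_, q_ = p[:, None, :], q[:, None, :]
    r_, s_ = r[None, :, :], s[None, :, :]
    d1 = cross(p_, q_, r_) * cross(p_, q_, s_)
    d2 = cross(r_, s_, p_) * cross(r_, s_, q_)
    return bool(np.any((d1 < 0) & (d2 < 0)))
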