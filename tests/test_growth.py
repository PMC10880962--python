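"""Growth-tensor estimation: links, texture statistics, maps."""

import itertools

import numpy as np
import pytest
from scipy.spatial import Delaunay

from jawmorph import config
from jawmorph.growth import (GrowthMap, GrowthTensor, ROIGrid, SingularTextureError,
                             assemble_growth_map, auto_cutoff, build_links,
                             conserved_link_pairs, interpolate_growth,
                             label_axes_assignment, velocity_gradient_roi)
from jawmorph.mesh import AnatomicalFrame, CANONICAL_FRAME
from jawmorph.synthetic import CentroidSet, TrackedPair

DT = config.WINDOW_SECONDS


def _tetra_cells():
    pos = np.array([[0, 0, 0], [10, 0, 0], [5, 8.66, 0], [5, 2.89, 8.16]],
                   float)
    return CentroidSet(np.arange(4), pos)


class TestLinks:
    def test_regular_tetrahedron_has_six_links(self):
        links = build_links(_tetra_cells(), cutoff=np.inf)
        assert len(links) == 6

    def test_cutoff_below_edge_length_removes_all(self):
        links = build_links(_tetra_cells(), cutoff=1.0)
        assert len(links) == 0

    def test_links_match_independent_delaunay_enumeration(self, cells30):
        cutoff = auto_cutoff(cells30)
        links = build_links(cells30, cutoff)
        # independent enumeration: every simplex edge within the cutoff
        cs = cells30.sorted_by_id()
        tri = Delaunay(cs.positions)
        expected = set()
        for s in tri.simplices:
            for a, b in itertools.combinations(sorted(s), 2):
                if np.linalg.norm(cs.positions[b] - cs.positions[a]) <= cutoff:
                    expected.add((cs.cell_ids[a], cs.cell_ids[b]))
        got = {tuple(p) for p in links.id_pairs}
        assert got == expected

    def test_coplanar_points_rejected(self):
        flat = CentroidSet(np.arange(6),
                           np.column_stack([np.arange(6), np.arange(6) ** 2,
                                            np.zeros(6)]))
        with pytest.raises(ValueError):
            build_links(flat, cutoff=np.inf)

    def test_conserved_pairs_identity_and_linearity(self, cells30):
        same = TrackedPair(cells30, CentroidSet(cells30.cell_ids,
                                                cells30.positions, 4.5), DT)
        links = conserved_link_pairs(same)
        assert np.allclose(links.l0, links.l1)
        scaled = TrackedPair(cells30, CentroidSet(cells30.cell_ids,
                                                  1.1 * cells30.positions,
                                                  4.5), DT)
        links = conserved_link_pairs(scaled)
        assert np.allclose(links.l1, 1.1 * links.l0, rtol=1e-12)

    def test_conserved_count_equals_links_when_ids_conserved(self,
                                                             noisefree_pair):
        links = build_links(noisefree_pair.t0)
        conserved = conserved_link_pairs(noisefree_pair)
        assert len(conserved) == len(links)


class TestVelocityGradient:
    def test_pure_translation_gives_zero_tensor(self, cells30):
        links = build_links(cells30, cutoff=np.inf)
        t = velocity_gradient_roi(links.vectors, links.vectors, DT)
        assert np.allclose(t.tensor, 0.0, atol=1e-18)

    def test_isotropic_scaling_closed_form(self, cells30):
        k = 0.3
        links = build_links(cells30, cutoff=np.inf)
        t = velocity_gradient_roi(links.vectors, (1 + k) * links.vectors, DT)
        assert np.allclose(t.tensor, (k / DT) * np.eye(3), rtol=1e-10)
        assert np.allclose(t.eigenvalues, 6.944e-6, rtol=1e-3)

    def test_uniaxial_stretch_closed_form(self, cells30):
        k = 0.2
        links = build_links(cells30, cutoff=np.inf)
        l1 = links.vectors.copy()
        l1[:, 2] *= (1 + k)
        t = velocity_gradient_roi(links.vectors, l1, DT)
        expected = np.diag([0.0, 0.0, k / DT])
        assert np.allclose(t.tensor, expected, atol=1e-12 * k / DT + 1e-18)
        assert abs(t.rate("VD") - k / DT) < 1e-12
        assert abs(t.tensor[0, 2]) < 1e-12

    def test_small_rotation_vanishes_to_first_order(self, cells30):
        th = 0.05
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        links = build_links(cells30, cutoff=np.inf)
        t = velocity_gradient_roi(links.vectors, links.vectors @ R.T, DT)
        assert np.linalg.norm(t.tensor) <= 1.1 * th**2 / DT

    def test_too_few_links_flagged(self):
        with pytest.raises(SingularTextureError):
            velocity_gradient_roi(np.eye(3), np.eye(3), DT)


class TestAxisLabelling:
    def test_identity_eigenvectors_label_exactly(self):
        labels, angles = label_axes_assignment(np.eye(3), CANONICAL_FRAME)
        assert labels == {"VD": 2, "AP": 0, "ML": 1}
        assert all(a == pytest.approx(0.0, abs=1e-9) for a in angles.values())

    def test_rotation_about_ap_moves_vd_ml_labels(self):
        th = np.radians(10)
        R = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        labels, angles = label_axes_assignment(R, CANONICAL_FRAME)
        assert labels == {"VD": 2, "AP": 0, "ML": 1}
        assert angles["VD"] == pytest.approx(10.0, abs=1e-9)
        assert angles["ML"] == pytest.approx(10.0, abs=1e-9)
        assert angles["AP"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_45_degree_tie_is_deterministic(self):
        s = 1 / np.sqrt(2)
        vecs = np.column_stack([[s, 0, s], [-s, 0, s], [0, 1, 0]])
        results = {tuple(sorted(label_axes_assignment(vecs, CANONICAL_FRAME)[0]
                                .items())) for _ in range(5)}
        assert len(results) == 1

    def test_labels_are_a_bijection(self, noisefree_map):
        for t in noisefree_map.tensors:
            assert sorted(t.axis_labels.values()) == [0, 1, 2]


class TestGrowthMap:
    def test_global_affine_recovered_in_every_roi(self, cells30):
        rng = np.random.default_rng(0)
        A = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        moved = cells30.positions @ A.T + np.array([3.0, -2.0, 1.0])
        pair = TrackedPair(cells30, CentroidSet(cells30.cell_ids, moved, 4.5),
                           DT)
        gm = assemble_growth_map(pair)
        expected = 0.5 * ((A - np.eye(3)) + (A - np.eye(3)).T) / DT
        for t in gm.tensors:
            assert np.allclose(t.tensor, expected,
                               rtol=1e-8, atol=1e-8 * np.abs(expected).max())

    def test_single_roi_equals_full_link_statistic(self, noisefree_pair):
        grid = ROIGrid(origin=np.array([-200.0, -200.0, -200.0]),
                       cube_side=500.0)
        grid.occupied = grid.cell_of(noisefree_pair.t0.positions)
        grid.occupied = np.unique(grid.occupied, axis=0)
        assert len(grid.occupied) == 1
        gm = assemble_growth_map(noisefree_pair, grid)
        links = conserved_link_pairs(noisefree_pair)
        direct = velocity_gradient_roi(links.l0, links.l1, DT)
        assert np.allclose(gm.tensors[0].tensor, direct.tensor)

    def test_vd_rates_exceed_ml_rates_in_most_rois(self, noisefree_map):
        frac = np.mean([t.rate("VD") > t.rate("ML")
                        for t in noisefree_map.tensors])
        assert frac >= 0.8

    def test_eigenvalue_scales_for_default_data(self, noisefree_map):
        for t in noisefree_map.tensors:
            assert np.all(t.eigenvalues > -5e-6)
            assert np.all(t.eigenvalues < 5e-5)

    def test_frame_objectivity_under_rotation(self, cells30):
        k = 0.15
        l1_fn = lambda p: p * np.array([1 + k, 1.0, 1 + 2 * k])
        pair = TrackedPair(cells30, CentroidSet(cells30.cell_ids,
                                                l1_fn(cells30.positions), 4.5),
                           DT)
        links = conserved_link_pairs(pair)
        t = velocity_gradient_roi(links.l0, links.l1, DT)
        th = np.radians(30)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        rot_cells = CentroidSet(cells30.cell_ids, cells30.positions @ R.T)
        rot_pair = TrackedPair(rot_cells,
                               CentroidSet(cells30.cell_ids,
                                           l1_fn(cells30.positions) @ R.T,
                                           4.5), DT)
        rot_links = conserved_link_pairs(rot_pair)
        rot_frame = AnatomicalFrame(R @ CANONICAL_FRAME.ap,
                                    R @ CANONICAL_FRAME.ml,
                                    R @ CANONICAL_FRAME.vd)
        t_rot = velocity_gradient_roi(rot_links.l0, rot_links.l1, DT,
                                      frame=rot_frame)
        assert np.allclose(t_rot.tensor, R @ t.tensor @ R.T, atol=1e-10)
        assert np.allclose(sorted(t_rot.eigenvalues), sorted(t.eigenvalues),
                           atol=1e-12)

    def test_noise_robustness_regression(self, default_mesh, cells30,
                                         free_field):
        # estimator eigenvalues vs the window-secant ground-truth rates
        # (the statistic measures the finite-window pattern change); the
        # median is pooled over ROIs and three fixed noise seeds
        from jawmorph.synthetic import advect_tracked_pair
        errs, leading = [], 0.0
        for seed in (21, 22, 23):
            pair = advect_tracked_pair(cells30, free_field, DT,
                                       noise_sd=config.CENTROID_NOISE_SD_UM,
                                       seed=seed)
            gm = assemble_growth_map(pair)
            truth = free_field.rates(gm.roi_centres)      # (K, 3) AP/ML/VD
            secant = (np.exp(truth * DT) - 1.0) / DT
            for t, s in zip(gm.tensors, secant):
                errs.append(np.abs(np.sort(t.eigenvalues) - np.sort(s)).max())
            leading = max(leading, np.abs(secant).max())
        assert np.median(errs) < 0.15 * leading

    def test_csv_round_trip(self, noisefree_map, tmp_path):
        path = tmp_path / "map.csv"
        noisefree_map.to_csv(path)
        back = GrowthMap.from_csv(path)
        assert np.array_equal(back.roi_indices, noisefree_map.roi_indices)
        for a, b in zip(back.tensors, noisefree_map.tensors):
            assert np.allclose(a.tensor, b.tensor)
            assert a.n_links == b.n_links


class TestInterpolation:
    def _two_roi_map(self):
        T = np.diag([1.0, 2.0, 3.0]) * 1e-6
        grid = ROIGrid(origin=np.zeros(3), cube_side=10.0,
                       occupied=np.array([[0, 0, 0], [1, 0, 0]]))
        tensors = [GrowthTensor.from_tensor(T),
                   GrowthTensor.from_tensor(3 * T)]
        return GrowthMap(grid=grid, roi_indices=grid.occupied,
                         tensors=tensors), T

    def test_query_at_roi_centre_is_exact(self):
        gm, T = self._two_roi_map()
        out = gm.interpolate(gm.roi_centres[:1])
        assert np.allclose(out[0], T)

    def test_query_midway_is_linear(self):
        gm, T = self._two_roi_map()
        mid = gm.roi_centres.mean(axis=0, keepdims=True)
        assert np.allclose(gm.interpolate(mid)[0], 2 * T)

    def test_query_far_outside_returns_nearest(self):
        gm, T = self._two_roi_map()
        far = np.array([[1000.0, 0.0, 0.0]])
        assert np.allclose(interpolate_growth(gm, far)[0], 3 * T)

    def test_interpolated_tensors_symmetric(self, noisefree_map):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-20, 100, size=(50, 3))
        out = noisefree_map.interpolate(pts)
        assert np.allclose(out, np.transpose(out, (0, 2, 1)), atol=1e-15)
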