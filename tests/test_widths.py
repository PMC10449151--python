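"""Centreline extraction, orientation, edge localisation and width accuracy."""

import numpy as np
import pytest
from scipy import ndimage

from retimorph import (VesselMask, WidthConfig, edge_points,
                       extract_centrelines, local_orientation, measure_widths)
from retimorph.synthetic import straight_vessel_image


class TestCentrelines:
    def test_straight_bar_is_one_segment(self):
        m = np.zeros((20, 60), bool)
        m[8:13, 10:50] = True
        graph = extract_centrelines(VesselMask(m))
        assert len(graph.segments) == 1
        pts = graph.segments[0].points
        assert 30 <= len(pts) <= 40
        interior = pts[2:-2]
        assert np.all(interior[:, 0] == interior[0, 0])   # collinear, horizontal
        assert len(graph.nodes) == 2                      # two end points

    def test_y_shape_has_three_segments_and_one_junction(self):
        from skimage import draw
        m = np.zeros((64, 64), bool)
        for r1, c1 in ((12, 50), (52, 50)):      # two branches from (32, 30)
            rr, cc = draw.line(32, 30, r1, c1)
            m[rr, cc] = True
        rr, cc = draw.line(32, 8, 32, 30)        # stem
        m[rr, cc] = True
        m = ndimage.binary_dilation(m, iterations=2)
        graph = extract_centrelines(VesselMask(m))
        assert len(graph.segments) == 3
        assert len(graph.nodes) >= 4             # junction cluster + 3 ends

    def test_skeleton_is_thin(self, segmented_default):
        _, _, _, graph = segmented_default
        sk = graph.skeleton
        solid = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
        assert not solid.any()

    def test_empty_mask_gives_empty_graph(self):
        graph = extract_centrelines(VesselMask(np.zeros((32, 32), bool)))
        assert graph.segments == [] and len(graph.nodes) == 0

    def test_skeleton_tracks_true_centrelines(self, default_retina):
        """Skeleton of the ground-truth mask stays near true centreline points."""
        _, truth = default_retina
        graph = extract_centrelines(VesselMask(truth.vessel_mask))
        pts = truth.centreline_array()
        from scipy.spatial import cKDTree
        tree = cKDTree(pts)
        widths = np.array([p.width for p in truth.centreline_points])
        excess = []
        for seg in graph.segments:
            d, j = tree.query(seg.points.astype(float))
            excess.extend(d - widths[j] / 2)
        excess = np.array(excess)
        assert np.mean(excess <= 1.0) >= 0.99   # junction bulges excepted
        assert excess.max() <= 2.0


class TestOrientation:
    def test_horizontal_chain(self):
        chain = np.array([[5, c] for c in range(11)])
        assert local_orientation(chain, 5) == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_chain(self):
        chain = np.array([[k, k] for k in range(11)])
        assert local_orientation(chain, 5) == pytest.approx(np.pi / 4, abs=1e-6)

    def test_circle_tangent_is_orthogonal_to_radius(self):
        angles = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        chain = np.array([(50 + 30 * np.sin(a), 50 + 30 * np.cos(a))
                          for a in angles]).round().astype(int)
        chain = chain[np.r_[True, np.any(np.diff(chain, axis=0) != 0, axis=1)]]
        for i in range(5, len(chain) - 5, 7):
            theta = local_orientation(chain, i, 5)
            radial = np.arctan2(chain[i, 0] - 50, chain[i, 1] - 50)
            diff = (theta - (radial + np.pi / 2)) % np.pi
            diff = min(diff, np.pi - diff)
            assert diff <= np.deg2rad(5)

    def test_single_point_window_rejected(self):
        with pytest.raises(ValueError):
            local_orientation(np.array([[1, 1], [1, 1]]), 0, 0)


class TestEdgePoints:
    def test_gaussian_trough_closed_form(self):
        """Second-derivative zero-crossings of a Gaussian trough sit at ±sigma."""
        img, _ = straight_vessel_image((96, 96), (48, 48), 0.0, 8)  # sigma=4
        res = edge_points(img, (48.0, 48.0), 0.0)
        assert res is not None
        el, er, width = res
        assert width == pytest.approx(8.0, abs=0.25)
        assert np.hypot(er[0] - el[0], er[1] - el[1]) == pytest.approx(width, abs=1e-9)

    def test_flat_image_has_no_edges(self):
        assert edge_points(np.full((64, 64), 0.5), (32.0, 32.0), 0.0) is None

    def test_width_invariant_to_rotation_and_rescaling(self):
        img, _ = straight_vessel_image((96, 96), (48, 48), 0.0, 12)
        w0 = edge_points(img, (48.0, 48.0), 0.0)[2]
        rot = np.rot90(img)
        w90 = edge_points(rot, (48.0, 47.0), np.pi / 2)[2]
        assert abs(w90 - w0) <= 0.25
        scaled = 0.2 + 0.5 * img
        ws = edge_points(scaled, (48.0, 48.0), 0.0)[2]
        assert abs(ws - w0) <= 0.25


class TestMeasureWidths:
    def test_empty_graph_gives_empty_list(self):
        from retimorph.widths import CentrelineGraph
        graph = CentrelineGraph(nodes=np.empty((0, 2), int), segments=[])
        assert measure_widths(np.ones((32, 32)), graph) == []

    @pytest.mark.parametrize("nominal", [5, 10, 15, 20, 25])
    def test_straight_vessel_widths_recovered(self, nominal):
        """Mean absolute error <= 1 px across 8 orientations per calibre."""
        errors = []
        for k in range(8):
            ang = k * np.pi / 8
            img, d = straight_vessel_image((128, 128), (64, 64), ang, nominal)
            mask = VesselMask(np.abs(d) <= nominal / 2)
            graph = extract_centrelines(mask)
            ms = measure_widths(img, graph, mask=mask)
            w = np.array([m.width for m in ms if m.valid])
            assert len(w) > 5
            errors.append(abs(w.mean() - nominal))
        assert np.mean(errors) <= 1.0

    def test_reflex_profiles_keep_outer_edges(self):
        """The bright axial reflex must not masquerade as the vessel wall."""
        for nominal in (8, 12, 16, 20):
            img, d = straight_vessel_image((128, 128), (64, 64), 0.4, nominal,
                                           "central_reflex", "A")
            mask = VesselMask(np.abs(d) <= nominal / 2)
            graph = extract_centrelines(mask)
            ms = measure_widths(img, graph, mask=mask)
            w = np.array([m.width for m in ms if m.valid])
            assert w.mean() >= 0.75 * nominal

    def test_disc_exclusion_zone(self):
        img, d = straight_vessel_image((128, 128), (64, 64), 0.0, 10)
        mask = VesselMask(np.abs(d) <= 5)
        graph = extract_centrelines(mask)
        ms = measure_widths(img, graph, mask=mask,
                            disc_centre=(64.0, 64.0), disc_radius=20.0)
        rejected = [m for m in ms if m.reject_reason == "optic_disc"]
        kept = [m for m in ms if m.valid]
        assert rejected
        assert all(np.hypot(m.centre[0] - 64, m.centre[1] - 64) > 24
                   for m in kept)

    def test_invalid_measurements_carry_reasons(self):
        img = np.full((64, 64), 0.5)               # flat: no edges anywhere
        m = np.zeros((64, 64), bool)
        m[30:35, 10:54] = True
        graph = extract_centrelines(VesselMask(m))
        ms = measure_widths(img, graph)
        assert ms and all(not x.valid and x.reject_reason == "no_edge"
                          for x in ms)
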