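"""Region geometry: backbones, orthogonal regions, assignment, validation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon
from shapely.ops import unary_union

from flowworm.events import EventTable
from flowworm.gating import (Backbone, PolygonRegion, RegionScheme, ViewSpec,
                             assign_events, build_orthogonal_regions,
                             ridge_anchors, segment_histogram_1d,
                             trace_backbone, validate_scheme)

VIEW = ViewSpec("x", "y")


class TestBackbone:
    def test_manual_anchors_returned_verbatim(self, simple_events):
        anchors = np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 0.0]])
        bb = trace_backbone(simple_events, VIEW, anchors=anchors)
        np.testing.assert_array_equal(bb.anchors, anchors)

    def test_line_data_gives_collinear_ridge(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 5_000)
        events = EventTable(pd.DataFrame(
            {"x": x, "y": x + rng.normal(0, 0.05, x.size)}))
        bb = trace_backbone(events, VIEW)
        # ridge of the smoothed histogram stays on y = x
        assert np.median(np.abs(bb.anchors[:, 1] - bb.anchors[:, 0])) < 0.15
        assert np.max(np.abs(bb.anchors[:, 1] - bb.anchors[:, 0])) < 0.5

    def test_disconnected_density_raises(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0, 0], 0.2, (3_000, 2))
        b = rng.normal([10, 10], 0.2, (3_000, 2))
        events = EventTable(pd.DataFrame(np.vstack([a, b]),
                                         columns=["x", "y"]))
        with pytest.raises(ValueError, match="manual anchors"):
            trace_backbone(events, VIEW)

    def test_worm_backbone_follows_true_curve(self, panels, model):
        # the automatically traced interphase worm stays within one local
        # noise SD of the noiseless trajectory (nearest-distance match)
        info = panels["a2"]
        events = info["pop"].events
        view = info["scheme"].regions[0].view
        interphase = events.subset(~events.masks["R3"].mask)
        bb = trace_backbone(interphase, view)
        u = np.linspace(0.001, 0.92, 600)
        truth = np.column_stack([
            np.arcsinh(model.curve("cyclin_a2")(u) / view.cofactor),
            np.arcsinh(model.curve("phh3")(u) / view.cofactor)])
        d = np.min(np.linalg.norm(bb.anchors[:, None, :] - truth[None], axis=2),
                   axis=1)
        sigma = np.sqrt(np.log1p(0.12 ** 2))
        assert np.median(d) < sigma
        assert d.max() < 3 * sigma

    def test_projection_orders_points_along_arc(self):
        bb = Backbone(VIEW, np.array([[0.0, 0.0], [10.0, 0.0]]))
        pts = np.array([[1.0, 0.2], [5.0, -0.3], [9.0, 0.1]])
        s = bb.project(pts)
        assert np.all(np.diff(s) > 0)


class TestOrthogonalRegions:
    def test_horizontal_backbone_gives_vertical_sides(self):
        bb = Backbone(VIEW, np.array([[0.0, 0.0], [10.0, 0.0]]))
        regions = build_orthogonal_regions(bb, n_regions=5, half_width=1.0)
        assert len(regions) == 5
        for r in regions:
            xs = r.vertices[:, 0]
            # dividing sides are vertical: paired x coordinates
            assert np.allclose(sorted(xs)[:2], sorted(xs)[0]) \
                and np.allclose(sorted(xs)[2:], sorted(xs)[2])

    def test_diagonal_backbone_gives_congruent_regions(self):
        bb = Backbone(VIEW, np.array([[0.0, 0.0], [10.0, 10.0]]))
        regions = build_orthogonal_regions(bb, n_regions=4, half_width=0.5)
        areas = [r.polygon.area for r in regions]
        np.testing.assert_allclose(areas, areas[0])
        # dividing sides are perpendicular to the 45 degree run
        v = regions[0].vertices
        side = v[1] - v[0]
        np.testing.assert_allclose(side @ np.array([1.0, 1.0]), 0, atol=1e-9)

    def test_semicircle_no_overlap_no_gap(self):
        theta = np.linspace(0, np.pi, 200)
        bb = Backbone(VIEW, np.column_stack([np.cos(theta), np.sin(theta)]))
        regions = build_orthogonal_regions(bb, n_regions=10, half_width=0.2)
        polys = [r.polygon for r in regions]
        # independent geometry oracle: pairwise intersections and union
        inter = sum(polys[i].intersection(polys[j]).area
                    for i in range(10) for j in range(i + 1, 10))
        assert inter < 1e-9
        union = unary_union(polys).area
        assert abs(union - sum(p.area for p in polys)) < 1e-9

    def test_high_curvature_raises_helpful_error(self):
        sharp = Backbone(VIEW, np.array([[0, 0], [1, 0], [1.05, 1.0]]))
        with pytest.raises(ValueError, match="fewer regions or a narrower"):
            build_orthogonal_regions(sharp, n_regions=8, half_width=2.0,
                                     tangent_window=0.005)

    def test_shared_edges_reused_exactly(self):
        bb = Backbone(VIEW, np.array([[0.0, 0.0], [10.0, 3.0]]))
        regions = build_orthogonal_regions(bb, n_regions=3, half_width=0.7)
        for a, b in zip(regions[:-1], regions[1:]):
            np.testing.assert_array_equal(a.vertices[3], b.vertices[0])
            np.testing.assert_array_equal(a.vertices[2], b.vertices[1])


def grid_scheme():
    """Two adjacent unit squares sharing the x=1 edge."""
    r1 = PolygonRegion(0, VIEW, [[0, 0], [1, 0], [1, 1], [0, 1]])
    r2 = PolygonRegion(1, VIEW, [[1, 0], [2, 0], [2, 1], [1, 1]])
    return RegionScheme([r1, r2])


class TestAssignment:
    def test_interior_point_assigned(self):
        events = EventTable(pd.DataFrame({"x": [0.5, 1.5], "y": [0.5, 0.5]}))
        labels = assign_events(events, grid_scheme())
        np.testing.assert_array_equal(labels, [0, 1])

    def test_shared_edge_goes_to_earlier_region(self):
        events = EventTable(pd.DataFrame({"x": [1.0], "y": [0.5]}))
        labels = assign_events(events, grid_scheme())
        assert labels[0] == 0

    def test_counts_conserved(self, panels):
        info = panels["a2"]
        labels = info["labels"]
        n_assigned = int((labels >= 0).sum())
        per_region = sum(int((labels == r.global_index).sum())
                         for r in info["scheme"].regions)
        assert per_region == n_assigned
        assert n_assigned + int((labels < 0).sum()) == len(labels)

    def test_gate_context_respected(self, panels):
        info = panels["a2"]
        events = info["pop"].events
        labels = info["labels"]
        r3 = events.masks["R3"].mask
        for region in info["scheme"].regions:
            sel = labels == region.global_index
            if region.gate_context in ("R3_RISE", "R3_TOP"):
                assert r3[sel].all()
            elif region.gate_context and "NOT R3)" in region.gate_context:
                assert not r3[sel].any()


class TestValidation:
    def test_orthogonal_scheme_validates_clean(self, panels):
        info = panels["a2"]
        report = validate_scheme(info["scheme"], info["pop"].events,
                                 truth_u=info["pop"].truth["u"].to_numpy())
        assert report.n_overlaps == 0
        assert report.unassigned_fraction < 0.02
        assert report.u_monotone is True
        assert report.min_events >= 50

    def test_shifted_region_flagged_as_overlap(self):
        scheme = grid_scheme()
        shifted = PolygonRegion(1, VIEW, np.array(
            [[0.5, 0], [1.5, 0], [1.5, 1], [0.5, 1]]))
        bad = RegionScheme([scheme.regions[0], shifted])
        events = EventTable(pd.DataFrame({"x": [0.5], "y": [0.5]}))
        report = validate_scheme(bad, events)
        assert report.n_overlaps >= 1 and not report.ok

    def test_scheme_json_roundtrip(self, panels, tmp_path):
        scheme = panels["a2"]["scheme"]
        path = tmp_path / "scheme.json"
        scheme.to_json(path)
        back = RegionScheme.from_json(path)
        assert len(back.regions) == len(scheme.regions)
        for a, b in zip(back.regions, scheme.regions):
            np.testing.assert_allclose(a.vertices, b.vertices)
            assert a.gate_context == b.gate_context
            assert a.view.key() == b.view.key()


class TestSegmentHistogram1D:
    def test_single_interval_is_whole_sample(self):
        values = np.arange(100.0)
        seg = segment_histogram_1d(values, [1000.0])
        assert seg.counts[0] == 100 and np.isnan(seg.medians[1])
        assert seg.medians[0] == np.median(values)

    def test_fig2_g1_interval_fraction_matches_cdf(self, fig2_mixture,
                                                   fig2_sample):
        from scipy.stats import norm
        from flowworm.pipeline import dna_segment_boundaries
        bounds = dna_segment_boundaries(100, 3, 200, 6, 7)
        seg = segment_histogram_1d(fig2_sample.values, bounds)
        oracle = sum(c.area * norm.cdf(bounds[0], c.mean, c.sd)
                     for c in fig2_mixture.components)
        assert abs(seg.fractions[0] - oracle) < 0.01

    def test_empty_interval_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            seg = segment_histogram_1d(np.array([1.0, 10.0]), [3.0, 5.0])
        assert seg.counts[1] == 0 and np.isnan(seg.medians[1])

    def test_nonincreasing_boundaries_rejected(self):
        with pytest.raises(ValueError):
            segment_histogram_1d(np.arange(10.0), [5.0, 2.0])


def test_ridge_anchors_monotone_and_centered():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 10, 8_000)
    y = 2 * x + rng.normal(0, 0.3, x.size)
    anchors = ridge_anchors(np.column_stack([x, y]), axis=0, n_bins=10)
    assert np.all(np.diff(anchors[:, 0]) > 0)
    np.testing.assert_allclose(anchors[:, 1], 2 * anchors[:, 0], atol=0.15)
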