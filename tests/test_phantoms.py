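"""Phantom generator: exact mass calibration, truth records, seeded reproducibility."""

import numpy as np
import pytest

from qpihuvec import (CellPhantomSpec, DebrisSpec, OpticsConfig, PlacementError,
                      ShapeDrift, brick_lattice_graph, line_graph, logistic3,
                      loop_graph, render_cell, render_field, render_network,
                      simulate_dose_response, simulate_timelapse, y_graph)
from qpihuvec.phantoms import SeedGraph

CONCS = list(np.linspace(-13.0, np.log10(3e-9), 8))


class TestRenderCell:
    def test_hemisphere_truth_sphericity_is_one(self, hemisphere_case):
        _, truth = hemisphere_case
        assert truth.objects[0].sphericity == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("model,radii,height", [
        ("spherical_cap", (15.0, 15.0), 6.0),
        ("ellipsoidal_cap", (16.6, 10.0), 5.0),
        ("gaussian_bump", (12.0, 9.0), 3.0),
    ])
    def test_dry_mass_rescaling_is_exact(self, model, radii, height, optics):
        spec = CellPhantomSpec(model, radii, height, dry_mass=12.0)
        image, truth = render_cell(spec, optics=optics)
        integrated = image.opd.sum() * optics.pixel_area / optics.alpha
        assert integrated == pytest.approx(12.0, abs=1e-9)
        assert truth.objects[0].dry_mass == 12.0

    def test_ellipsoidal_cap_axis_ratio_truth(self):
        spec = CellPhantomSpec("ellipsoidal_cap", (16.6, 10.0), 5.0)
        _, truth = render_cell(spec)
        assert truth.objects[0].length_width_ratio == pytest.approx(1.66)

    def test_footprint_must_fit_canvas(self, optics):
        spec = CellPhantomSpec("spherical_cap", (40.0, 40.0), 10.0,
                               centroid=(10.0, 10.0))
        with pytest.raises(ValueError, match="canvas"):
            render_cell(spec, optics=optics, canvas=(64, 64))

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError, match="height"):
            CellPhantomSpec("spherical_cap", (10.0, 10.0), 0.0)

    def test_opd_nonnegative_and_canvas_shape(self, hemisphere_case):
        image, _ = hemisphere_case
        assert image.opd.shape == (128, 128)
        assert np.all(image.opd >= 0)


class TestRenderField:
    def test_truth_debris_percentage(self, optics):
        cells = [CellPhantomSpec("spherical_cap", (12.0, 12.0), 4.0)
                 for _ in range(37)]
        image, truth = render_field(cells, DebrisSpec(count=4), optics=optics,
                                    canvas=(700, 700), seed=3)
        assert truth.debris_percent == pytest.approx(100.0 * 4 / 41)
        assert sum(o.is_debris for o in truth.objects) == 4

    def test_no_debris_gives_zero_percent(self, optics):
        cells = [CellPhantomSpec("spherical_cap", (12.0, 12.0), 4.0)]
        _, truth = render_field(cells, None, optics=optics, canvas=(256, 256), seed=0)
        assert truth.debris_percent == 0.0

    def test_composite_mass_is_sum_of_parts(self, optics):
        # direct-summation oracle over the composite raster
        spec = CellPhantomSpec("spherical_cap", (10.0, 10.0), 4.0, dry_mass=7.5)
        single, _ = render_cell(spec, optics=optics)
        single_mass = single.opd.sum() * optics.pixel_area / optics.alpha
        image, truth = render_field([spec] * 10, None, optics=optics,
                                    canvas=(600, 600), seed=1)
        composite_mass = image.opd.sum() * optics.pixel_area / optics.alpha
        assert composite_mass == pytest.approx(10 * single_mass, rel=1e-12)
        assert truth.total_dry_mass == pytest.approx(75.0)

    def test_same_seed_reproduces_raster_bitwise(self, optics):
        cells = [CellPhantomSpec("ellipsoidal_cap", (14.0, 9.0), 4.0)
                 for _ in range(10)]
        img1, _ = render_field(cells, DebrisSpec(count=3), optics=optics,
                               canvas=(512, 512), seed=11)
        img2, _ = render_field(cells, DebrisSpec(count=3), optics=optics,
                               canvas=(512, 512), seed=11)
        assert np.array_equal(img1.opd, img2.opd)

    def test_impossible_density_raises_with_achieved_count(self, optics):
        cells = [CellPhantomSpec("spherical_cap", (20.0, 20.0), 5.0)
                 for _ in range(50)]
        with pytest.raises(PlacementError, match="attempts"):
            render_field(cells, None, optics=optics, canvas=(128, 128),
                         seed=0, max_attempts=50)

    def test_debris_areas_must_stay_below_gate(self):
        with pytest.raises(ValueError, match="gate"):
            DebrisSpec(count=1, area_range=(100.0, 450.0))


class TestRenderNetwork:
    def test_y_graph_truth(self):
        truth = y_graph(100.0).truth()
        assert (truth.n_segments, truth.n_junctions, truth.n_extremities,
                truth.n_branches) == (3, 1, 3, 3)
        assert truth.total_length == pytest.approx(300.0)
        assert truth.median_segment_length == pytest.approx(100.0)

    def test_single_tube_truth(self):
        truth = line_graph(250.0).truth()
        assert (truth.n_segments, truth.n_junctions, truth.n_extremities,
                truth.n_branches) == (1, 0, 2, 1)
        assert truth.total_length == pytest.approx(250.0)

    def test_lattice_truth_matches_adjacency_tally(self):
        g = brick_lattice_graph(3, 3, 100.0, whisker=40.0)
        truth = g.truth()
        # independent brute-force tally over the seed edge list
        deg = {}
        for u, v, _ in g.edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        assert truth.n_segments == len(g.edges)
        assert truth.n_junctions == sum(1 for d in deg.values() if d >= 3)
        assert truth.n_extremities == sum(1 for d in deg.values() if d == 1)
        assert truth.n_branches == sum(1 for u, v, _ in g.edges
                                       if deg[u] == 1 or deg[v] == 1)

    def test_degree_two_node_rejected(self):
        g = SeedGraph(nodes={0: (0, 0), 1: (50, 0), 2: (100, 0)},
                      edges=[(0, 1, None), (1, 2, None)])
        with pytest.raises(ValueError, match="degree 2"):
            render_network(g.translated(50, 50), canvas=(400, 400))

    def test_rendered_image_covers_tubes(self):
        g = line_graph(100.0).translated(50, 100)
        image, truth = render_network(g, tube_width=12.0, tube_opd=0.3,
                                      canvas=(400, 400))
        area = (image.opd > 0).sum() * image.optics.pixel_area
        stadium = 100.0 * 12.0 + np.pi * 6.0**2  # rectangle + end caps
        assert area == pytest.approx(stadium, rel=0.05)
        assert truth.network.n_segments == 1

    def test_loop_truth_has_no_nodes(self):
        truth = loop_graph(150.0).truth()
        assert (truth.n_segments, truth.n_junctions, truth.n_extremities,
                truth.n_branches) == (1, 0, 0, 0)
        assert truth.total_length == pytest.approx(600.0)


class TestSimulateDoseResponse:
    def test_half_maximal_point(self):
        table, _ = simulate_dose_response(2.0, 1.0, -10.0, [-10.0],
                                          n_replicates=1, noise_sd=0.0)
        assert table["y"].iloc[0] == pytest.approx(1.5)

    def test_lower_plateau(self):
        table, truth = simulate_dose_response(2.0, 1.0, -10.0, [-20.0],
                                              n_replicates=1, noise_sd=0.0)
        span = truth.dose_response.span
        assert abs(table["y"].iloc[0] - 1.0) < 1e-6 * span

    def test_noiseless_table_reproduces_pointwise_formula(self):
        top, bottom, lec = 100.0, 36.6, -10.37
        table, _ = simulate_dose_response(top, bottom, lec, CONCS,
                                          n_replicates=2, noise_sd=0.0)
        # independent pointwise evaluation of the printed formula
        for x, y in zip(table["x"], table["y"]):
            expected = bottom + (top - bottom) / (10.0 ** (lec - x) + 1.0)
            assert y == pytest.approx(expected, abs=1e-12)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_dose_response(1.0, 0.0, -10.0, [], 2, 0.0)

    def test_seeded_noise_reproducible(self):
        t1, _ = simulate_dose_response(1.0, 0.0, -10.0, CONCS, 2, 0.1, seed=5)
        t2, _ = simulate_dose_response(1.0, 0.0, -10.0, CONCS, 2, 0.1, seed=5)
        assert t1.equals(t2)


class TestSimulateTimelapse:
    POP = [CellPhantomSpec("ellipsoidal_cap", (1.66 * b, b), 0.25 * b)
           for b in (9.0, 10.0, 11.0, 12.0)]

    def test_zero_drift_keeps_truth_constant(self):
        _, truth = simulate_timelapse(self.POP, ShapeDrift(), frames=3,
                                      interval_h=3.0, canvas=(512, 512), seed=2)
        sph = [f.mean_sphericity for f in truth.frames]
        lw = [f.mean_length_width_ratio for f in truth.frames]
        assert max(sph) - min(sph) < 1e-12
        assert max(lw) - min(lw) < 1e-12

    def test_elongation_drift_accumulates_linearly(self):
        # +0.005/h on L/W for 36 h from 1.66 -> 1.84 by direct accumulation
        _, truth = simulate_timelapse(self.POP, ShapeDrift(lw_per_h=0.005),
                                      frames=13, interval_h=3.0,
                                      canvas=(640, 640), seed=2)
        assert truth.frames[0].mean_length_width_ratio == pytest.approx(1.66)
        assert truth.frames[-1].mean_length_width_ratio == pytest.approx(
            1.66 + 0.005 * 36.0, abs=1e-9)

    def test_rounding_drift_monotone_sphericity(self):
        _, truth = simulate_timelapse(self.POP,
                                      ShapeDrift(height_ratio_per_h=0.01),
                                      frames=5, interval_h=3.0,
                                      canvas=(512, 512), seed=2)
        sph = [f.mean_sphericity for f in truth.frames]
        assert all(b >= a for a, b in zip(sph, sph[1:]))

    def test_needs_at_least_two_frames(self):
        with pytest.raises(ValueError, match="frames"):
            simulate_timelapse(self.POP, frames=1)


def test_logistic3_plateaus_and_midpoint():
    assert logistic3(-10.0, 2.0, 1.0, -10.0) == pytest.approx(1.5)
    assert logistic3(0.0, 2.0, 1.0, -10.0) == pytest.approx(2.0, abs=1e-9)
    assert logistic3(-30.0, 2.0, 1.0, -10.0) == pytest.approx(1.0, abs=1e-9)
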