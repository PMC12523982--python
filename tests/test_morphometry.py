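"""Segmentation, size gate and per-cell metric accuracy against phantom truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qpihuvec import (CellPhantomSpec, DebrisSpec, GateSummary, LabelMap,
                      OpticsConfig, PhaseImage, apply_size_gate,
                      cap_ratio_for_sphericity, measure, pair_fluorescence,
                      render_cell, render_field, segment, split_by_sphericity)
from conftest import measure_single


class TestSegment:
    def test_single_phantom_one_object(self, hemisphere_case):
        image, _ = hemisphere_case
        assert segment(image).n_objects == 1

    def test_all_zero_image_yields_empty_labelmap(self, optics):
        image = PhaseImage(np.zeros((64, 64)), optics)
        lm = segment(image)
        assert lm.n_objects == 0

    def test_field_objects_match_truth_centroids(self, optics):
        cells = [CellPhantomSpec("ellipsoidal_cap", (14.0, 10.0), 4.0)
                 for _ in range(20)]
        image, truth = render_field(cells, None, optics=optics,
                                    canvas=(1024, 1024), seed=4)
        lm = segment(image)
        assert lm.n_objects == 20
        px = optics.pixel_size
        for obj in truth.objects:
            cx, cy = obj.centroid
            label = lm.labels[int(cy / px), int(cx / px)]
            assert label > 0, "every truth centroid falls inside a segmented object"
        # and each object holds exactly one truth centroid
        hit = {lm.labels[int(o.centroid[1] / px), int(o.centroid[0] / px)]
               for o in truth.objects}
        assert len(hit) == 20

    def test_touching_cells_split_by_watershed(self, optics):
        # two caps whose footprints meet at a tangent point
        a = CellPhantomSpec("spherical_cap", (12.0, 12.0), 5.0, centroid=(50.0, 64.0))
        b = CellPhantomSpec("spherical_cap", (12.0, 12.0), 5.0, centroid=(74.5, 64.0))
        opd = np.zeros((256, 256))
        image = PhaseImage(opd, optics)
        from qpihuvec.phantoms import _render_onto
        _render_onto(image.opd, a, optics, 1)
        _render_onto(image.opd, b, optics, 2)
        lm = segment(image)
        assert lm.n_objects == 2
        px = optics.pixel_size
        la = lm.labels[int(64 / px), int(50 / px)]
        lb = lm.labels[int(64 / px), int(74.5 / px)]
        assert la != lb and la > 0 and lb > 0

    def test_nonfinite_image_rejected(self, optics):
        opd = np.zeros((32, 32))
        opd[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            segment(PhaseImage(opd, optics))


class TestSizeGate:
    def _labelmap_with_areas(self, areas_um2):
        """Rectangular objects of exact pixel-count areas at 1 µm/px."""
        h = 30
        widths = [int(a) // h for a in areas_um2]
        assert all(int(a) % h == 0 or True for a in areas_um2)
        total_w = sum(w + 3 for w in widths) + 3
        labels = np.zeros((h + 6, total_w), dtype=np.int32)
        x = 3
        for i, a in enumerate(areas_um2, start=1):
            w = int(a) // h
            rem = int(a) - w * h
            labels[3:3 + h, x:x + w] = i
            if rem:
                labels[3:3 + rem, x + w] = i
            x += w + 3
        return LabelMap(labels, pixel_size=1.0)

    def test_strict_gate_boundary(self):
        lm = self._labelmap_with_areas([399, 400, 401])
        cells, debris, summary = apply_size_gate(lm, min_area=400.0, strict=True)
        assert summary.n_cells == 1 and summary.n_debris == 2
        assert cells.n_objects == 1 and debris.n_objects == 2

    def test_inclusive_gate_boundary(self):
        lm = self._labelmap_with_areas([399, 400, 401])
        _, _, summary = apply_size_gate(lm, min_area=400.0, strict=False)
        assert summary.n_cells == 2 and summary.n_debris == 1

    def test_empty_labelmap_summary(self):
        lm = LabelMap(np.zeros((16, 16), dtype=np.int32), 1.0)
        _, _, summary = apply_size_gate(lm)
        assert (summary.n_total, summary.n_cells, summary.n_debris) == (0, 0, 0)
        assert summary.debris_percent == 0.0

    def test_field_debris_percent_matches_seeded_fraction(self, optics):
        cells = [CellPhantomSpec("spherical_cap", (13.0, 13.0), 4.0)
                 for _ in range(37)]  # area 531 µm², safely above the gate
        image, truth = render_field(cells, DebrisSpec(4, (60.0, 320.0)),
                                    optics=optics, canvas=(720, 720), seed=9)
        lm = segment(image)
        _, _, summary = apply_size_gate(lm)
        assert summary.n_total == 41
        assert summary.debris_percent == pytest.approx(truth.debris_percent)

    @given(st.lists(st.integers(min_value=30, max_value=900), min_size=1,
                    max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_gate_partition_is_exhaustive(self, areas):
        lm = self._labelmap_with_areas(areas)
        _, _, summary = apply_size_gate(lm)
        assert summary.n_cells + summary.n_debris == summary.n_total == len(areas)

    def test_partition_invariant_enforced(self):
        with pytest.raises(ValueError):
            GateSummary(n_total=3, n_cells=1, n_debris=1)


class TestMeasure:
    def test_hemisphere_sphericity_near_one(self, hemisphere_record):
        record, truth = hemisphere_record
        assert record.sphericity == pytest.approx(1.0, rel=0.02)
        assert truth.sphericity == pytest.approx(1.0)

    def test_zero_image_forced_mask(self, optics):
        image = PhaseImage(np.zeros((32, 32)), optics)
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:20, 10:20] = 1
        rec = measure(image, LabelMap(labels, optics.pixel_size))[0]
        assert rec.dry_mass == 0.0
        assert rec.mean_optical_thickness == 0.0
        assert rec.max_optical_thickness == 0.0

    def test_gaussian_bump_mass_within_half_percent(self):
        spec = CellPhantomSpec("gaussian_bump", (12.0, 9.0), 3.0, dry_mass=12.0)
        record, _ = measure_single(spec)
        assert record.dry_mass == pytest.approx(12.0, rel=0.005)

    def test_ellipsoidal_cap_axis_ratio(self):
        spec = CellPhantomSpec("ellipsoidal_cap", (16.6, 10.0), 5.0,
                               orientation=0.7)
        record, truth = measure_single(spec)
        assert record.length_width_ratio == pytest.approx(1.66, rel=0.02)
        assert truth.length_width_ratio == pytest.approx(1.66)

    def test_flat_cap_sphericity_matches_analytic(self):
        k = cap_ratio_for_sphericity(0.24)
        spec = CellPhantomSpec("spherical_cap", (18.0, 18.0), k * 18.0)
        record, truth = measure_single(spec)
        assert truth.sphericity == pytest.approx(0.24, abs=1e-9)
        assert record.sphericity == pytest.approx(0.24, rel=0.02)

    def test_rotation_invariance_of_shape_metrics(self):
        base = CellPhantomSpec("ellipsoidal_cap", (15.0, 9.0), 4.0)
        rot = CellPhantomSpec("ellipsoidal_cap", (15.0, 9.0), 4.0,
                              orientation=np.radians(37.0))
        r0, _ = measure_single(base)
        r1, _ = measure_single(rot)
        assert r1.length_width_ratio == pytest.approx(r0.length_width_ratio, rel=0.02)
        assert r1.sphericity == pytest.approx(r0.sphericity, rel=0.02)

    def test_mass_conservation_over_field(self, optics):
        cells = [CellPhantomSpec("spherical_cap", (12.0, 12.0), 5.0, dry_mass=20.0)
                 for _ in range(15)]
        image, truth = render_field(cells, None, optics=optics,
                                    canvas=(800, 800), seed=6)
        lm = segment(image)
        records = measure(image, lm)
        assert sum(r.dry_mass for r in records) == pytest.approx(
            truth.total_dry_mass, rel=0.01)

    def test_dry_mass_oracle_on_random_phantoms(self, optics):
        # independent oracle: summation over the full single-phantom raster
        rng = np.random.default_rng(12)
        for _ in range(20):
            model = rng.choice(["spherical_cap", "ellipsoidal_cap", "gaussian_bump"])
            b = rng.uniform(8.0, 14.0)
            a = b * rng.uniform(1.0, 1.8) if model != "spherical_cap" else b
            mass = rng.uniform(5.0, 80.0)
            spec = CellPhantomSpec(model, (a, b), rng.uniform(0.2, 0.8) * b,
                                   orientation=rng.uniform(0, np.pi),
                                   dry_mass=float(mass))
            image, _ = render_cell(spec, optics=optics, canvas=(160, 160))
            oracle = image.opd.sum() * optics.pixel_area / optics.alpha
            record = measure(image, segment(image))[0]
            assert record.dry_mass == pytest.approx(oracle, rel=0.005)
            assert oracle == pytest.approx(mass, abs=1e-9)

    def test_sphericity_monotone_in_height_ratio_at_fixed_volume(self):
        from qpihuvec.geometry import spherical_cap_volume
        v_ref = spherical_cap_volume(15.0, 0.25 * 15.0)
        measured = []
        for k in (0.1, 0.25, 0.5, 1.0):
            # base radius solving V(a, ka) = v_ref
            a = (6.0 * v_ref / (np.pi * k * (3.0 + k * k))) ** (1.0 / 3.0)
            spec = CellPhantomSpec("spherical_cap", (a, a), k * a)
            record, _ = measure_single(spec)
            measured.append(record.sphericity)
        assert all(b > a for a, b in zip(measured, measured[1:]))

    def test_small_object_flagged_unreliable(self, optics):
        image = PhaseImage(np.zeros((16, 16)), optics)
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[5, 5:7] = 1
        rec = measure(image, LabelMap(labels, optics.pixel_size))[0]
        assert rec.unreliable

    def test_border_object_flagged(self, optics):
        image = PhaseImage(np.zeros((16, 16)), optics)
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[0:4, 0:4] = 1
        rec = measure(image, LabelMap(labels, optics.pixel_size))[0]
        assert rec.touches_border

    def test_shape_mismatch_rejected(self, optics):
        image = PhaseImage(np.zeros((16, 16)), optics)
        with pytest.raises(ValueError, match="shape"):
            measure(image, LabelMap(np.zeros((8, 8), dtype=np.int32), 0.5))


class TestFluorescence:
    @pytest.fixture()
    def masked(self, optics):
        image = PhaseImage(np.zeros((32, 32)), optics)
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[4:14, 4:14] = 1
        lm = LabelMap(labels, optics.pixel_size)
        records = measure(image, lm)
        return records, lm

    def test_uniform_subthreshold_reads_zero(self, masked):
        records, lm = masked
        out = pair_fluorescence(records, lm, np.full((32, 32), 49.0))
        assert out[0].fluorescence_mean == 0.0

    def test_uniform_suprathreshold_reads_itself(self, masked):
        records, lm = masked
        out = pair_fluorescence(records, lm, np.full((32, 32), 200.0))
        assert out[0].fluorescence_mean == pytest.approx(200.0)

    def test_half_and_half_averages(self, masked):
        records, lm = masked
        fluor = np.zeros((32, 32))
        fluor[4:9, :] = 100.0  # upper half of the object
        out = pair_fluorescence(records, lm, fluor)
        assert out[0].fluorescence_mean == pytest.approx(50.0)

    def test_dimension_mismatch_names_shapes(self, masked):
        records, lm = masked
        with pytest.raises(ValueError, match=r"\(16, 16\).*\(32, 32\)"):
            pair_fluorescence(records, lm, np.zeros((16, 16)))


class TestSphericitySplit:
    def _records(self, sph_fluor_pairs):
        from qpihuvec.morphometry import CellRecord
        return [CellRecord(object_id=i + 1, area=500.0, dry_mass=1.0,
                           mean_optical_thickness=0.1, max_optical_thickness=0.2,
                           sphericity=s, length_width_ratio=1.5,
                           centroid=(0.0, 0.0), fluorescence_mean=f)
                for i, (s, f) in enumerate(sph_fluor_pairs)]

    def test_two_groups_means(self):
        low, high = split_by_sphericity(self._records([(0.20, 10.0), (0.30, 90.0)]))
        assert (low.n, low.mean_fluorescence) == (1, 10.0)
        assert (high.n, high.mean_fluorescence) == (1, 90.0)

    def test_empty_high_group_flagged(self):
        low, high = split_by_sphericity(self._records([(0.1, 5.0), (0.2, 7.0)]))
        assert low.n == 2
        assert high.n == 0 and high.empty

    def test_group_fluorescence_ratio_recovers_generator_contrast(self):
        rng = np.random.default_rng(3)
        pairs = [(0.15, rng.normal(20.0, 1.0)) for _ in range(50)]
        pairs += [(0.35, rng.normal(100.0, 5.0)) for _ in range(50)]
        low, high = split_by_sphericity(self._records(pairs))
        assert high.mean_fluorescence / low.mean_fluorescence == pytest.approx(
            5.0, rel=0.1)
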