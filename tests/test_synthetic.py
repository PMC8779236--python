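"""Tests for the synthetic layout generator, manipulation, and rendering."""

import numpy as np
import pytest

from titinafm import (
    Blob,
    Filament,
    HeightMap,
    LayoutConfig,
    ManipulationEvent,
    MoleculeLayout,
    ScanArtifacts,
    ThinPlateParams,
    add_scan_artifacts,
    apply_manipulation,
    cap_volume,
    generate_layout,
    make_scan_pair,
    render_true_surface,
)
from titinafm.exceptions import LayoutError
from titinafm.models import eval_thin_plate
from titinafm.synthetic import cap_support_radius


class TestGenerateLayout:
    def test_filament_count_and_attachment(self):
        cfg = LayoutConfig(n_blobs=1, n_filaments=6)
        layout = generate_layout(cfg, seed=42)
        assert len(layout.filaments) == 6
        center = np.array(layout.blobs[0].center)
        for fil in layout.filaments:
            assert np.hypot(*(fil.points[0] - center)) < 1e-9

    def test_array_spacing_without_jitter(self):
        cfg = LayoutConfig(n_blobs=4, blob_spacing_mean=30.0,
                           blob_spacing_sd=0.0, n_filaments=0)
        layout = generate_layout(cfg, seed=0)
        xs = np.array([b.center[0] for b in layout.blobs])
        assert np.allclose(np.diff(np.sort(xs)), 30.0)

    def test_array_gap_distribution_matches_configured_mean(self):
        # 20 gaps ~ N(29.37, 7.12): sample mean within 3 SEM of the mean
        cfg = LayoutConfig(field_size=(1000.0, 400.0), n_blobs=21,
                           blob_spacing_mean=29.37, blob_spacing_sd=7.12,
                           blob_radius=10.0, n_filaments=0)
        layout = generate_layout(cfg, seed=7)
        xs = np.sort([b.center[0] for b in layout.blobs])
        gaps = np.diff(xs)
        assert len(gaps) == 20
        assert abs(gaps.mean() - 29.37) <= 3 * 7.12 / np.sqrt(20)

    def test_seed_reproducibility(self):
        cfg = LayoutConfig(n_blobs=3, n_filaments=5, blob_peak_sd=0.5)
        a = generate_layout(cfg, seed=11)
        b = generate_layout(cfg, seed=11)
        for fa, fb in zip(a.filaments, b.filaments):
            np.testing.assert_array_equal(fa.points, fb.points)
        assert [x.peak_height for x in a.blobs] == [x.peak_height for x in b.blobs]

    def test_infeasible_geometry_raises(self):
        cfg = LayoutConfig(field_size=(100.0, 100.0), n_blobs=10,
                           blob_spacing_mean=50.0, blob_spacing_sd=0.0)
        with pytest.raises(LayoutError):
            generate_layout(cfg, seed=0)

    def test_oriented_mode_filaments_are_parallel(self):
        cfg = LayoutConfig(n_filaments=4, oriented=True, orientation_deg=0.0,
                           filament_spacing_sd=0.0)
        layout = generate_layout(cfg, seed=3)
        for fil in layout.filaments:
            d = fil.points[-1] - fil.points[0]
            assert abs(d[1]) < 1e-9  # horizontal


class TestApplyManipulation:
    def _layout(self):
        return MoleculeLayout(
            field_size=(400.0, 400.0),
            filaments=[Filament(points=np.array([[50.0, 200.0], [350.0, 200.0]]),
                                tube_radius=3.0, peak_height=0.3)],
        )

    def test_zero_distance_is_identity(self):
        layout = self._layout()
        event = ManipulationEvent(start_xy=(200.0, 200.0),
                                  direction=(0.0, 1.0), distance=0.0)
        out = apply_manipulation(layout, event)
        assert len(out.filaments) == 1
        np.testing.assert_array_equal(out.filaments[0].points,
                                      layout.filaments[0].points)

    def test_loop_apex_displacement_matches_model(self):
        layout = self._layout()
        params = ThinPlateParams(k=10.0, r0=60.0, d=7.0)
        event = ManipulationEvent(start_xy=(200.0, 200.0),
                                  direction=(0.0, 1.0), distance=100.0,
                                  loop_params=params,
                                  strand_height_after=0.2)
        out = apply_manipulation(layout, event, sample_step=1.0)
        strands = [f for f in out.filaments if f.peak_height == 0.2]
        assert len(strands) == 2
        apex_y = max(f.points[:, 1].max() for f in strands)
        # innermost sampled arc offset
        n = int(np.floor((params.r0 - params.d) / 1.0))
        r_inner = params.d + (params.r0 - params.d) / n
        expected = 200.0 + eval_thin_plate(params, r_inner)
        assert apex_y == pytest.approx(expected, abs=1e-9)

    def test_untargeted_portion_conserved_exactly(self):
        layout = self._layout()
        layout.filaments.append(
            Filament(points=np.array([[50.0, 100.0], [350.0, 100.0]]),
                     tube_radius=3.0, peak_height=0.3))
        params = ThinPlateParams(k=10.0, r0=40.0, d=7.0)
        event = ManipulationEvent(start_xy=(200.0, 200.0),
                                  direction=(0.0, 1.0), distance=100.0,
                                  loop_params=params)
        out = apply_manipulation(layout, event)
        untouched = [f for f in out.filaments
                     if np.allclose(f.points[0, 1], 100.0)]
        assert len(untouched) == 1
        np.testing.assert_array_equal(untouched[0].points,
                                      layout.filaments[1].points)
        # remaining segments of the targeted filament keep the original line
        stubs = [f for f in out.filaments
                 if f.peak_height == 0.3 and np.allclose(f.points[:, 1], 200.0)]
        assert len(stubs) == 2
        ends = sorted(s.points[:, 0].max() for s in stubs)
        assert ends[0] == pytest.approx(200.0 - 40.0)

    def test_loop_beyond_field_raises(self):
        layout = self._layout()
        params = ThinPlateParams(k=100.0, r0=60.0, d=7.0)  # huge displacement
        event = ManipulationEvent(start_xy=(200.0, 200.0),
                                  direction=(0.0, 1.0), distance=300.0,
                                  loop_params=params)
        with pytest.raises(LayoutError, match="field"):
            apply_manipulation(layout, event)

    def test_event_off_molecule_raises(self):
        layout = self._layout()
        event = ManipulationEvent(start_xy=(200.0, 50.0),
                                  direction=(0.0, 1.0), distance=50.0,
                                  loop_params=ThinPlateParams(k=5, r0=30, d=7))
        with pytest.raises(LayoutError, match="not on or near"):
            apply_manipulation(layout, event)

    def test_blob_volume_increment_rendered(self):
        """A slow drag through an M-complex grows its rendered volume by
        the prescribed increment (within discretization)."""
        layout = MoleculeLayout(
            field_size=(200.0, 200.0),
            blobs=[Blob(center=(100.0, 100.0), radius=20.0, peak_height=16.6)],
        )
        event = ManipulationEvent(start_xy=(100.0, 100.0),
                                  direction=(1.0, 0.0), distance=100.0,
                                  speed_class="slow", volume_increment=3300.0)
        after = apply_manipulation(layout, event)
        px = 0.5
        v0 = render_true_surface(layout, px).heights.sum() * px**2
        v1 = render_true_surface(after, px).heights.sum() * px**2
        assert v1 - v0 == pytest.approx(3300.0, rel=0.02)

    def test_invalid_distance_rejected(self):
        with pytest.raises(LayoutError, match="distance"):
            ManipulationEvent(start_xy=(0, 0), direction=(1, 0), distance=5.0)


class TestRenderTrueSurface:
    def test_empty_layout_renders_zero(self):
        layout = MoleculeLayout(field_size=(100.0, 100.0))
        img = render_true_surface(layout, 2.0)
        assert np.all(img.heights == 0)

    def test_cap_peak_and_support_diameter(self):
        R, h = 10.0, 5.0
        layout = MoleculeLayout(
            field_size=(100.0, 100.0),
            blobs=[Blob(center=(50.0, 50.0), radius=R, peak_height=h)],
        )
        img = render_true_surface(layout, 0.5)
        assert img.heights.max() == pytest.approx(h, abs=1e-12)
        row = img.heights[100, :]  # row through the centre (y = 50 nm)
        support = np.nonzero(row > 0)[0]
        measured = (support[-1] - support[0]) * 0.5
        expected = 2 * np.sqrt(R**2 - (R - h) ** 2)
        assert measured == pytest.approx(expected, abs=1.0)

    def test_overlapping_blobs_combine_by_max(self):
        blobs = [Blob(center=(50.0, 50.0), radius=10.0, peak_height=5.0),
                 Blob(center=(54.0, 50.0), radius=10.0, peak_height=5.0)]
        both = render_true_surface(
            MoleculeLayout(field_size=(100.0, 100.0), blobs=blobs), 1.0)
        singles = [render_true_surface(
            MoleculeLayout(field_size=(100.0, 100.0), blobs=[b]), 1.0)
            for b in blobs]
        np.testing.assert_array_equal(
            both.heights, np.maximum(singles[0].heights, singles[1].heights))
        assert both.heights.max() == pytest.approx(5.0)

    @pytest.mark.parametrize("px,tol", [(2.0, 0.05), (1.0, 0.02), (0.5, 0.01)])
    def test_blob_volume_converges_to_cap_volume(self, px, tol):
        R, h = 20.0, 16.6
        layout = MoleculeLayout(
            field_size=(200.0, 200.0),
            blobs=[Blob(center=(100.0, 100.0), radius=R, peak_height=h)],
        )
        img = render_true_surface(layout, px)
        v = img.heights.sum() * px**2
        assert v == pytest.approx(cap_volume(R, h), rel=tol)

    def test_cap_support_radius_closed_form(self):
        assert cap_support_radius(10.0, 5.0) == pytest.approx(np.sqrt(75))

    def test_bad_pixel_size_raises(self):
        layout = MoleculeLayout(field_size=(100.0, 100.0))
        with pytest.raises(LayoutError):
            render_true_surface(layout, 0.0)


class TestScanArtifacts:
    def test_identity_artifacts(self, single_blob_layout):
        img = render_true_surface(single_blob_layout, 2.0)
        out = add_scan_artifacts(img, ScanArtifacts())
        np.testing.assert_array_equal(out.heights, img.heights)

    def test_gain_scales_exactly(self, single_blob_layout):
        img = render_true_surface(single_blob_layout, 2.0)
        out = add_scan_artifacts(img, ScanArtifacts(gain=1.1))
        np.testing.assert_array_equal(out.heights, img.heights * 1.1)

    def test_seeded_noise_is_reproducible(self, flat_map):
        art = ScanArtifacts(noise_sd=0.05, per_line_tilt_sd=0.1, seed=99)
        a = add_scan_artifacts(flat_map, art)
        b = add_scan_artifacts(flat_map, art)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_invalid_gain_rejected(self):
        with pytest.raises(LayoutError):
            ScanArtifacts(gain=0.0)


class TestMakeScanPair:
    def test_identical_inputs_identical_images(self, single_blob_layout):
        art = ScanArtifacts(noise_sd=0.05, seed=4)
        a1, a2, *_ = make_scan_pair(single_blob_layout, single_blob_layout,
                                    art, art, pixel_size=2.0, tip_radius=7.0)
        np.testing.assert_array_equal(a1.heights, a2.heights)

    def test_reference_volume_ratio_equals_gain_ratio(self, single_blob_layout):
        """An unmanipulated object's uncorrected volume ratio between scans
        reflects the inter-scan gain (analytic under linear scaling)."""
        g1, g2 = 1.0, 1.2
        im1, im2, *_ = make_scan_pair(
            single_blob_layout, single_blob_layout,
            ScanArtifacts(gain=g1), ScanArtifacts(gain=g2),
            pixel_size=2.0, tip_radius=7.0)
        v1 = im1.heights.sum()
        v2 = im2.heights.sum()
        assert v2 / v1 == pytest.approx(g2 / g1, rel=1e-12)

    def test_mismatched_fields_raise(self, single_blob_layout):
        other = MoleculeLayout(field_size=(300.0, 300.0))
        with pytest.raises(LayoutError, match="mismatched"):
            make_scan_pair(single_blob_layout, other,
                           ScanArtifacts(), ScanArtifacts())
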