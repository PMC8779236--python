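"""Filament metrics: contour length, spacings, strain, decay, necking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titinafm import (Blob, CrossSection, Filament, HeightMap, LayoutConfig,
                      MoleculeLayout, SigmoidModel, SigmoidParams,
                      TracePolyline, axial_height_decay, contour_length,
                      dilate_with_tip, generate_layout, neck_profile,
                      peak_spacings, render_true_surface, strain)
from titinafm.exceptions import DomainError
from titinafm.filament import fit_top_hat
from titinafm.models import eval_sigmoid


class TestContourLength:
    def test_straight_segment(self):
        assert contour_length([[0, 0], [0, 100]]) == pytest.approx(100.0)

    def test_closed_square(self):
        square = [[0, 0], [50, 0], [50, 50], [0, 50], [0, 0]]
        assert contour_length(square) == pytest.approx(200.0)

    def test_matches_generator_bookkeeping(self):
        layout = generate_layout(LayoutConfig(n_filaments=4), seed=9)
        for fil in layout.filaments:
            assert contour_length(fil.points) == pytest.approx(
                fil.arc_length, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50),
           dy=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, angle, dx, dy):
        pts = np.array([[0.0, 0.0], [30.0, 10.0], [60.0, -5.0], [90.0, 0.0]])
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T + [dx, dy]
        assert contour_length(moved) == pytest.approx(contour_length(pts),
                                                      rel=1e-9)


class TestPeakSpacings:
    def _comb(self, spacing=30.0, n_peaks=8, step=1.0):
        x = np.arange(0, spacing * (n_peaks + 1), step)
        h = np.zeros_like(x)
        for k in range(1, n_peaks + 1):
            h += 2.0 * np.exp(-((x - k * spacing) ** 2) / (2 * 3.0**2))
        return CrossSection(arc_positions=x, heights=h)

    def test_equal_comb_recovers_spacing(self):
        stats = peak_spacings(self._comb(30.0), min_prominence=0.3,
                              min_separation=10.0)
        assert stats.n == 7
        assert stats.mean == pytest.approx(30.0, abs=0.01)
        assert stats.sd == pytest.approx(0.0, abs=0.01)

    def test_constant_offset_invariance(self):
        prof = self._comb(25.0)
        shifted = CrossSection(arc_positions=prof.arc_positions,
                               heights=prof.heights + 5.0)
        a = peak_spacings(prof)
        b = peak_spacings(shifted)
        np.testing.assert_array_equal(a.peak_positions, b.peak_positions)

    def test_monotone_profile_has_no_gaps(self):
        prof = CrossSection(arc_positions=np.arange(0, 100.0),
                            heights=np.linspace(0, 5, 100))
        stats = peak_spacings(prof)
        assert stats.n == 0
        assert np.isnan(stats.mean)

    def test_short_profile_rejected(self):
        prof = CrossSection(arc_positions=np.arange(0, 15.0),
                            heights=np.zeros(15))
        with pytest.raises(DomainError, match="span"):
            peak_spacings(prof, min_separation=10.0)

    def test_rendered_array_recovery(self):
        """Blob-array gaps drawn N(29.37, 7.12) recovered from the rendered,
        tip-dilated image within 3 SEM."""
        cfg = LayoutConfig(field_size=(1000.0, 300.0), n_blobs=21,
                           blob_spacing_mean=29.37, blob_spacing_sd=7.12,
                           blob_radius=10.0, blob_peak_mean=4.4,
                           n_filaments=0)
        layout = generate_layout(cfg, seed=21)
        img = dilate_with_tip(render_true_surface(layout, 2.0), 7.0)
        y = layout.blobs[0].center[1]
        from titinafm import extract_profile

        prof = extract_profile(img, [[100.0, y], [900.0, y]])
        stats = peak_spacings(prof, min_prominence=0.3, min_separation=10.0)
        assert stats.n >= 18  # nearly all gaps resolved
        assert abs(stats.mean - 29.37) <= 3 * 7.12 / np.sqrt(20)


class TestStrain:
    @pytest.mark.parametrize("L0,L1,L2,expected", [
        (65.0, 130.0, 130.0, 4.0),   # slow manipulation regime
        (50.0, 150.0, 150.0, 6.0),   # fast manipulation regime
        (80.0, 40.0, 40.0, 1.0),     # unstretched two-strand limit
    ])
    def test_reference_values(self, L0, L1, L2, expected):
        assert strain(L0, L1, L2).strain == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.01, 100), L0=st.floats(1, 200), L1=st.floats(1, 400),
           L2=st.floats(1, 400))
    def test_scale_invariance(self, a, L0, L1, L2):
        assert strain(a * L0, a * L1, a * L2).strain == pytest.approx(
            strain(L0, L1, L2).strain, rel=1e-9)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(DomainError):
            strain(0.0, 10.0, 10.0)


class TestAxialHeightDecay:
    def test_constant_ridge_gives_flat_series(self):
        layout = MoleculeLayout(
            field_size=(300.0, 100.0),
            filaments=[Filament(points=np.array([[20.0, 50.0], [280.0, 50.0]]),
                                tube_radius=4.0, peak_height=2.0)],
        )
        img = render_true_surface(layout, 1.0)
        series = axial_height_decay(
            img, TracePolyline(np.array([[30.0, 50.0], [270.0, 50.0]])))
        np.testing.assert_allclose(series.heights, 2.0, atol=0.02)
        assert np.all(np.diff(series.arc_positions) > 0)

    def test_sigmoid_ground_truth_recovered(self):
        """Strand with a sigmoid axial height renders and fits back to the
        generating parameters within 5% (noiseless)."""
        true = SigmoidParams(B=0.2, T=4.0, half_height=120.0, S=3.0)
        arcs = np.linspace(0.0, 300.0, 301)
        heights = eval_sigmoid(true, arcs)
        pts = np.column_stack([arcs + 30.0, np.full_like(arcs, 50.0)])
        layout = MoleculeLayout(
            field_size=(400.0, 100.0),
            filaments=[Filament(points=pts, tube_radius=4.0,
                                peak_height=4.0, axial_heights=heights)],
        )
        img = render_true_surface(layout, 1.0)
        series = axial_height_decay(
            img, TracePolyline(np.array([[30.0, 50.0], [330.0, 50.0]])),
            origin_xy=(30.0, 50.0))
        fit = SigmoidModel(series.arc_positions, series.heights).fit()
        assert fit.params_dict["B"] == pytest.approx(0.2, rel=0.05)
        assert fit.params_dict["T"] == pytest.approx(4.0, rel=0.05)
        assert fit.params_dict["half_height"] == pytest.approx(120.0, rel=0.05)
        assert fit.params_dict["S"] == pytest.approx(3.0, rel=0.05)
        assert fit.r2 > 0.95

    def test_origin_orients_the_series(self):
        layout = MoleculeLayout(
            field_size=(300.0, 100.0),
            filaments=[Filament(points=np.array([[20.0, 50.0], [280.0, 50.0]]),
                                tube_radius=4.0, peak_height=2.0)],
        )
        img = render_true_surface(layout, 1.0)
        trace = TracePolyline(np.array([[270.0, 50.0], [30.0, 50.0]]))
        series = axial_height_decay(img, trace, origin_xy=(30.0, 50.0))
        assert np.all(np.diff(series.arc_positions) > 0)


class TestNeckProfile:
    def _strand_map(self, width_profile):
        """Rectangular-cross-section ridge along x with axially varying
        half-width; built directly on the pixel grid."""
        px = 1.0
        z = np.zeros((80, 200))
        xs = np.arange(200) * px
        for j, x in enumerate(xs):
            half_w = width_profile(x) / 2
            if half_w <= 0:
                continue
            lo = int(np.ceil((40.0 - half_w) / px))
            hi = int(np.floor((40.0 + half_w) / px))
            z[lo:hi + 1, j] = 2.0
        return HeightMap(z, px)

    def test_uniform_rectangular_strand(self):
        img = self._strand_map(lambda x: 10.0)
        trace = TracePolyline(np.array([[20.0, 40.0], [180.0, 40.0]]))
        prof = neck_profile(img, trace, station_step=8.0, cross_length=40.0)
        assert np.all(~prof.degenerate)
        np.testing.assert_allclose(prof.height, 2.0, atol=0.05)
        np.testing.assert_allclose(prof.width, 10.0, atol=1.5)

    def test_necked_strand_width_dips_mid_span(self):
        def width(x):  # 12 nm wide, thinning to 4 nm at mid-span
            return 12.0 - 8.0 * np.exp(-((x - 100.0) ** 2) / (2 * 20.0**2))

        img = self._strand_map(width)
        trace = TracePolyline(np.array([[20.0, 40.0], [180.0, 40.0]]))
        prof = neck_profile(img, trace, station_step=8.0, cross_length=40.0)
        mid = np.argmin(np.abs(prof.axial_position - 80.0))
        assert prof.width[mid] == pytest.approx(
            prof.width.min(), abs=1e-9)
        assert prof.width.min() < 0.6 * prof.width.max()

    def test_flat_background_is_degenerate(self):
        img = HeightMap(np.zeros((60, 60)), 1.0)
        trace = TracePolyline(np.array([[10.0, 30.0], [50.0, 30.0]]))
        prof = neck_profile(img, trace, station_step=10.0, cross_length=30.0)
        assert np.all(prof.degenerate)
        np.testing.assert_array_equal(prof.height, 0.0)
        np.testing.assert_array_equal(prof.width, 0.0)

    def test_station_outside_map_skipped_with_warning(self):
        img = self._strand_map(lambda x: 10.0)
        trace = TracePolyline(np.array([[20.0, 40.0], [180.0, 40.0]]))
        with pytest.warns(UserWarning, match="skipped"):
            prof = neck_profile(img, trace, station_step=8.0,
                                cross_length=200.0)
        assert len(prof.axial_position) == 0

    def test_width_monotone_under_tip_dilation(self):
        layout = MoleculeLayout(
            field_size=(200.0, 80.0),
            filaments=[Filament(points=np.array([[20.0, 40.0], [180.0, 40.0]]),
                                tube_radius=5.0, peak_height=3.0)],
        )
        img = render_true_surface(layout, 1.0)
        trace = TracePolyline(np.array([[40.0, 40.0], [160.0, 40.0]]))
        prev = None
        for radius in (0.0, 4.0, 8.0):
            prof = neck_profile(dilate_with_tip(img, radius), trace,
                                station_step=20.0, cross_length=60.0)
            mean_w = prof.width.mean()
            if prev is not None:
                assert mean_w >= prev - 1e-9
            prev = mean_w


class TestFitTopHat:
    def test_exact_top_hat_recovered(self):
        x = np.arange(0, 40.0)
        h = np.where(np.abs(x - 20.0) <= 5.0, 2.0, 0.0)
        c, W, H, degen = fit_top_hat(x, h)
        assert not degen
        assert H == pytest.approx(2.0)
        assert c == pytest.approx(20.0, abs=0.5)
        assert W == pytest.approx(10.0, abs=1.0)
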