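import numpy as np
import pytest

from octlumen.frame_io import CalibrationSpec
from octlumen.lumen_segmentation import (EXTREMA_NAMES, IncompleteSegmentationError,
                                         MorphologyParams, NoTissueError,
                                         bridge_gaps, extract_border,
                                         filter_small_components, open_close,
                                         trace_components)


def brute_force_open_close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Independent Minkowski-operation oracle: erosion scans every footprint
    offset with the image edge treated as foreground, dilation with the
    edge treated as background."""
    from skimage.morphology import disk

    fp = disk(radius).astype(bool)
    r = radius

    def erode(m):
        p = np.pad(m, r, constant_values=True)
        out = np.ones_like(m)
        for dr in range(-r, r + 1):
            for dc in range(-r, r + 1):
                if fp[dr + r, dc + r]:
                    out &= p[r + dr:r + dr + m.shape[0], r + dc:r + dc + m.shape[1]]
        return out

    def dilate(m):
        p = np.pad(m, r, constant_values=False)
        out = np.zeros_like(m)
        for dr in range(-r, r + 1):
            for dc in range(-r, r + 1):
                if fp[dr + r, dc + r]:
                    out |= p[r + dr:r + dr + m.shape[0], r + dc:r + dc + m.shape[1]]
        return out

    opened = dilate(erode(mask))
    return erode(dilate(opened))


def ring_mask(n_ang=360, n_rad=255, r0=150, thickness=35, gaps=()):
    """Rasterized intima band with angular gaps (start_deg, width_deg)."""
    mask = np.zeros((n_ang, n_rad), bool)
    for a in range(n_ang):
        if any(abs(((a - center + 180) % 360) - 180) < width / 2
               for center, width in gaps):
            continue
        mask[a, r0:r0 + thickness] = True
    return mask


class TestOpenClose:
    def test_small_square_removed(self):
        mask = np.zeros((30, 30), bool)
        mask[10:13, 10:13] = True
        assert not open_close(mask, MorphologyParams(5)).any()

    def test_hole_filled_shape_preserved(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        holed = mask.copy()
        holed[30:33, 30:33] = False
        out = open_close(holed, MorphologyParams(5))
        assert out[30:33, 30:33].all()  # hole filled
        assert out[15:45, 15:45].all()  # interior intact
        assert not out[:8].any()  # nothing leaks outward

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_minkowski_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndimage_smooth_noise(rng)
        assert np.array_equal(open_close(mask, MorphologyParams(5)),
                              brute_force_open_close(mask, 5))

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        mask = ndimage_smooth_noise(rng)
        once = open_close(mask, MorphologyParams(5))
        assert np.array_equal(open_close(once, MorphologyParams(5)), once)


def ndimage_smooth_noise(rng, shape=(64, 64)):
    from scipy import ndimage
    return ndimage.gaussian_filter(rng.random(shape), 2) > 0.5


class TestTraceComponents:
    def test_rectangle_extrema_collapse_to_corners(self):
        mask = np.zeros((20, 20), bool)
        mask[5:11, 3:15] = True
        (comp,) = trace_components(mask)
        e = comp.extrema
        assert e["top_left"] == e["left_top"] == (5, 3)
        assert e["top_right"] == e["right_top"] == (5, 14)
        assert e["bottom_right"] == e["right_bottom"] == (10, 14)
        assert e["bottom_left"] == e["left_bottom"] == (10, 3)

    def test_components_ordered_top_to_bottom(self):
        mask = np.zeros((30, 30), bool)
        mask[20:25, 2:8] = True
        mask[2:6, 10:20] = True
        comps = trace_components(mask)
        assert [c.top_row for c in comps] == [2, 20]

    def test_l_shape_extrema_match_exhaustive_search(self):
        mask = np.zeros((30, 30), bool)
        mask[5:20, 5:10] = True
        mask[15:20, 5:25] = True
        (comp,) = trace_components(mask)
        rows, cols = np.nonzero(mask)

        def brute(primary, pmin, secondary, smin):
            pv = primary.min() if pmin else primary.max()
            sel = primary == pv
            sv = secondary[sel].min() if smin else secondary[sel].max()
            i = np.flatnonzero(sel & (secondary == sv))[0]
            return (rows[i], cols[i])

        expected = {
            "top_left": brute(rows, True, cols, True),
            "top_right": brute(rows, True, cols, False),
            "right_top": brute(cols, False, rows, True),
            "right_bottom": brute(cols, False, rows, False),
            "bottom_right": brute(rows, False, cols, False),
            "bottom_left": brute(rows, False, cols, True),
            "left_bottom": brute(cols, True, rows, False),
            "left_top": brute(cols, True, rows, True),
        }
        assert comp.extrema == expected

    def test_boundary_chain_closed_and_8_connected(self):
        mask = np.zeros((30, 30), bool)
        mask[5:20, 5:10] = True
        mask[15:20, 5:25] = True
        (comp,) = trace_components(mask)
        chain = np.array(comp.boundary)
        steps = np.abs(np.diff(np.vstack([chain, chain[:1]]), axis=0))
        assert steps.max() <= 1  # 8-connected incl. closure
        # extrema lie on the traced boundary
        boundary_set = {tuple(p) for p in comp.boundary}
        for name in EXTREMA_NAMES:
            assert comp.extrema[name] in boundary_set

    def test_empty_mask_rejected(self):
        with pytest.raises(NoTissueError):
            trace_components(np.zeros((10, 10), bool))


class TestBridgeGaps:
    calibration = CalibrationSpec(pixel_spacing_mm=0.01)

    def test_full_height_component_unchanged(self):
        mask = ring_mask()
        (comp,) = trace_components(mask)
        out, bridges = bridge_gaps([comp], mask, self.calibration)
        assert np.array_equal(out, mask)
        assert bridges == []

    def test_aligned_gap_bridged_vertically(self):
        mask = np.zeros((60, 40), bool)
        mask[0:20, 10:20] = True
        mask[30:60, 10:20] = True
        comps = trace_components(mask)
        out, bridges = bridge_gaps(comps, mask, self.calibration)
        assert len(bridges) == 2  # interior gap + angular wrap seam
        assert out[20:30, 10].all()  # vertical connecting segment
        from skimage.measure import label
        assert label(out, connectivity=2).max() == 1

    def test_bifurcation_chord_length_from_phantom_geometry(self):
        # 30 deg wedge at radius 1.5 mm: chord = 2 * 1.5 * sin(15 deg)
        mask = ring_mask(gaps=[(90, 30)])
        comps = trace_components(mask)
        out, bridges = bridge_gaps(comps, mask, self.calibration)
        gap = max(b.gap_length_mm for b in bridges)
        expected = 2 * 1.5 * np.sin(np.radians(15))
        assert abs(gap - expected) <= 2 * 0.01  # within 2 radial bins
        assert not any(b.is_bifurcation for b in bridges)  # 0.78 mm < 2 mm

    def test_wide_gap_flagged_as_bifurcation(self):
        # 90 deg wedge at 1.5 mm: chord = 2 * 1.5 * sin(45 deg) = 2.12 mm
        mask = ring_mask(gaps=[(180, 90)])
        comps = trace_components(mask)
        _, bridges = bridge_gaps(comps, mask, self.calibration)
        assert any(b.is_bifurcation for b in bridges)

    def test_gap_across_angular_wraparound(self):
        mask = ring_mask(gaps=[(0, 20)])  # wedge straddles row 0
        comps = trace_components(mask)
        out, _ = bridge_gaps(comps, mask, self.calibration)
        assert out.any(axis=1).all()  # every A-line reconnected
        from skimage.measure import label
        assert label(out, connectivity=2).max() <= 2  # seam may stay split in-array

    def test_bridging_only_adds_foreground(self):
        mask = ring_mask(gaps=[(45, 25), (200, 40)])
        comps = trace_components(mask)
        out, _ = bridge_gaps(comps, mask, self.calibration)
        assert (out & ~mask).sum() > 0
        assert not (mask & ~out).any()


class TestExtractBorder:
    def test_straight_border(self):
        mask = np.zeros((90, 120), bool)
        mask[:, 50:] = True
        contour = extract_border(mask)
        assert contour.all_valid
        assert np.abs(contour.radius_per_angle - 50).max() <= 1

    def test_sine_wave_border_recovered(self):
        n_ang, n_rad = 360, 200
        rows = np.arange(n_ang)
        wave = 100 + 30 * np.sin(2 * np.pi * rows / n_ang * 3)
        mask = np.zeros((n_ang, n_rad), bool)
        for a in rows:
            mask[a, int(round(wave[a])):] = True
        contour = extract_border(mask)
        assert np.abs(contour.radius_per_angle - np.round(wave)).max() <= 1

    def test_innermost_edge_of_nested_rings(self):
        mask = np.zeros((60, 120), bool)
        mask[:, 40:55] = True
        mask[:, 80:95] = True
        contour = extract_border(mask)
        assert np.abs(contour.radius_per_angle - 40).max() <= 1

    def test_outer_foreground_does_not_move_border(self):
        mask = np.zeros((60, 120), bool)
        mask[:, 40:55] = True
        augmented = mask.copy()
        augmented[:, 100:110] = True  # beyond existing foreground + Sobel support
        assert np.array_equal(extract_border(mask).radius_per_angle,
                              extract_border(augmented).radius_per_angle)

    def test_missing_rows_rejected(self):
        mask = np.zeros((60, 120), bool)
        mask[:30, 40:55] = True
        with pytest.raises(IncompleteSegmentationError):
            extract_border(mask)


def test_filter_small_components_drops_clutter():
    mask = np.zeros((40, 40), bool)
    mask[5:30, 10:20] = True  # 250 px component
    mask[35:38, 30:33] = True  # 9 px blob
    out = filter_small_components(mask, min_area=81)
    assert out[5:30, 10:20].all()
    assert not out[35:38, 30:33].any()
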