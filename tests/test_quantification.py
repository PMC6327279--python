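import numpy as np
import pytest

from octlumen.quantification import (LumenMetrics, absolute_relative_difference,
                                     bland_altman, compare_series, icc,
                                     lumen_metrics, relative_difference)


def circle_contour(r=1.5, n=360, cx=0.0, cy=0.0):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def ellipse_contour(a=2.0, b=1.0, n=720):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def rectangle_contour(w=2.0, h=1.0, pts_per_edge=50):
    xs = np.linspace(-w / 2, w / 2, pts_per_edge, endpoint=False)
    ys = np.linspace(-h / 2, h / 2, pts_per_edge, endpoint=False)
    bottom = np.column_stack([xs, np.full_like(xs, -h / 2)])
    right = np.column_stack([np.full_like(ys, w / 2), ys])
    top = np.column_stack([-xs, np.full_like(xs, h / 2)])
    left = np.column_stack([np.full_like(ys, -w / 2), -ys])
    return np.vstack([bottom, right, top, left])


class TestLumenMetrics:
    def test_circle_closed_forms(self):
        m = lumen_metrics(circle_contour(1.5), n_rays=180)
        assert m.area_mm2 == pytest.approx(np.pi * 1.5 ** 2, rel=1e-3)
        for d in (m.mean_diameter_mm, m.min_diameter_mm, m.max_diameter_mm):
            assert d == pytest.approx(3.0, rel=1e-3)

    def test_ellipse_closed_forms(self):
        m = lumen_metrics(ellipse_contour(2.0, 1.0), n_rays=720)
        assert m.area_mm2 == pytest.approx(2 * np.pi, rel=2e-3)
        assert m.min_diameter_mm == pytest.approx(2.0, rel=5e-3)
        assert m.max_diameter_mm == pytest.approx(4.0, rel=5e-3)

    def test_rectangle_area_and_chords(self):
        m = lumen_metrics(rectangle_contour(2.0, 1.0), n_rays=720)
        assert m.area_mm2 == pytest.approx(2.0, rel=1e-6)
        assert m.min_diameter_mm == pytest.approx(1.0, rel=5e-3)
        assert m.max_diameter_mm == pytest.approx(np.sqrt(5.0), rel=5e-3)

    def test_rotation_invariant_within_discretization(self):
        pts = ellipse_contour(1.8, 1.2, n=720)
        ang = 0.37
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        m0 = lumen_metrics(pts, n_rays=360)
        m1 = lumen_metrics(pts @ rot.T, n_rays=360)
        assert m1.area_mm2 == pytest.approx(m0.area_mm2, rel=1e-9)
        assert m1.min_diameter_mm == pytest.approx(m0.min_diameter_mm, rel=2e-3)
        assert m1.max_diameter_mm == pytest.approx(m0.max_diameter_mm, rel=2e-3)
        assert m1.mean_diameter_mm == pytest.approx(m0.mean_diameter_mm, rel=2e-3)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2],
                           [0, 0.1], [1.9, 2], [1.9, 0], [0, 1.9]])
        with pytest.raises(ValueError):
            lumen_metrics(bowtie)

    def test_metrics_invariants(self):
        with pytest.raises(ValueError):
            LumenMetrics(-1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            LumenMetrics(1.0, 1.0, 2.0, 3.0)  # min > mean


class TestRelativeDifferences:
    def test_identical_series_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert relative_difference(x, x) == 0.0
        assert absolute_relative_difference(x, x) == 0.0

    def test_single_pair_worked_example(self):
        assert relative_difference([2.0], [1.0]) == pytest.approx(-50.0)
        assert absolute_relative_difference([2.0], [1.0]) == pytest.approx(50.0)

    def test_two_pair_worked_example(self):
        o, i = [2.0, 4.0], [1.0, 5.0]
        assert relative_difference(o, i) == pytest.approx(-15.0)
        assert absolute_relative_difference(o, i) == pytest.approx(35.0)

    def test_rd_antisymmetric_ard_symmetric(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(1, 10, 25)
        b = rng.uniform(1, 10, 25)
        assert relative_difference(a, b) == pytest.approx(-relative_difference(b, a))
        assert absolute_relative_difference(a, b) == pytest.approx(
            absolute_relative_difference(b, a))
        assert absolute_relative_difference(a, b) >= abs(relative_difference(a, b))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            relative_difference([1.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            absolute_relative_difference([1.0], [-1.0])


def brute_force_icc21(o, i):
    """Two-way ANOVA mean-squares computation of ICC(2,1)."""
    x = np.column_stack([o, i])
    n, k = x.shape
    gm = x.mean()
    rm, cm = x.mean(axis=1), x.mean(axis=0)
    msr = k * ((rm - gm) ** 2).sum() / (n - 1)
    msc = n * ((cm - gm) ** 2).sum() / (k - 1)
    mse = ((x - rm[:, None] - cm[None, :] + gm) ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_matches_mean_squares_oracle(self):
        rng = np.random.default_rng(12)
        o = rng.normal(5, 1, 10)
        i = o + rng.normal(0.2, 0.3, 10)
        value, _ = icc(o, i)
        assert value == pytest.approx(brute_force_icc21(o, i), abs=1e-10)

    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        value, _ = icc(x, x)
        assert value == pytest.approx(1.0)

    def test_offset_penalized_below_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        value, _ = icc(x, x + 10.0)
        assert value < 0.5  # Pearson correlation would be 1

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(13)
        o = rng.normal(5, 1, 12)
        i = o + rng.normal(0, 0.4, 12)
        v0, _ = icc(o, i)
        v1, _ = icc(3.0 * o - 2.0, 3.0 * i - 2.0)
        assert v1 == pytest.approx(v0, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            icc([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        mean_d, lo, hi, means, diffs = bland_altman(x, x)
        assert mean_d == lo == hi == 0.0
        assert np.array_equal(means, x)
        assert np.array_equal(diffs, np.zeros(3))

    def test_symmetric_pair_hand_computation(self):
        first = np.array([1.0, 3.0])
        second = np.array([2.0, 2.0])  # d = (-1, 1)
        mean_d, lo, hi, _, _ = bland_altman(first, second)
        assert mean_d == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96 * np.sqrt(2.0))
        assert hi == pytest.approx(1.96 * np.sqrt(2.0))

    def test_constant_shift_collapses_limits(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        c = 0.7
        mean_d, lo, hi, _, _ = bland_altman(x, x - c)
        assert mean_d == pytest.approx(c)
        assert lo == pytest.approx(c)
        assert hi == pytest.approx(c)


def test_compare_series_report_invariants():
    rng = np.random.default_rng(14)
    a = rng.uniform(4, 8, 20)
    b = a + rng.normal(0.1, 0.2, 20)
    rep = compare_series(a, b)
    assert rep.ard_percent >= abs(rep.rd_percent)
    assert rep.loa_low <= rep.mean_difference <= rep.loa_high
    assert -1 <= rep.icc <= 1
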