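import itertools

import numpy as np
import pytest

from lastkit.recognition import (ModelSet, RecognitionConfig, ShapeLabel,
                                 amplitude_fraction, artificial_rect_models,
                                 artificial_tri_models, classify_characters,
                                 dtw_distance, hough_horizontal_fraction,
                                 min_enclosing_rectangle,
                                 min_enclosing_triangle,
                                 perfect_triangle_template, select_models)
from lastkit.scan_io import ValidationError
from lastkit.segmentation import CharacterROI, CharacterSignal


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_min_rect(pts):
    """Smallest hull-edge-aligned rectangle, by direct enumeration."""
    from scipy.spatial import ConvexHull

    hv = pts[ConvexHull(pts).vertices]
    best = np.inf
    for p, q in zip(hv, np.roll(hv, -1, axis=0)):
        d = q - p
        nrm = np.hypot(*d)
        if nrm == 0:
            continue
        u = d / nrm
        v = np.array([-u[1], u[0]])
        pu, pv = hv @ u, hv @ v
        best = min(best, float(np.ptp(pu) * np.ptp(pv)))
    return best


def brute_min_tri(pts):
    """O(n^3) flush-side search: every minimal enclosing triangle has a side
    flush with a hull edge and the other sides either flush or touching a
    hull vertex at their midpoint; enumerate all such candidates."""
    from scipy.spatial import ConvexHull

    hv = pts[ConvexHull(pts).vertices]
    n = len(hv)
    if n == 3:
        return 0.5 * abs((hv[1, 0] - hv[0, 0]) * (hv[2, 1] - hv[0, 1])
                         - (hv[1, 1] - hv[0, 1]) * (hv[2, 0] - hv[0, 0]))
    dirs = np.roll(hv, -1, axis=0) - hv
    best = np.inf

    def contains(tri):
        a, b, c = tri
        ar = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(ar) < 1e-10:
            return False
        s = np.sign(ar)
        for p, q in ((a, b), (b, c), (c, a)):
            cr = ((q[0] - p[0]) * (hv[:, 1] - p[1])
                  - (q[1] - p[1]) * (hv[:, 0] - p[0]))
            if np.any(s * cr < -1e-7):
                return False
        return True

    for i, j in itertools.combinations(range(n), 2):
        di, dj = dirs[i], dirs[j]
        den = di[0] * dj[1] - di[1] * dj[0]
        if abs(den) < 1e-12:
            continue
        r = hv[j] - hv[i]
        X = hv[i] + ((r[0] * dj[1] - r[1] * dj[0]) / den) * di
        for k in range(n):
            v = hv[k] - X
            ss = 2 * (v[0] * dj[1] - v[1] * dj[0]) / den
            tt = 2 * (di[0] * v[1] - di[1] * v[0]) / den
            if abs(ss) < 1e-12 or abs(tt) < 1e-12:
                continue
            tri = np.array([X, X + ss * di, X + tt * dj])
            if contains(tri):
                best = min(best, 0.5 * abs(ss * tt * den))
        for k in range(n):
            if k in (i, j):
                continue
            dk = dirs[k]
            d1 = di[0] * dk[1] - di[1] * dk[0]
            d2 = dj[0] * dk[1] - dj[1] * dk[0]
            if abs(d1) < 1e-12 or abs(d2) < 1e-12:
                continue
            s1 = ((hv[k, 0] - hv[i, 0]) * dk[1]
                  - (hv[k, 1] - hv[i, 1]) * dk[0]) / d1
            s2 = ((hv[k, 0] - hv[j, 0]) * dk[1]
                  - (hv[k, 1] - hv[j, 1]) * dk[0]) / d2
            Y, Z = hv[i] + s1 * di, hv[j] + s2 * dj
            tri = np.array([X, Y, Z])
            if contains(tri):
                area = 0.5 * abs((Y[0] - X[0]) * (Z[1] - X[1])
                                 - (Y[1] - X[1]) * (Z[0] - X[0]))
                best = min(best, area)
    return best


def dtw_oracle(a, b, window_frac=1.0):
    """Exhaustive DP over the full cost matrix with the band predicate."""
    n, m = len(a), len(b)
    w = window_frac * max(n, m)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if abs(i * (m / n) - j) > w:
                continue
            D[i, j] = ((a[i - 1] - b[j - 1]) ** 2
                       + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1]))
    return D[n, m]


# ---------------------------------------------------------------------------
# minimum enclosing shapes
# ---------------------------------------------------------------------------

class TestMinEnclosingRectangle:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        area, corners = min_enclosing_rectangle(pts)
        assert area == pytest.approx(1.0)

    def test_rotation_invariance(self):
        th = np.deg2rad(45)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) @ R.T
        area, _ = min_enclosing_rectangle(pts)
        assert area == pytest.approx(1.0)

    def test_matches_shapely_oracle(self, rng):
        from shapely.geometry import MultiPoint

        for _ in range(50):
            pts = rng.normal(size=(10, 2))
            area, _ = min_enclosing_rectangle(pts)
            expected = MultiPoint([tuple(p) for p in pts]) \
                .minimum_rotated_rectangle.area
            assert area == pytest.approx(expected, rel=1e-9)

    def test_scaling_is_quadratic(self, rng):
        pts = rng.normal(size=(12, 2))
        a1, _ = min_enclosing_rectangle(pts)
        a2, _ = min_enclosing_rectangle(3.0 * pts)
        assert a2 == pytest.approx(9.0 * a1, rel=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValidationError):
            min_enclosing_rectangle(pts)


class TestMinEnclosingTriangle:
    def test_triangle_encloses_itself(self):
        pts = np.array([[0, 0], [2, 0], [1, np.sqrt(3)]])
        area, _ = min_enclosing_triangle(pts)
        assert area == pytest.approx(np.sqrt(3), rel=1e-9)

    def test_unit_square_needs_area_two(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        area, _ = min_enclosing_triangle(pts)
        assert area == pytest.approx(2.0, rel=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            pts = rng.normal(size=(int(rng.integers(4, 13)), 2))
            area, tri = min_enclosing_triangle(pts)
            assert area == pytest.approx(brute_min_tri(pts), rel=1e-6)

    def test_at_least_hull_area_and_quadratic_scaling(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.normal(size=(10, 2))
        area, _ = min_enclosing_triangle(pts)
        assert area >= ConvexHull(pts).volume - 1e-9
        area3, _ = min_enclosing_triangle(3.0 * pts)
        assert area3 == pytest.approx(9.0 * area, rel=1e-6)


# ---------------------------------------------------------------------------
# per-character cues
# ---------------------------------------------------------------------------

def _roi_from_mask(mask):
    rows, cols = np.nonzero(mask)
    return CharacterROI(mask=mask,
                        bbox=(int(cols.min()), int(cols.max()) + 1,
                              int(rows.min()), int(rows.max()) + 1),
                        index=0)


def _open_rect_mask(w=60, h=40, pad=5):
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    m[pad, pad:pad + w] = True              # top stroke
    m[pad:pad + h, pad] = True              # left
    m[pad:pad + h, pad + w - 1] = True      # right
    return m


def _tent_mask(w=61, h=40, pad=5):
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    apex = w // 2
    for c in range(w):
        rise = int(round(h * (c / apex if c <= apex else (w - 1 - c) / apex)))
        m[pad + h - min(rise, h), pad + c] = True
    return m


class TestHoughHorizontalFraction:
    def test_open_rectangle_has_long_horizontal(self):
        frac = hough_horizontal_fraction(_roi_from_mask(_open_rect_mask()))
        assert frac > 0.8

    def test_triangle_has_no_long_horizontal(self):
        frac = hough_horizontal_fraction(_roi_from_mask(_tent_mask()))
        assert frac < 0.25

    def test_vertical_stroke_near_zero(self):
        m = np.zeros((50, 20), dtype=bool)
        m[5:45, 10] = True
        assert hough_horizontal_fraction(_roi_from_mask(m)) < 0.2


class TestAmplitudeFraction:
    def test_flat_plateau_is_one(self):
        cs = CharacterSignal(x_range=(0, 10),
                             values=np.array([0.] + [5.] * 8 + [0.]))
        # plateau at max covers 8/10 of the samples
        assert amplitude_fraction(cs) == pytest.approx(0.8)

    def test_symmetric_tent_is_one_fifth(self):
        n = 1001
        tent = np.minimum(np.linspace(0, 2, n), np.linspace(2, 0, n))
        cs = CharacterSignal(x_range=(0, n), values=tent)
        assert amplitude_fraction(cs) == pytest.approx(0.20, abs=0.01)

    def test_seventy_percent_plateau(self):
        n = 1000
        ramp = 150
        vals = np.concatenate([np.linspace(0, 1, ramp),
                               np.ones(n - 2 * ramp),
                               np.linspace(1, 0, ramp)])
        cs = CharacterSignal(x_range=(0, n), values=vals)
        frac = amplitude_fraction(cs)
        assert frac == pytest.approx(0.76, abs=0.02)
        assert frac > 0.66  # the rectangle-model rule fires

    def test_zero_amplitude_rejected(self):
        cs = CharacterSignal(x_range=(0, 5), values=np.zeros(5))
        with pytest.raises(ValidationError):
            amplitude_fraction(cs)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _char(mask, sig_values):
    roi = _roi_from_mask(mask)
    cs = CharacterSignal(x_range=(0, len(sig_values)),
                         values=np.asarray(sig_values, float))
    return roi, cs


def _rect_char():
    tent = np.ones(60)
    tent[0] = tent[-1] = 0.0
    return _char(_open_rect_mask(), tent * 40)


def _tri_char():
    n = 61
    tent = np.minimum(np.linspace(0, 2, n), np.linspace(2, 0, n)) * 40
    return _char(_tent_mask(), tent)


class TestSelectModels:
    def test_mixed_series_gives_real_models_of_both_classes(self):
        chars = [_rect_char(), _tri_char(), _rect_char(), _tri_char()]
        models, assignments = select_models(chars)
        assert not models.rect_artificial
        assert not models.tri_artificial
        assert set(assignments.values()) == {ShapeLabel.RECTANGLE,
                                             ShapeLabel.TRIANGLE}

    def test_all_triangles_fall_back_to_artificial_rectangles(self):
        chars = [_tri_char(), _tri_char(), _tri_char()]
        models, _ = select_models(chars)
        assert models.rect_artificial
        assert len(models.rect_models) == 3
        assert not models.tri_artificial

    def test_degenerate_blob_gives_both_artificial(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 4:7] = True  # collinear: no enclosing shapes, no amplitude
        chars = [_char(m, np.zeros(3))]
        models, assignments = select_models(chars)
        assert models.rect_artificial and models.tri_artificial
        assert assignments == {}

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            select_models([])


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

class TestDtw:
    def test_identical_sequences_zero(self, rng):
        a = rng.normal(size=20)
        assert dtw_distance(a, a, 1.0) == 0.0
        assert dtw_distance(a, a, 0.05) == 0.0

    def test_constant_offset_hand_dp(self):
        assert dtw_distance([0, 0, 0], [1, 1, 1], 1.0) == pytest.approx(3.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(60):
            n, m = rng.integers(3, 31, size=2)
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            assert dtw_distance(a, b, 1.0) == pytest.approx(
                dtw_oracle(a, b, 1.0), abs=1e-12)

    def test_constrained_matches_constrained_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 31))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            got = dtw_distance(a, b, 0.2)
            want = dtw_oracle(a, b, 0.2)
            if np.isfinite(want):
                assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_for_equal_lengths(self, rng):
        a, b = rng.normal(size=(2, 25))
        assert dtw_distance(a, b, 0.3) == pytest.approx(
            dtw_distance(b, a, 0.3))

    def test_infeasible_band_falls_back(self):
        # extreme length ratio: the 1%-band cannot reach the first column
        d = dtw_distance(np.zeros(3), np.ones(300), 0.01)
        assert np.isfinite(d)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            dtw_distance([], [1.0])


class TestClassify:
    def _models(self, length=50):
        return ModelSet(rect_models=artificial_rect_models(length),
                        tri_models=artificial_tri_models(length),
                        rect_artificial=True, tri_artificial=True,
                        model_length=length)

    def test_tent_signal_goes_to_triangle(self):
        n = 80
        tent = np.minimum(np.linspace(0, 2, n), np.linspace(2, 0, n)) * 33
        cs = CharacterSignal(x_range=(0, n), values=tent)
        labels = classify_characters([cs], self._models())
        assert labels == [ShapeLabel.TRIANGLE]

    def test_plateau_signal_goes_to_rectangle(self):
        n = 80
        vals = np.ones(n) * 12
        vals[:4] = np.linspace(0, 12, 4)
        vals[-4:] = np.linspace(12, 0, 4)
        cs = CharacterSignal(x_range=(0, n), values=vals)
        labels = classify_characters([cs], self._models())
        assert labels == [ShapeLabel.RECTANGLE]

    def test_amplitude_scaling_invariance(self):
        n = 70
        tent = np.minimum(np.linspace(0, 2, n), np.linspace(2, 0, n))
        for scale in (0.5, 1.0, 250.0):
            cs = CharacterSignal(x_range=(0, n), values=tent * scale)
            assert classify_characters([cs], self._models()) \
                == [ShapeLabel.TRIANGLE]

    def test_model_characters_keep_their_class(self):
        n = 50
        cs = CharacterSignal(x_range=(0, n),
                             values=perfect_triangle_template(n))
        labels = classify_characters(
            [cs], self._models(), model_assignments={0: ShapeLabel.RECTANGLE})
        assert labels == [ShapeLabel.RECTANGLE]
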