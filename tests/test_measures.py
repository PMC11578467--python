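"""Geometric measures against independent oracles, plus invariance properties."""
import numpy as np
import pytest

from gustoface.errors import DegenerateFrameError, UndefinedFitError, ValidationError
from gustoface.io import LandmarkFrame
from gustoface.measures import (MEASURE_NAMES, compute_measure_series,
                                eyebrow_elevation, eyebrow_shape, eyebrow_tilt,
                                lip_elevation, mirror_frame, mouth_corner,
                                moving_average, palpebral_aperture,
                                reference_distance)

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)
# ---------------------------------------------------------------------------

def euclid_oracle(a, b):
    return sum((ai - bi) ** 2 for ai, bi in zip(a, b)) ** 0.5


def weiszfeld_oracle(pts):
    """Scalar-loop geometric median, written independently of the package.

    Checks each data point's vertex optimality (resultant of unit
    vectors to the others has norm <= multiplicity) before iterating.
    """
    for cand in pts:
        rx = ry = 0.0
        mult = 0
        for p in pts:
            d = euclid_oracle(p, cand)
            if d <= 1e-15:
                mult += 1
            else:
                rx += (p[0] - cand[0]) / d
                ry += (p[1] - cand[1]) / d
        if (rx * rx + ry * ry) ** 0.5 <= mult + 1e-12:
            return [cand[0], cand[1]]
    y = [sum(p[0] for p in pts) / len(pts), sum(p[1] for p in pts) / len(pts)]
    for _ in range(200):
        num = [0.0, 0.0]
        den = 0.0
        for p in pts:
            d = euclid_oracle(p, y)
            w = 1.0 / max(d, 1e-30)
            num[0] += p[0] * w
            num[1] += p[1] * w
            den += w
        y_new = [num[0] / den, num[1] / den]
        move = euclid_oracle(y, y_new)
        y = y_new
        if move < 1e-11:
            break
    for _ in range(80):  # scalar damped-Newton polish (smooth case)
        gx = gy = hxx = hyy = hxy = 0.0
        for p in pts:
            d = max(euclid_oracle(p, y), 1e-30)
            ux, uy = (y[0] - p[0]) / d, (y[1] - p[1]) / d
            gx += ux
            gy += uy
            hxx += (1.0 - ux * ux) / d
            hyy += (1.0 - uy * uy) / d
            hxy += -ux * uy / d
        det = hxx * hyy - hxy * hxy
        if abs(det) < 1e-300:
            break
        sx = (hyy * gx - hxy * gy) / det
        sy = (hxx * gy - hxy * gx) / det
        cost = lambda q: sum(euclid_oracle(p, q) for p in pts)
        y_try = [y[0] - sx, y[1] - sy]
        y = y_try if cost(y_try) <= cost(y) else [y[0] - 0.5 * sx, y[1] - 0.5 * sy]
        if (sx * sx + sy * sy) ** 0.5 < 1e-14:
            break
    return y


def tilt_oracle(brow_xy, corner_a, corner_b):
    """Principal axis of the 2x2 covariance vs the corner line, folded to [0,90]."""
    c = brow_xy - brow_xy.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    line = np.asarray(corner_b[:2]) - np.asarray(corner_a[:2])
    cos = abs(np.dot(axis, line)) / (np.linalg.norm(axis) * np.linalg.norm(line))
    return np.degrees(np.arccos(np.clip(cos, -1, 1)))


def angle_oracle(p, mid, q):
    u = np.asarray(p[:2]) - np.asarray(mid[:2])
    v = np.asarray(q[:2]) - np.asarray(mid[:2])
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(cos, -1, 1)))


def fan_area_oracle(poly_xy):
    """Signed fan triangulation from the first vertex, absolute total."""
    total = 0.0
    p0 = poly_xy[0]
    for i in range(1, len(poly_xy) - 1):
        a, b = poly_xy[i] - p0, poly_xy[i + 1] - p0
        total += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return abs(total)


def set_coords(frame, lmap, landmark_id, xyz):
    k = int(np.flatnonzero(frame.landmark_ids == landmark_id)[0])
    frame.coords[k] = xyz


def region_coords(frame, lmap, region):
    ids = lmap.regions()[region]
    pos = {int(i): k for k, i in enumerate(frame.landmark_ids)}
    return np.array([frame.coords[pos[i]] for i in ids])


# ---------------------------------------------------------------------------
# hand-constructed examples
# ---------------------------------------------------------------------------

def test_reference_distance_345(template, lmap):
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    set_coords(f, lmap, lmap.right_inner_eye_corner, (0.0, 0.0, 0.0))
    set_coords(f, lmap, lmap.nose_tip, (3.0, 4.0, 0.0))
    assert reference_distance(f, lmap) == pytest.approx(5.0)


def test_reference_distance_degenerate(template, lmap):
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    set_coords(f, lmap, lmap.right_inner_eye_corner, (0.2, 0.3, 0.0))
    set_coords(f, lmap, lmap.nose_tip, (0.2, 0.3, 0.5))  # same x-y point
    with pytest.raises(DegenerateFrameError):
        reference_distance(f, lmap)


def test_eyebrow_elevation_unit_case(template, lmap):
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    for i in lmap.left_eyebrow:
        set_coords(f, lmap, i, (0.0, 1.0, 0.0))
    set_coords(f, lmap, lmap.nose_tip, (0.0, 0.0, 0.0))
    set_coords(f, lmap, lmap.right_inner_eye_corner, (1.0, 0.0, 0.0))  # reference 1
    assert eyebrow_elevation(f, lmap, "L") == pytest.approx(1.0)
    # uniform scaling cancels through the reference
    f2 = LandmarkFrame(0, f.landmark_ids.copy(), f.coords * 2.0)
    assert eyebrow_elevation(f2, lmap, "L") == pytest.approx(1.0)


def test_eyebrow_tilt_known_angles(template, lmap):
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    set_coords(f, lmap, lmap.left_inner_eye_corner, (0.0, 0.0, 0.0))
    set_coords(f, lmap, lmap.right_inner_eye_corner, (1.0, 0.0, 0.0))
    for k, i in enumerate(lmap.left_eyebrow):
        set_coords(f, lmap, i, (k * 0.1, 0.0, 0.0))       # flat brow
    assert eyebrow_tilt(f, lmap, "L") == pytest.approx(0.0, abs=1e-9)
    for k, i in enumerate(lmap.left_eyebrow):
        set_coords(f, lmap, i, (k * 0.1, k * 0.1, 0.0))   # y = x
    assert eyebrow_tilt(f, lmap, "L") == pytest.approx(45.0)
    for i in lmap.left_eyebrow:
        set_coords(f, lmap, i, (0.5, 0.5, 0.0))           # coincident: undefined
    with pytest.raises(UndefinedFitError):
        eyebrow_tilt(f, lmap, "L")


def test_eyebrow_shape_known_angles(template, lmap):
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    for k, i in enumerate(lmap.left_eyebrow):
        set_coords(f, lmap, i, (float(k), 0.0, 0.0))      # collinear
    assert eyebrow_shape(f, lmap, "L") == pytest.approx(180.0)
    ids = lmap.left_eyebrow
    set_coords(f, lmap, ids[0], (-1.0, 0.0, 0.0))
    set_coords(f, lmap, ids[2], (0.0, 1.0, 0.0))
    set_coords(f, lmap, ids[4], (1.0, 0.0, 0.0))
    assert eyebrow_shape(f, lmap, "L") == pytest.approx(90.0)


def test_palpebral_aperture_square(template, lmap):
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    square = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    # first four contour points trace the unit square; the rest sit on the
    # closing edge back to the origin (collinear, zero area contribution)
    for j, i in enumerate(lmap.left_eye_contour):
        p = square[j] if j < 4 else (0.0, 0.0)
        set_coords(f, lmap, i, (p[0], p[1], 0.0))
    set_coords(f, lmap, lmap.nose_tip, (5.0, 5.0, 0.0))
    set_coords(f, lmap, lmap.right_inner_eye_corner, (5.0, 6.0, 0.0))  # reference 1
    assert palpebral_aperture(f, lmap, "L") == pytest.approx(1.0)
    set_coords(f, lmap, lmap.right_inner_eye_corner, (5.0, 7.0, 0.0))  # reference 2
    assert palpebral_aperture(f, lmap, "L") == pytest.approx(0.25)


def test_lip_and_mouth_corner_cases(template, lmap):
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    set_coords(f, lmap, lmap.nose_tip, (0.0, 0.0, 0.0))
    set_coords(f, lmap, lmap.right_inner_eye_corner, (0.0, 1.0, 0.0))  # reference 1
    set_coords(f, lmap, lmap.lower_mid_lip, (0.0, -2.0, 0.0))
    set_coords(f, lmap, lmap.left_mouth_corner, (1.0, -1.0, 0.0))
    assert lip_elevation(f, lmap, "lower") == pytest.approx(2.0)
    assert mouth_corner(f, lmap, "L") == pytest.approx(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# oracle equivalence on random frames
# ---------------------------------------------------------------------------

def test_all_operations_match_oracles(lmap, random_frame_factory):
    """Every geometric operation equals its naive oracle to 1e-9 on random frames."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        f = random_frame_factory(rng)
        ref = reference_distance(f, lmap)
        nose = f.coord_of(lmap.nose_tip)
        corner_r = f.coord_of(lmap.right_inner_eye_corner)
        corner_l = f.coord_of(lmap.left_inner_eye_corner)
        assert ref == pytest.approx(euclid_oracle(nose[:2], corner_r[:2]), abs=1e-9)

        brow = region_coords(f, lmap, "left_eyebrow")
        med = weiszfeld_oracle(brow[:, :2])
        assert eyebrow_elevation(f, lmap, "L") == pytest.approx(
            euclid_oracle(med, nose[:2]) / ref, abs=1e-9)

        assert eyebrow_tilt(f, lmap, "R") == pytest.approx(
            tilt_oracle(region_coords(f, lmap, "right_eyebrow")[:, :2],
                        corner_l, corner_r), abs=1e-7)

        assert eyebrow_shape(f, lmap, "L") == pytest.approx(
            angle_oracle(brow[0], brow[2], brow[4]), abs=1e-9)

        contour = region_coords(f, lmap, "right_eye_contour")[:, :2]
        assert palpebral_aperture(f, lmap, "R") == pytest.approx(
            fan_area_oracle(contour) / ref ** 2, abs=1e-9)

        lip = f.coord_of(lmap.upper_mid_lip)
        assert lip_elevation(f, lmap, "upper") == pytest.approx(
            euclid_oracle(lip[:2], nose[:2]) / ref, abs=1e-9)

        corner = f.coord_of(lmap.left_mouth_corner)
        assert mouth_corner(f, lmap, "L") == pytest.approx(
            euclid_oracle(corner[:2], nose[:2]) / ref, abs=1e-9)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

def all_measures(frame, lmap):
    return np.array([
        eyebrow_elevation(frame, lmap, "L"), eyebrow_elevation(frame, lmap, "R"),
        eyebrow_tilt(frame, lmap, "L"), eyebrow_tilt(frame, lmap, "R"),
        eyebrow_shape(frame, lmap, "L"), eyebrow_shape(frame, lmap, "R"),
        palpebral_aperture(frame, lmap, "L"), palpebral_aperture(frame, lmap, "R"),
        lip_elevation(frame, lmap, "upper"), lip_elevation(frame, lmap, "lower"),
        mouth_corner(frame, lmap, "L"), mouth_corner(frame, lmap, "R"),
    ])


def test_similarity_invariance(lmap, random_frame_factory):
    """Translation + in-plane rotation + uniform scaling leave all measures fixed."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        f = random_frame_factory(rng)
        base = all_measures(f, lmap)
        theta = rng.uniform(0, 2 * np.pi)
        s = float(rng.uniform(0.3, 3.0))
        t = rng.standard_normal(2)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        coords = f.coords.copy()
        coords[:, :2] = s * coords[:, :2] @ R.T + t
        coords[:, 2] = s * coords[:, 2]
        g = LandmarkFrame(0, f.landmark_ids.copy(), coords)
        np.testing.assert_allclose(all_measures(g, lmap), base, rtol=0, atol=1e-6)


def test_mirror_symmetry_swaps_sides(lmap, random_frame_factory):
    """Reflection across the midline swaps every L/R measure pair to 1e-9."""
    rng = np.random.default_rng(11)
    swap = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4, 6: 7, 7: 6, 8: 8, 9: 9, 10: 11, 11: 10}
    for _ in range(50):
        f = random_frame_factory(rng, symmetric_reference=True)
        base = all_measures(f, lmap)
        mirrored = all_measures(mirror_frame(f, lmap), lmap)
        expected = np.array([base[swap[j]] for j in range(12)])
        np.testing.assert_allclose(mirrored, expected, rtol=0, atol=1e-9)


def test_aperture_nonnegative_and_zero_iff_degenerate(template, lmap,
                                                      random_frame_factory):
    rng = np.random.default_rng(3)
    for _ in range(30):
        f = random_frame_factory(rng)
        assert palpebral_aperture(f, lmap, "L") >= 0.0
    f = LandmarkFrame(0, template.landmark_ids.copy(), template.coords.copy())
    for i in lmap.left_eye_contour:
        set_coords(f, lmap, i, (0.3, 0.3, 0.0))  # collapsed contour
    assert palpebral_aperture(f, lmap, "L") == 0.0


# ---------------------------------------------------------------------------
# series computation and smoothing
# ---------------------------------------------------------------------------

def test_constant_stream_constant_series(constant_stream_factory, lmap):
    stream = constant_stream_factory(n_si=5, n_sii=5)
    series = compute_measure_series(stream, lmap)
    assert len(series) == 10
    assert (series.values.nunique() == 1).all()


def test_zoom_drift_leaves_measures_constant(constant_stream_factory, lmap):
    """A 2x zoom over the video changes no rescaled measure beyond 1e-6."""
    stream = constant_stream_factory(n_si=10, n_sii=10)
    n = stream.n_frames
    for t, f in enumerate(stream.frames):
        f.coords *= 1.0 + t / (n - 1)   # linear drift up to 2x
    series = compute_measure_series(stream, lmap)
    spread = series.values.max() - series.values.min()
    assert (spread < 1e-6).all()
    # but the raw reference tracks the zoom
    assert series.reference_distance[-1] == pytest.approx(
        2 * series.reference_distance[0])


def test_degenerate_frame_dropped_and_counted(constant_stream_factory, lmap):
    stream = constant_stream_factory(n_si=6, n_sii=0)
    f = stream.frames[2]
    pos = {int(i): k for k, i in enumerate(f.landmark_ids)}
    f.coords[pos[lmap.nose_tip], :2] = f.coords[pos[lmap.right_inner_eye_corner], :2]
    series = compute_measure_series(stream, lmap, section="SI")
    assert len(series) == 5
    assert series.n_dropped_degenerate == 1


def test_moving_average_against_oracle(constant_stream_factory, lmap):
    stream = constant_stream_factory(n_si=12, n_sii=0)
    rng = np.random.default_rng(5)
    for f in stream.frames:
        f.coords += rng.normal(0, 0.01, f.coords.shape)
    series = compute_measure_series(stream, lmap, section="SI")
    sm = moving_average(series, 3)
    assert len(sm) == len(series) - 2
    x = series.values["mouth_corner_L"].to_numpy()
    naive = np.array([x[i - 1:i + 2].mean() for i in range(1, len(x) - 1)])
    np.testing.assert_allclose(sm.values["mouth_corner_L"].to_numpy(), naive,
                               atol=1e-12)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=40),
           half=st.integers(0, 2))
    def test_moving_average_property(values, half):
        """Centred mean over any data and odd window matches the naive oracle."""
        import pandas as pd
        from gustoface.measures import MeasureSeries
        window = 2 * half + 1
        n = len(values)
        if window > n:
            return
        vals = np.tile(np.asarray(values)[:, None], (1, 12))
        series = MeasureSeries(video_id="v", section="SI",
                               frame_indices=np.arange(n),
                               values=pd.DataFrame(vals, columns=list(MEASURE_NAMES)),
                               reference_distance=np.ones(n))
        sm = moving_average(series, window)
        assert len(sm) == n - window + 1
        for i in range(len(sm)):
            expected = float(np.mean(values[i:i + window]))
            assert sm.values.iloc[i, 0] == pytest.approx(expected, abs=1e-9)
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_moving_average_window_rules(constant_stream_factory, lmap):
    series = compute_measure_series(constant_stream_factory(5, 0), lmap, section="SI")
    assert moving_average(series, 1) is series
    single = moving_average(series, 5)
    assert len(single) == 1
    with pytest.raises(ValidationError):
        moving_average(series, 4)
    with pytest.raises(ValidationError):
        moving_average(series, 7)
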