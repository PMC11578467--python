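"""The twelve rescaled geometric facial measures.

Six measure families, each with two variants, computed per frame from
the key-landmark subset:

* eyebrow elevation (L/R) — distance from the geometric median of the
  five brow landmarks to the nose tip, over the reference distance;
* eyebrow tilt (L/R) — unsigned angle in [0, 90] degrees between the
  total-least-squares line through the five brow landmarks and the line
  joining the two inner eye corners;
* eyebrow shape (L/R) — interior angle in [0, 180] degrees at the middle
  brow landmark between the segments to the two brow endpoints;
* palpebral aperture (L/R) — absolute shoelace area of the eye-contour
  polygon, over the squared reference distance;
* lip elevation (upper/lower) — mid-lip to nose-tip distance over the
  reference distance;
* mouth corner (L/R) — mouth-corner to nose-tip distance over the
  reference distance.

The reference distance is the per-frame Euclidean distance between the
right inner eye corner and the nose tip; dividing by it (or its square,
for the area) cancels camera distance and zoom.  All constructions are
planar in the x-y image plane by default ("2d"); a "3d" mode uses full
Euclidean distances for the distance-family measures.  Every measure is
invariant under translation, in-plane rotation and uniform scaling of
the landmarks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import (DegenerateFrameError, EmptySeriesError, UndefinedFitError,
                     ValidationError)
from .io import LandmarkFrame, LandmarkStream, Section, select_frames
from .maps import LandmarkMap

log = logging.getLogger(__name__)

#: Fixed measure order used everywhere downstream (feature columns, reports).
MEASURE_NAMES = (
    "eyebrow_elevation_L", "eyebrow_elevation_R",
    "eyebrow_tilt_L", "eyebrow_tilt_R",
    "eyebrow_shape_L", "eyebrow_shape_R",
    "palpebral_aperture_L", "palpebral_aperture_R",
    "lip_elevation_upper", "lip_elevation_lower",
    "mouth_corner_L", "mouth_corner_R",
)

Mode = Literal["2d", "3d"]
_EPS = 1e-12


@dataclass
class MeasureSeries:
    """Per-frame measure vectors for one video and section."""

    video_id: str
    section: str
    frame_indices: np.ndarray          # (n,)
    values: pd.DataFrame               # (n, 12), columns = MEASURE_NAMES
    reference_distance: np.ndarray     # (n,) pre-scaling reference per frame
    n_dropped_degenerate: int = 0

    def __post_init__(self) -> None:
        if not (len(self.frame_indices) == len(self.values) == len(self.reference_distance)):
            raise ValidationError("MeasureSeries sequence lengths differ")
        if np.any(self.reference_distance <= 0):
            raise ValidationError("reference_distance must be > 0 for retained frames")

    def __len__(self) -> int:
        return len(self.frame_indices)

    def to_tidy(self) -> pd.DataFrame:
        """Long-form table (video_id, section, frame_index, measure, value)."""
        df = self.values.copy()
        df.insert(0, "frame_index", self.frame_indices)
        long = df.melt(id_vars="frame_index", var_name="measure", value_name="value")
        long.insert(0, "section", self.section)
        long.insert(0, "video_id", self.video_id)
        return long


# ---------------------------------------------------------------------------
# vectorised geometric core: arrays shaped (n_frames, ..., 3)
# ---------------------------------------------------------------------------

def _frame_stack(frames: list[LandmarkFrame], lmap: LandmarkMap) -> dict[str, np.ndarray]:
    """Stack frames into per-region coordinate arrays of shape (n, k, 3)."""
    regions = lmap.regions()
    out: dict[str, np.ndarray] = {}
    pos_cache: dict[tuple, np.ndarray] = {}
    arrs = []
    for f in frames:
        key = tuple(f.landmark_ids.tolist())
        if key not in pos_cache:
            pos = {int(i): k for k, i in enumerate(f.landmark_ids)}
            idx = []
            for region, ids in regions.items():
                for i in ids:
                    if i not in pos:
                        from .errors import MissingLandmarkError
                        raise MissingLandmarkError(i, region)
                    idx.append(pos[i])
            pos_cache[key] = np.array(idx, dtype=np.intp)
        arrs.append(f.coords[pos_cache[key]])
    stack = np.stack(arrs) if arrs else np.empty((0, len(lmap.all_ids()), 3))
    k = 0
    for region, ids in regions.items():
        out[region] = stack[:, k:k + len(ids), :]
        k += len(ids)
    return out


def _dist(a: np.ndarray, b: np.ndarray, mode: Mode) -> np.ndarray:
    d = a - b
    if mode == "2d":
        d = d[..., :2]
    return np.linalg.norm(d, axis=-1)


def _reference(parts: dict[str, np.ndarray], mode: Mode) -> np.ndarray:
    return _dist(parts["right_inner_eye_corner"][:, 0], parts["nose_tip"][:, 0], mode)


def geometric_median(points: np.ndarray, tol: float = 1e-13,
                     max_iter: int = 2000) -> np.ndarray:
    """Geometric median of point sets, batched: (n, k, d) -> (n, d).

    The geometric median is equivariant under any similarity transform
    (translation, rotation, uniform scaling), unlike the coordinate-wise
    median, which is what makes the elevation measures rotation-invariant
    after rescaling.

    A data point is returned exactly when it satisfies the vertex
    optimality condition (the resultant of unit vectors towards the
    other points has norm at most the point's multiplicity) — Weiszfeld
    iteration stalls there; in the smooth case the Weiszfeld fixed-point
    iteration from the centroid converges linearly.
    """
    pts = np.asarray(points, dtype=float)
    n, k, dim = pts.shape
    # vertex optimality check for every candidate data point
    diff = pts[:, None, :, :] - pts[:, :, None, :]          # (n, cand, other, d)
    dist = np.linalg.norm(diff, axis=-1)
    nonzero = dist > 1e-15
    unit = np.where(nonzero[..., None], diff / np.where(nonzero, dist, 1.0)[..., None], 0.0)
    resultant = np.linalg.norm(unit.sum(axis=2), axis=-1)    # (n, cand)
    multiplicity = (~nonzero).sum(axis=2).astype(float)      # counts self
    is_median = resultant <= multiplicity + 1e-12
    best = np.argmax(is_median, axis=1)
    has_vertex = is_median.any(axis=1)
    out = np.empty((n, dim))
    out[has_vertex] = pts[np.flatnonzero(has_vertex), best[has_vertex]]

    todo = np.flatnonzero(~has_vertex)
    if todo.size:
        p = pts[todo]
        y = p.mean(axis=1)
        for _ in range(max_iter):
            d = np.linalg.norm(p - y[:, None, :], axis=-1)
            w = 1.0 / np.maximum(d, 1e-30)
            y_new = np.sum(p * w[..., None], axis=1) / np.sum(w, axis=1)[:, None]
            shift = np.max(np.linalg.norm(y_new - y, axis=-1))
            y = y_new
            if shift < 1e-9:   # hand over to Newton once in the basin
                break
        # Newton polish: Weiszfeld's linear rate degrades when the median
        # lies near (but not at) a data point; the objective is smooth
        # there, so damped Newton converges quadratically.
        eye = np.eye(dim)
        for _ in range(60):
            r = y[:, None, :] - p                      # (m, k, d)
            d = np.maximum(np.linalg.norm(r, axis=-1), 1e-30)
            u = r / d[..., None]
            g = u.sum(axis=1)                          # gradient
            hess = np.einsum("mk,mkab->mab",
                             1.0 / d, eye[None, None] - u[..., :, None] * u[..., None, :])
            step = np.linalg.solve(hess + 1e-300 * eye, g[..., None])[..., 0]
            cost_old = np.linalg.norm(p - y[:, None, :], axis=-1).sum(axis=1)
            y_try = y - step
            cost_new = np.linalg.norm(p - y_try[:, None, :], axis=-1).sum(axis=1)
            ok = cost_new <= cost_old
            y = np.where(ok[:, None], y_try, y - 0.5 * step)
            if np.max(np.linalg.norm(step, axis=-1)) < tol:
                break
        out[todo] = y
    return out


def _elevation(brow: np.ndarray, nose: np.ndarray, ref: np.ndarray, mode: Mode) -> np.ndarray:
    pts = brow[..., :2] if mode == "2d" else brow
    med = geometric_median(pts)
    d = np.linalg.norm(med - (nose[:, :2] if mode == "2d" else nose), axis=-1)
    return d / ref


def _tls_angle(points_xy: np.ndarray) -> np.ndarray:
    """Orientation (radians, mod pi) of the total-least-squares line per frame.

    For the centred 2x2 scatter matrix [[a, b], [b, c]], the principal
    axis makes angle 0.5 * atan2(2b, a - c) with the x-axis.
    """
    c = points_xy - points_xy.mean(axis=1, keepdims=True)
    a = np.sum(c[..., 0] ** 2, axis=1)
    b = np.sum(c[..., 0] * c[..., 1], axis=1)
    d = np.sum(c[..., 1] ** 2, axis=1)
    degenerate = (a + d) < _EPS
    theta = 0.5 * np.arctan2(2 * b, a - d)
    return np.where(degenerate, np.nan, theta)


def _tilt(brow: np.ndarray, left_corner: np.ndarray, right_corner: np.ndarray) -> np.ndarray:
    theta = _tls_angle(brow[..., :2])
    axis = right_corner[:, 0, :2] - left_corner[:, 0, :2]
    phi = np.arctan2(axis[:, 1], axis[:, 0])
    diff = np.abs(theta - phi) % np.pi
    return np.degrees(np.minimum(diff, np.pi - diff))


def _shape(brow: np.ndarray) -> np.ndarray:
    """Interior angle at the middle (3rd) of 5 ordered brow points, degrees."""
    mid = brow[:, 2, :2]
    u = brow[:, 0, :2] - mid
    v = brow[:, 4, :2] - mid
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu < _EPS) | (nv < _EPS)
    cos = np.einsum("ij,ij->i", u, v) / np.where(bad, 1.0, nu * nv)
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return np.where(bad, np.nan, ang)


def _shoelace(contour_xy: np.ndarray) -> np.ndarray:
    x = contour_xy[..., 0]
    y = contour_xy[..., 1]
    x2 = np.roll(x, -1, axis=1)
    y2 = np.roll(y, -1, axis=1)
    return 0.5 * np.abs(np.sum(x * y2 - x2 * y, axis=1))


def measure_matrix(parts: dict[str, np.ndarray], mode: Mode = "2d"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """All 12 measures for stacked frames.

    Returns ``(values, reference)`` with values shaped (n, 12) in
    :data:`MEASURE_NAMES` order.  Degenerate frames yield NaN rows
    (zero reference) or NaN entries (undefined fits); callers decide
    the drop policy.
    """
    ref = _reference(parts, mode)
    safe_ref = np.where(ref < _EPS, np.nan, ref)
    nose = parts["nose_tip"][:, 0]
    li = parts["left_inner_eye_corner"]
    ri = parts["right_inner_eye_corner"]
    cols = {
        "eyebrow_elevation_L": _elevation(parts["left_eyebrow"], nose, safe_ref, mode),
        "eyebrow_elevation_R": _elevation(parts["right_eyebrow"], nose, safe_ref, mode),
        "eyebrow_tilt_L": _tilt(parts["left_eyebrow"], li, ri),
        "eyebrow_tilt_R": _tilt(parts["right_eyebrow"], li, ri),
        "eyebrow_shape_L": _shape(parts["left_eyebrow"]),
        "eyebrow_shape_R": _shape(parts["right_eyebrow"]),
        "palpebral_aperture_L": _shoelace(parts["left_eye_contour"][..., :2]) / safe_ref ** 2,
        "palpebral_aperture_R": _shoelace(parts["right_eye_contour"][..., :2]) / safe_ref ** 2,
        "lip_elevation_upper": _dist(parts["upper_mid_lip"][:, 0], nose, mode) / safe_ref,
        "lip_elevation_lower": _dist(parts["lower_mid_lip"][:, 0], nose, mode) / safe_ref,
        "mouth_corner_L": _dist(parts["left_mouth_corner"][:, 0], nose, mode) / safe_ref,
        "mouth_corner_R": _dist(parts["right_mouth_corner"][:, 0], nose, mode) / safe_ref,
    }
    values = np.column_stack([cols[m] for m in MEASURE_NAMES])
    return values, ref


# ---------------------------------------------------------------------------
# single-frame operations (thin wrappers over the vectorised core)
# ---------------------------------------------------------------------------

def _one(frame: LandmarkFrame, lmap: LandmarkMap) -> dict[str, np.ndarray]:
    return _frame_stack([frame], lmap)


def reference_distance(frame: LandmarkFrame, lmap: LandmarkMap, mode: Mode = "2d") -> float:
    """Right inner eye corner to nose tip distance (the scaling reference)."""
    r = float(_reference(_one(frame, lmap), mode)[0])
    if r < _EPS:
        raise DegenerateFrameError(
            f"frame {frame.frame_index}: reference landmarks coincide")
    return r


def eyebrow_elevation(frame: LandmarkFrame, lmap: LandmarkMap, side: str,
                      mode: Mode = "2d") -> float:
    parts = _one(frame, lmap)
    ref = reference_distance(frame, lmap, mode)
    brow = parts[f"{_side(side)}_eyebrow"]
    return float(_elevation(brow, parts["nose_tip"][:, 0], np.array([ref]), mode)[0])


def eyebrow_tilt(frame: LandmarkFrame, lmap: LandmarkMap, side: str) -> float:
    parts = _one(frame, lmap)
    v = float(_tilt(parts[f"{_side(side)}_eyebrow"],
                    parts["left_inner_eye_corner"], parts["right_inner_eye_corner"])[0])
    if np.isnan(v):
        raise UndefinedFitError(f"frame {frame.frame_index}: eyebrow points coincident")
    return v


def eyebrow_shape(frame: LandmarkFrame, lmap: LandmarkMap, side: str) -> float:
    parts = _one(frame, lmap)
    v = float(_shape(parts[f"{_side(side)}_eyebrow"])[0])
    if np.isnan(v):
        raise UndefinedFitError(
            f"frame {frame.frame_index}: middle brow point coincides with an endpoint")
    return v


def palpebral_aperture(frame: LandmarkFrame, lmap: LandmarkMap, side: str,
                       mode: Mode = "2d") -> float:
    parts = _one(frame, lmap)
    contour = parts[f"{_side(side)}_eye_contour"]
    if contour.shape[1] < 3:
        raise ValidationError("eye contour needs at least 3 points")
    ref = reference_distance(frame, lmap, mode)
    return float(_shoelace(contour[..., :2])[0]) / ref ** 2


def lip_elevation(frame: LandmarkFrame, lmap: LandmarkMap, which: str,
                  mode: Mode = "2d") -> float:
    if which not in ("upper", "lower"):
        raise ValidationError(f"which must be 'upper' or 'lower', got {which!r}")
    parts = _one(frame, lmap)
    ref = reference_distance(frame, lmap, mode)
    lip = parts[f"{which}_mid_lip"][:, 0]
    return float(_dist(lip, parts["nose_tip"][:, 0], mode)[0]) / ref


def mouth_corner(frame: LandmarkFrame, lmap: LandmarkMap, side: str,
                 mode: Mode = "2d") -> float:
    parts = _one(frame, lmap)
    ref = reference_distance(frame, lmap, mode)
    corner = parts[f"{_side(side)}_mouth_corner"][:, 0]
    return float(_dist(corner, parts["nose_tip"][:, 0], mode)[0]) / ref


def _side(side: str) -> str:
    if side in ("L", "left"):
        return "left"
    if side in ("R", "right"):
        return "right"
    raise ValidationError(f"side must be 'L' or 'R', got {side!r}")


# ---------------------------------------------------------------------------
# series-level operations
# ---------------------------------------------------------------------------

def compute_measure_series(stream: LandmarkStream, lmap: LandmarkMap,
                           section: Section = "SI+SII", mode: Mode = "2d") -> MeasureSeries:
    """All 12 measures for every retained frame of the requested section.

    Frames are retained if valid and geometrically non-degenerate; the
    measures are computed on every retained frame regardless of whether
    the expression is at baseline, transitioning or at peak.  Degenerate
    frames (zero reference, undefined fits) are dropped and counted.
    """
    frames = select_frames(stream, section)
    if not frames:
        raise EmptySeriesError(f"video {stream.video_id}: no valid frames in section {section}")
    parts = _frame_stack(frames, lmap)
    values, ref = measure_matrix(parts, mode)
    ok = (ref > _EPS) & ~np.isnan(values).any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("video %s: dropped %d degenerate frame(s)", stream.video_id, n_dropped)
    if not ok.any():
        raise EmptySeriesError(f"video {stream.video_id}: all frames degenerate")
    idx = np.array([f.frame_index for f in frames])[ok]
    df = pd.DataFrame(values[ok], columns=list(MEASURE_NAMES))
    return MeasureSeries(video_id=stream.video_id, section=section,
                         frame_indices=idx, values=df,
                         reference_distance=ref[ok], n_dropped_degenerate=n_dropped)


def moving_average(series: MeasureSeries, window: int) -> MeasureSeries:
    """Centred moving average for display (window odd; window=1 is identity).

    The series is shortened by window-1 frames; the frame indices and
    per-frame references are trimmed to the window centres.  Statistics
    downstream use unsmoothed series; smoothing is a plotting aid.
    """
    if window % 2 == 0 or window < 1:
        raise ValidationError(f"window must be an odd integer >= 1, got {window}")
    if window > len(series):
        raise ValidationError(f"window {window} exceeds series length {len(series)}")
    if window == 1:
        return series
    kernel = np.full(window, 1.0 / window)
    sm = np.column_stack([
        np.convolve(series.values[m].to_numpy(), kernel, mode="valid")
        for m in MEASURE_NAMES])
    h = (window - 1) // 2
    sl = slice(h, len(series) - h)
    return MeasureSeries(video_id=series.video_id, section=series.section,
                         frame_indices=series.frame_indices[sl],
                         values=pd.DataFrame(sm, columns=list(MEASURE_NAMES)),
                         reference_distance=series.reference_distance[sl],
                         n_dropped_degenerate=series.n_dropped_degenerate)


def mirror_frame(frame: LandmarkFrame, lmap: LandmarkMap) -> LandmarkFrame:
    """Reflect a frame across the facial midline (x -> -x, sided ids swapped).

    Used for symmetry checks: measure_L(mirror) equals measure_R(original)
    exactly when the reference landmarks are themselves symmetric.
    """
    pairs = lmap.mirror_pairs()
    new_ids = np.array([pairs.get(int(i), int(i)) for i in frame.landmark_ids], dtype=np.int64)
    coords = frame.coords.copy()
    coords[:, 0] = -coords[:, 0]
    order = np.argsort(new_ids, kind="stable")
    return LandmarkFrame(frame.frame_index, new_ids[order], coords[order], valid=frame.valid)


def write_measures_csv(series_list: list[MeasureSeries], path: str | Path) -> None:
    """Tidy CSV (video_id, section, frame_index, measure, value) for all series."""
    pd.concat([s.to_tidy() for s in series_list], ignore_index=True).to_csv(path, index=False)
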