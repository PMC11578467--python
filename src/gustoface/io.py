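"""Reading, validating and writing landmark streams and session metadata.

Two interchangeable stream formats are supported:

* long-form CSV — one row per landmark per frame with columns
  ``video_id, subject_id, frame_index, landmark_id, x, y, z, valid``.
  Frames on which the estimator failed carry a single placeholder row
  with ``landmark_id = -1`` and empty coordinates.  Section annotations
  are not part of the CSV; they travel in the session-metadata table
  (or are passed to the reader directly).
* nested JSON — one object per video embedding frames, section
  annotations, fps and ids; the full-fidelity format.

Coordinates are kept in the estimator's normalised units throughout;
all downstream measures are ratio- or angle-based, so no pixel
conversion is ever needed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import MissingLandmarkError, MissingSectionError, ParseError, ValidationError
from .maps import LandmarkMap

TASTES = ("control", "sweet", "sour", "bitter")
SEXES = ("male", "female")
#: The three randomised strip orders (the control strip always comes first).
ORDER_SEQUENCES = ("sweet-sour-bitter", "sour-bitter-sweet", "bitter-sweet-sour")

SESSION_COLUMNS = [
    "subject_id", "age", "sex", "taste", "order_sequence", "hedonic_score",
    "video_id", "si_start", "si_end", "sii_start", "sii_end",
]

Section = Literal["SI", "SII", "SI+SII"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LandmarkFrame:
    """One video frame's indexed 3D landmarks.

    ``valid=False`` marks frames on which the estimator failed (subject
    turned away, face covered); such frames may carry no coordinates.
    """

    frame_index: int
    landmark_ids: np.ndarray   # (n,) int64, unique
    coords: np.ndarray         # (n, 3) float64
    valid: bool = True

    def __post_init__(self) -> None:
        self.landmark_ids = np.asarray(self.landmark_ids, dtype=np.int64).reshape(-1)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.landmark_ids.shape[0] != self.coords.shape[0]:
            raise ValidationError("landmark_ids and coords length mismatch")
        if len(np.unique(self.landmark_ids)) != len(self.landmark_ids):
            raise ValidationError(f"duplicate landmark ids in frame {self.frame_index}")
        if self.valid and not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"non-finite coordinates in valid frame {self.frame_index}")

    def coord_of(self, landmark_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.landmark_ids == landmark_id)
        if idx.size == 0:
            raise MissingLandmarkError(landmark_id, "unknown")
        return self.coords[idx[0]]


@dataclass(frozen=True)
class SectionAnnotation:
    """Inclusive frame bounds of the tasting (SI) and post-tasting (SII) sections."""

    si_start: int
    si_end: int
    sii_start: int | None = None
    sii_end: int | None = None

    def __post_init__(self) -> None:
        if self.si_start > self.si_end:
            raise ValidationError(f"si_start {self.si_start} > si_end {self.si_end}")
        if (self.sii_start is None) != (self.sii_end is None):
            raise ValidationError("sii_start and sii_end must both be present or both absent")
        if self.sii_start is not None:
            if self.sii_start <= self.si_end:
                raise ValidationError(
                    f"sii_start {self.sii_start} must be > si_end {self.si_end}")
            if self.sii_start > self.sii_end:
                raise ValidationError(f"sii_start {self.sii_start} > sii_end {self.sii_end}")

    @property
    def has_sii(self) -> bool:
        return self.sii_start is not None

    def bounds(self, section: Section) -> list[tuple[int, int]]:
        if section == "SI":
            return [(self.si_start, self.si_end)]
        if section == "SII":
            if not self.has_sii:
                raise MissingSectionError("SII requested but not annotated")
            return [(self.sii_start, self.sii_end)]
        if section == "SI+SII":
            out = [(self.si_start, self.si_end)]
            if self.has_sii:
                out.append((self.sii_start, self.sii_end))
            return out
        raise ValidationError(f"unknown section {section!r}")


@dataclass
class LandmarkStream:
    """Ordered landmark frames of one tasting video, with section annotations."""

    video_id: str
    subject_id: str
    frames: list[LandmarkFrame]
    sections: SectionAnnotation
    fps: float | None = None

    def __post_init__(self) -> None:
        idx = np.array([f.frame_index for f in self.frames])
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValidationError(f"frame_index not strictly increasing in {self.video_id}")
        if self.fps is not None and self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if idx.size:
            lo, hi = idx[0], idx[-1]
            s = self.sections
            for a, b in [(s.si_start, s.si_end)] + ([(s.sii_start, s.sii_end)] if s.has_sii else []):
                if a < lo or b > hi:
                    raise ValidationError(
                        f"section bounds [{a},{b}] outside frame range [{lo},{hi}] "
                        f"of video {self.video_id}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def valid_fraction(self) -> float:
        """Exact fraction of frames with valid=True (1.0 for an empty stream)."""
        if not self.frames:
            return 1.0
        return sum(f.valid for f in self.frames) / len(self.frames)


@dataclass
class SessionRecord:
    """One (subject, taste) session: demographics, outcome and video linkage."""

    subject_id: str
    age: int
    sex: str
    taste: str
    order_sequence: str
    hedonic_score: int
    video_id: str | None = None
    sections: SectionAnnotation | None = None

    def __post_init__(self) -> None:
        if not 4 <= self.age <= 11:
            raise ValidationError(f"age {self.age} outside [4, 11] for {self.subject_id}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.taste not in TASTES:
            raise ValidationError(f"unknown taste {self.taste!r}")
        if self.order_sequence not in ORDER_SEQUENCES:
            raise ValidationError(f"unknown order_sequence {self.order_sequence!r}")
        if not 1 <= self.hedonic_score <= 5:
            raise ValidationError(
                f"hedonic_score {self.hedonic_score} outside 1-5 for {self.subject_id}")


# ---------------------------------------------------------------------------
# stream I/O
# ---------------------------------------------------------------------------

def write_landmark_stream(stream: LandmarkStream, path: str | Path,
                          format: Literal["csv", "json"] = "json") -> None:
    """Serialise a stream; the output round-trips through :func:`read_landmark_stream`."""
    path = Path(path)
    if format == "json":
        obj = {
            "video_id": stream.video_id,
            "subject_id": stream.subject_id,
            "fps": stream.fps,
            "sections": {
                "si_start": stream.sections.si_start,
                "si_end": stream.sections.si_end,
                "sii_start": stream.sections.sii_start,
                "sii_end": stream.sections.sii_end,
            },
            "frames": [
                {
                    "frame_index": f.frame_index,
                    "valid": bool(f.valid),
                    "landmarks": [
                        [int(i), float(x), float(y), float(z)]
                        for i, (x, y, z) in zip(f.landmark_ids.tolist(), f.coords.tolist())
                    ],
                }
                for f in stream.frames
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)
            fh.write("\n")
    elif format == "csv":
        rows = []
        for f in stream.frames:
            if f.landmark_ids.size == 0:
                rows.append((stream.video_id, stream.subject_id, f.frame_index,
                             -1, "", "", "", f.valid))
            else:
                for i, (x, y, z) in zip(f.landmark_ids.tolist(), f.coords.tolist()):
                    rows.append((stream.video_id, stream.subject_id, f.frame_index,
                                 i, repr(x), repr(y), repr(z), f.valid))
        df = pd.DataFrame(rows, columns=["video_id", "subject_id", "frame_index",
                                         "landmark_id", "x", "y", "z", "valid"])
        df.to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown stream format {format!r}")


def read_landmark_stream(path: str | Path, format: Literal["csv", "json"] = "json",
                         sections: SectionAnnotation | None = None,
                         fps: float | None = None) -> LandmarkStream:
    """Read a landmark stream.

    For the CSV format, which does not carry section annotations, pass
    ``sections`` explicitly (typically taken from the session table).
    """
    path = Path(path)
    if format == "json":
        try:
            with open(path) as fh:
                obj = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
        sec = obj.get("sections") or {}
        try:
            ann = SectionAnnotation(
                si_start=int(sec["si_start"]), si_end=int(sec["si_end"]),
                sii_start=None if sec.get("sii_start") is None else int(sec["sii_start"]),
                sii_end=None if sec.get("sii_end") is None else int(sec["sii_end"]),
            )
        except KeyError as e:
            raise ParseError(f"{path}: sections object missing key {e}") from e
        frames = []
        for k, fr in enumerate(obj.get("frames", [])):
            try:
                lm = fr.get("landmarks", [])
                ids = [int(r[0]) for r in lm]
                xyz = [[float(r[1]), float(r[2]), float(r[3])] for r in lm]
                frames.append(LandmarkFrame(
                    frame_index=int(fr["frame_index"]),
                    landmark_ids=np.array(ids, dtype=np.int64),
                    coords=np.array(xyz, dtype=np.float64).reshape(-1, 3),
                    valid=bool(fr["valid"]),
                ))
            except (KeyError, TypeError, IndexError, ValueError) as e:
                raise ParseError(f"{path}: malformed frame object #{k}: {e}") from e
        frames.sort(key=lambda f: f.frame_index)
        return LandmarkStream(video_id=str(obj["video_id"]),
                              subject_id=str(obj.get("subject_id", "")),
                              frames=frames, sections=ann,
                              fps=obj.get("fps") if fps is None else fps)

    if format == "csv":
        if sections is None:
            raise ValidationError("CSV streams carry no section annotations; pass sections=")
        try:
            df = pd.read_csv(path, dtype={"video_id": str, "subject_id": str},
                             float_precision="round_trip")
        except Exception as e:  # pandas raises several parser error types
            raise ParseError(f"{path}: {e}") from e
        required = {"video_id", "subject_id", "frame_index", "landmark_id", "x", "y", "z", "valid"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for col in ("frame_index", "landmark_id"):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                # +2: 1-based line numbers plus the header line
                raise ParseError(f"{path}: non-integer {col} at line {bad.idxmax() + 2}")
        video_ids = df["video_id"].unique()
        if len(video_ids) != 1:
            raise ParseError(f"{path}: expected one video per CSV, found {list(video_ids)}")
        subject_ids = df["subject_id"].unique()
        frames = []
        for fi, grp in df.groupby("frame_index", sort=True):
            valid = bool(grp["valid"].iloc[0])
            if (grp["landmark_id"] == -1).all():
                frames.append(LandmarkFrame(int(fi), np.empty(0, dtype=np.int64),
                                            np.empty((0, 3)), valid=valid))
            else:
                try:
                    coords = grp[["x", "y", "z"]].to_numpy(dtype=np.float64)
                except ValueError as e:
                    raise ParseError(f"{path}: non-numeric coordinate in frame {fi}: {e}") from e
                frames.append(LandmarkFrame(int(fi), grp["landmark_id"].to_numpy(np.int64),
                                            coords, valid=valid))
        return LandmarkStream(video_id=str(video_ids[0]), subject_id=str(subject_ids[0]),
                              frames=frames, sections=sections, fps=fps)

    raise ValidationError(f"unknown stream format {format!r}")


# ---------------------------------------------------------------------------
# session metadata
# ---------------------------------------------------------------------------

def _opt_int(v) -> int | None:
    if v is None or (pd.isna(v) if not isinstance(v, str) else v == ""):
        return None
    return int(v)


def read_session_table(path: str | Path) -> list[SessionRecord]:
    """Read and validate the session-metadata CSV (one row per subject×taste)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "video_id": str})
    except Exception as e:
        raise ParseError(f"{path}: {e}") from e
    missing = set(SESSION_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records: list[SessionRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        line = i + 2
        try:
            video_id = row.get("video_id")
            if pd.isna(video_id) or video_id == "":
                video_id = None
            sections = None
            if video_id is not None and _opt_int(row.get("si_start")) is not None:
                sections = SectionAnnotation(
                    si_start=int(row["si_start"]), si_end=int(row["si_end"]),
                    sii_start=_opt_int(row.get("sii_start")),
                    sii_end=_opt_int(row.get("sii_end")))
            rec = SessionRecord(
                subject_id=str(row["subject_id"]), age=int(row["age"]),
                sex=str(row["sex"]), taste=str(row["taste"]),
                order_sequence=str(row["order_sequence"]),
                hedonic_score=int(row["hedonic_score"]),
                video_id=video_id, sections=sections)
        except ValidationError as e:
            raise ValidationError(f"{path} line {line}: {e}") from e
        except (TypeError, ValueError) as e:
            raise ParseError(f"{path} line {line}: {e}") from e
        key = (rec.subject_id, rec.taste)
        if key in seen:
            raise ValidationError(f"{path} line {line}: duplicate (subject, taste) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_session_table(records: Iterable[SessionRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        s = r.sections
        rows.append({
            "subject_id": r.subject_id, "age": r.age, "sex": r.sex, "taste": r.taste,
            "order_sequence": r.order_sequence, "hedonic_score": r.hedonic_score,
            "video_id": "" if r.video_id is None else r.video_id,
            "si_start": "" if s is None else s.si_start,
            "si_end": "" if s is None else s.si_end,
            "sii_start": "" if s is None or s.sii_start is None else s.sii_start,
            "sii_end": "" if s is None or s.sii_end is None else s.sii_end,
        })
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# frame selection and landmark subsetting
# ---------------------------------------------------------------------------

def select_frames(stream: LandmarkStream, section: Section) -> list[LandmarkFrame]:
    """Valid frames inside the requested section's inclusive bounds, in order.

    Raises :class:`MissingSectionError` if SII is requested but absent
    (SI+SII falls back to SI alone when SII is absent).
    """
    bounds = stream.sections.bounds(section)
    out = []
    for f in stream.frames:
        if f.valid and any(a <= f.frame_index <= b for a, b in bounds):
            out.append(f)
    return out


def subset_landmarks(frame: LandmarkFrame, lmap: LandmarkMap) -> LandmarkFrame:
    """Restrict a frame to exactly the map's landmark ids (in map order)."""
    pos = {int(i): k for k, i in enumerate(frame.landmark_ids)}
    idx = []
    for region, ids in lmap.regions().items():
        for i in ids:
            if i not in pos:
                raise MissingLandmarkError(i, region)
            idx.append(pos[i])
    idx = np.array(idx, dtype=np.intp)
    return LandmarkFrame(frame.frame_index, frame.landmark_ids[idx],
                         frame.coords[idx], valid=frame.valid)
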