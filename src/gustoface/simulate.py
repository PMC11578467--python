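"""Synthetic landmark streams and hedonic cohorts with known ground truth.

The generator emulates the data-generating structure of a remote
taste-strip session: a neutral symmetric face template, taste-dependent
expression events that displace landmark regions, rigid head motion
(translation/rotation random walks and smooth scale drift), isotropic
landmark noise, and estimator drop-out frames.  Every video is fully
determined by its seed, and the realised events are recorded in a
:class:`CohortTruth` so recovery tests can check the pipeline against
known effect sizes.

Amplitudes are expressed as fractions of the template's inter-ocular
distance, the conventional normalisation for face-mesh geometry.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import study
from .errors import ValidationError
from .io import (LandmarkFrame, LandmarkStream, ORDER_SEQUENCES, SectionAnnotation,
                 SessionRecord, TASTES)
from .maps import LandmarkMap, default_map

EVENT_REGIONS = ("eyebrow_L", "eyebrow_R", "mouth_corner_L", "mouth_corner_R",
                 "upper_lip", "lower_lip", "eye_L", "eye_R")
PROFILES = ("ramp", "pulse", "sustained")


# ---------------------------------------------------------------------------
# neutral face template
# ---------------------------------------------------------------------------

def neutral_face_template(lmap: LandmarkMap | None = None) -> LandmarkFrame:
    """Symmetric neutral face in normalised coordinates (nose tip at origin).

    Eyebrows arch above elliptical eye contours; the mouth sits below
    the nose.  The layout is mirror-symmetric across the midline x = 0
    to machine precision, with equal left/right apertures.
    """
    lmap = lmap or default_map()
    coords: dict[int, tuple[float, float, float]] = {}

    def place(ids: Sequence[int], pts: np.ndarray) -> None:
        for i, p in zip(ids, pts):
            coords[int(i)] = (float(p[0]), float(p[1]), float(p[2]))

    # left side constructed explicitly; right side mirrored positionally
    t = np.linspace(0.0, 1.0, 5)
    brow_left = np.column_stack([-(0.10 + 0.20 * t),
                                 0.27 + 0.06 * np.sin(np.pi * t),
                                 np.full(5, 0.005)])
    brow_right = brow_left * np.array([-1.0, 1.0, 1.0])
    place(lmap.left_eyebrow, brow_left)
    place(lmap.right_eyebrow, brow_right)

    k = len(lmap.left_eye_contour)
    ang = 2 * np.pi * (np.arange(k) + 0.5) / k
    eye_left = np.column_stack([-0.21 + 0.085 * np.cos(ang),
                                0.18 + 0.040 * np.sin(ang),
                                np.full(k, 0.01)])
    eye_right = eye_left * np.array([-1.0, 1.0, 1.0])
    place(lmap.left_eye_contour, eye_left)
    place(lmap.right_eye_contour, eye_right)

    coords[lmap.nose_tip] = (0.0, 0.0, -0.06)
    coords[lmap.left_inner_eye_corner] = (-0.115, 0.175, 0.0)
    coords[lmap.right_inner_eye_corner] = (0.115, 0.175, 0.0)
    coords[lmap.left_mouth_corner] = (-0.19, -0.28, 0.0)
    coords[lmap.right_mouth_corner] = (0.19, -0.28, 0.0)
    coords[lmap.upper_mid_lip] = (0.0, -0.24, -0.01)
    coords[lmap.lower_mid_lip] = (0.0, -0.33, -0.01)

    ids = np.array(sorted(coords), dtype=np.int64)
    xyz = np.array([coords[int(i)] for i in ids], dtype=np.float64)
    return LandmarkFrame(frame_index=0, landmark_ids=ids, coords=xyz, valid=True)


def interocular_distance(lmap: LandmarkMap, template: LandmarkFrame | None = None) -> float:
    """Distance between the left and right eye-contour centroids (x-y plane)."""
    template = template or neutral_face_template(lmap)
    pos = {int(i): template.coords[k] for k, i in enumerate(template.landmark_ids)}
    cl = np.mean([pos[i][:2] for i in lmap.left_eye_contour], axis=0)
    cr = np.mean([pos[i][:2] for i in lmap.right_eye_contour], axis=0)
    return float(np.linalg.norm(cr - cl))


# ---------------------------------------------------------------------------
# events and parameters
# ---------------------------------------------------------------------------

@dataclass
class ExpressionEvent:
    """One localised expression excursion on a landmark region."""

    region: str
    onset: int
    duration: int
    amplitude: float              # fraction of inter-ocular distance
    profile: str = "pulse"

    def __post_init__(self) -> None:
        if self.region not in EVENT_REGIONS:
            raise ValidationError(f"unknown event region {self.region!r}")
        if self.duration < 1:
            raise ValidationError("event duration must be >= 1 frame")
        if self.profile not in PROFILES:
            raise ValidationError(f"unknown profile {self.profile!r}")
        if not np.isfinite(self.amplitude):
            raise ValidationError("event amplitude must be finite")

    def envelope(self, n_frames: int) -> np.ndarray:
        """Activation in [0, 1] per frame."""
        env = np.zeros(n_frames)
        lo = max(self.onset, 0)
        hi = min(self.onset + self.duration, n_frames)
        if hi <= lo:
            return env
        u = (np.arange(lo, hi) - self.onset) / self.duration
        if self.profile == "ramp":
            env[lo:hi] = u
        elif self.profile == "pulse":
            env[lo:hi] = 1.0 - np.abs(2.0 * u - 1.0)
        else:  # sustained
            env[lo:hi] = 1.0
        return env


@dataclass
class MotionParams:
    """Rigid-motion nuisance parameters (per-frame random-walk steps)."""

    translation_step: float = 0.002   # normalised units per frame
    rotation_step: float = 0.2       # degrees per frame
    scale_step: float = 0.002         # relative log-scale per frame

    @classmethod
    def off(cls) -> "MotionParams":
        return cls(0.0, 0.0, 0.0)


@dataclass
class NoiseParams:
    """Landmark noise and estimator drop-out.

    The nose tip and inner eye corners sit on semi-rigid facial anatomy
    and are tracked far more stably than deformable regions — the very
    reason they serve as the scaling reference — so their jitter is
    scaled down by ``reference_sigma_factor``.
    """

    sigma: float = 0.002              # isotropic Gaussian SD, normalised units
    dropout: float = study.FRAME_DROPOUT
    reference_sigma_factor: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.reference_sigma_factor < 0:
            raise ValidationError("reference_sigma_factor must be >= 0")


@dataclass
class HedonicModel:
    """Per-taste distribution of the 5-point hedonic score.

    Defaults encode the expected pattern: control peaked at 3, sweet at
    5, bitter at 1, and a dispersed (near-uniform) sour distribution.
    """

    probs: dict = field(default_factory=lambda: {
        "control": [0.05, 0.15, 0.45, 0.25, 0.10],
        "sweet":   [0.02, 0.03, 0.10, 0.25, 0.60],
        "bitter":  [0.55, 0.20, 0.12, 0.08, 0.05],
        "sour":    [0.22, 0.18, 0.20, 0.18, 0.22],
    })

    def __post_init__(self) -> None:
        for taste in TASTES:
            p = np.asarray(self.probs[taste], dtype=float)
            if p.shape != (5,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValidationError(f"invalid score distribution for {taste!r}")

    def sample(self, taste: str, rng: np.random.Generator) -> int:
        return int(rng.choice(np.arange(1, 6), p=np.asarray(self.probs[taste], float)))

    @classmethod
    def degenerate(cls, score: int = 3) -> "HedonicModel":
        p = [0.0] * 5
        p[score - 1] = 1.0
        return cls(probs={t: list(p) for t in TASTES})


#: Default per-taste event-amplitude profiles (fractions of inter-ocular
#: distance).  They loosely encode the observed pattern — bitter drives
#: lower-lip activity, sweet drives a brow raise with the observer-right
#: side stronger — but are configuration, not hard-coded truth.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "control": {"eyebrow_R": 0.02, "eyebrow_L": 0.02, "lower_lip": 0.02,
                "mouth_corner_L": 0.02, "mouth_corner_R": 0.02},
    "sweet":   {"eyebrow_R": 0.14, "eyebrow_L": 0.10, "mouth_corner_L": 0.06,
                "mouth_corner_R": 0.06, "lower_lip": 0.03},
    "sour":    {"eyebrow_R": 0.05, "eyebrow_L": 0.05, "eye_L": 0.10, "eye_R": 0.10,
                "mouth_corner_L": 0.08, "mouth_corner_R": 0.08, "upper_lip": 0.05},
    "bitter":  {"lower_lip": 0.14, "upper_lip": 0.08, "eyebrow_R": 0.05,
                "eyebrow_L": 0.05, "mouth_corner_L": 0.04, "mouth_corner_R": 0.04},
}


def eyebrow_only_effects(amplitudes: dict[str, float] | None = None,
                         lr_ratio: float = 0.7) -> dict[str, dict[str, float]]:
    """Effect profiles in which only eyebrow-raise amplitude varies by taste.

    Both brows are driven by the same events with the observer-right
    side at full class amplitude and the left at ``lr_ratio`` of it, so
    eyebrow elevation is the sole class-informative measure.
    """
    amplitudes = amplitudes or {"control": 0.0, "sweet": 0.14, "sour": 0.05, "bitter": 0.10}
    return {t: {"eyebrow_R": a, "eyebrow_L": lr_ratio * a} for t, a in amplitudes.items()}


@dataclass
class SubjectTruth:
    subject_id: str
    age: int
    sex: str
    order_sequence: str
    amplitude_scale: float        # subject-level random effect (lognormal)
    effects: dict                 # taste -> region -> amplitude


@dataclass
class VideoTruth:
    video_id: str
    subject_id: str
    taste: str
    seed: int
    events: list[ExpressionEvent]
    dropped_frames: list[int]


@dataclass
class CohortTruth:
    """Everything needed to regenerate and to verify a synthetic cohort."""

    master_seed: int
    n_si: int = study.DEFAULT_SI_FRAMES
    n_sii: int = study.DEFAULT_SII_FRAMES
    fps: float = study.DEFAULT_FPS
    motion: MotionParams = field(default_factory=MotionParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    subjects: dict = field(default_factory=dict)   # subject_id -> SubjectTruth
    videos: dict = field(default_factory=dict)     # video_id -> VideoTruth

    def to_json(self, path: str | Path) -> None:
        obj = asdict(self)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# stream rendering
# ---------------------------------------------------------------------------

def _event_ids(lmap: LandmarkMap) -> dict[str, tuple[int, ...]]:
    return {
        "eyebrow_L": lmap.left_eyebrow, "eyebrow_R": lmap.right_eyebrow,
        "mouth_corner_L": (lmap.left_mouth_corner,),
        "mouth_corner_R": (lmap.right_mouth_corner,),
        "upper_lip": (lmap.upper_mid_lip,), "lower_lip": (lmap.lower_mid_lip,),
        "eye_L": lmap.left_eye_contour, "eye_R": lmap.right_eye_contour,
    }


def render_stream(events: Sequence[ExpressionEvent], *, video_id: str, subject_id: str,
                  lmap: LandmarkMap | None = None, n_si: int = study.DEFAULT_SI_FRAMES,
                  n_sii: int = study.DEFAULT_SII_FRAMES,
                  motion: MotionParams | None = None, noise: NoiseParams | None = None,
                  fps: float = study.DEFAULT_FPS, seed: int = 0,
                  ) -> tuple[LandmarkStream, list[int]]:
    """Render a landmark stream from explicit events; returns (stream, dropped).

    Frame composition per frame t: template + event displacements, then
    a similarity transform (scale drift x in-plane rotation + translation
    walks), then isotropic Gaussian noise.  A Bernoulli(dropout) subset
    of frames is emitted as invalid with no coordinates, emulating
    estimator failures.  Deterministic given the seed.
    """
    lmap = lmap or default_map()
    motion = motion or MotionParams.off()
    noise = noise or NoiseParams(sigma=0.0, dropout=0.0)
    rng = np.random.default_rng(seed)
    template = neutral_face_template(lmap)
    iod = interocular_distance(lmap, template)
    n = n_si + n_sii
    ids = template.landmark_ids
    pos = {int(i): k for k, i in enumerate(ids)}
    base = np.broadcast_to(template.coords, (n,) + template.coords.shape).copy()

    region_ids = _event_ids(lmap)
    for ev in events:
        env = ev.envelope(n) * ev.amplitude * iod
        rows = np.array([pos[int(i)] for i in region_ids[ev.region]], dtype=np.intp)
        if ev.region in ("eyebrow_L", "eyebrow_R"):
            base[:, rows, 1] += env[:, None]                      # brow raise
        elif ev.region in ("mouth_corner_L", "mouth_corner_R"):
            sign = -1.0 if ev.region.endswith("L") else 1.0
            base[:, rows, 0] += 0.6 * sign * env[:, None]         # lateral pull
            base[:, rows, 1] -= 0.8 * env[:, None]                # downward pull
        elif ev.region == "upper_lip":
            base[:, rows, 1] += env[:, None]                      # raise toward nose
        elif ev.region == "lower_lip":
            base[:, rows, 1] -= env[:, None]                      # depress
        else:  # eye squint: contract contour toward its centroid
            centroid = base[:, rows, :].mean(axis=1, keepdims=True)
            # amplitude read as the relative contraction fraction, not a distance
            shrink = np.clip(ev.envelope(n) * ev.amplitude, 0.0, 0.95)
            base[:, rows, :] = centroid + (1.0 - shrink[:, None, None]) \
                * (base[:, rows, :] - centroid)

    # landmark noise is applied in face coordinates, before the rigid motion,
    # because estimator error scales with the face (it is quoted relative to
    # inter-ocular distance); this keeps measure SDs motion-independent
    if noise.sigma > 0:
        sig = np.full(len(ids), noise.sigma)
        stable = [pos[lmap.nose_tip], pos[lmap.left_inner_eye_corner],
                  pos[lmap.right_inner_eye_corner]]
        sig[stable] *= noise.reference_sigma_factor
        base = base + rng.normal(0.0, 1.0, base.shape) * sig[None, :, None]

    # rigid motion: smooth random walks in translation/rotation, log-scale drift
    trans = np.cumsum(rng.normal(0.0, motion.translation_step, (n, 2)), axis=0) \
        if motion.translation_step > 0 else np.zeros((n, 2))
    rot = np.cumsum(rng.normal(0.0, np.radians(motion.rotation_step), n)) \
        if motion.rotation_step > 0 else np.zeros(n)
    scale = np.exp(np.cumsum(rng.normal(0.0, motion.scale_step, n))) \
        if motion.scale_step > 0 else np.ones(n)
    c, s = np.cos(rot), np.sin(rot)
    xy = base[..., :2]
    xr = c[:, None] * xy[..., 0] - s[:, None] * xy[..., 1]
    yr = s[:, None] * xy[..., 0] + c[:, None] * xy[..., 1]
    out = base.copy()
    out[..., 0] = scale[:, None] * xr + trans[:, None, 0]
    out[..., 1] = scale[:, None] * yr + trans[:, None, 1]
    out[..., 2] = scale[:, None] * base[..., 2]

    drop_mask = rng.random(n) < noise.dropout
    dropped = np.flatnonzero(drop_mask).tolist()
    frames = []
    for t in range(n):
        if drop_mask[t]:
            frames.append(LandmarkFrame(t, np.empty(0, dtype=np.int64),
                                        np.empty((0, 3)), valid=False))
        else:
            frames.append(LandmarkFrame(t, ids.copy(), out[t], valid=True))
    sections = SectionAnnotation(si_start=0, si_end=n_si - 1,
                                 sii_start=n_si if n_sii else None,
                                 sii_end=n - 1 if n_sii else None)
    stream = LandmarkStream(video_id=video_id, subject_id=subject_id,
                            frames=frames, sections=sections, fps=fps)
    return stream, dropped


#: L/R region pairs whose events are bilateral (shared timing and profile,
#: per-side amplitude): brow raises, smiles/grimaces and squints engage
#: both sides of the face together.
BILATERAL_GROUPS = (("eyebrow_L", "eyebrow_R"),
                    ("mouth_corner_L", "mouth_corner_R"),
                    ("eye_L", "eye_R"))


def sample_events(effects: dict[str, float], amplitude_scale: float, n_si: int,
                  n_sii: int, rng: np.random.Generator) -> list[ExpressionEvent]:
    """Draw expression events for one video given region amplitudes.

    Sided regions of a bilateral group fire together: one drawn event
    produces an :class:`ExpressionEvent` per active side, sharing onset,
    duration, profile and realisation noise, scaled by each side's
    amplitude.  Midline regions (lips) are drawn independently.
    """
    n = n_si + n_sii
    grouped: list[tuple[tuple[str, ...], tuple[float, ...]]] = []
    paired = {r for grp in BILATERAL_GROUPS for r in grp}
    for grp in BILATERAL_GROUPS:
        amps = tuple(effects.get(r, 0.0) for r in grp)
        if any(a > 0 for a in amps):
            grouped.append((grp, amps))
    for region, amp in effects.items():
        if region not in paired and amp > 0:
            grouped.append(((region,), (amp,)))

    events: list[ExpressionEvent] = []
    for regions, amps in grouped:
        for _ in range(2 + int(rng.integers(0, 2))):
            in_si = rng.random() < 0.7
            onset = int(rng.integers(0, max(n_si - 20, 1))) if in_si \
                else int(rng.integers(n_si, max(n - 20, n_si + 1)))
            duration = int(rng.integers(30, 91))
            profile = PROFILES[int(rng.integers(0, 3))]
            wobble = float(rng.lognormal(0.0, 0.25))
            for region, amp in zip(regions, amps):
                if amp <= 0:
                    continue
                events.append(ExpressionEvent(
                    region=region, onset=onset, duration=duration,
                    amplitude=amp * amplitude_scale * wobble, profile=profile))
    return events


def generate_stream(truth: CohortTruth, subject_id: str, taste: str, seed: int,
                    lmap: LandmarkMap | None = None,
                    ) -> tuple[LandmarkStream, list[ExpressionEvent]]:
    """Generate one video for a subject/taste under a cohort's parameters."""
    sub = truth.subjects[subject_id]
    effects = sub.effects.get(taste, {}) if isinstance(sub, SubjectTruth) \
        else sub["effects"].get(taste, {})
    scale = sub.amplitude_scale if isinstance(sub, SubjectTruth) else sub["amplitude_scale"]
    rng = np.random.default_rng(seed)
    events = sample_events(effects, scale, truth.n_si, truth.n_sii, rng)
    video_id = f"{subject_id}_{taste}"
    stream, dropped = render_stream(
        events, video_id=video_id, subject_id=subject_id, lmap=lmap,
        n_si=truth.n_si, n_sii=truth.n_sii, motion=truth.motion, noise=truth.noise,
        fps=truth.fps, seed=int(rng.integers(0, 2**31 - 1)))
    truth.videos[video_id] = VideoTruth(video_id=video_id, subject_id=subject_id,
                                        taste=taste, seed=seed, events=events,
                                        dropped_frames=dropped)
    return stream, events


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    streams: list[LandmarkStream]
    records: list[SessionRecord]
    truth: CohortTruth


def generate_cohort(n_subjects: int, hedonic: HedonicModel | None = None,
                    effects: dict[str, dict[str, float]] | None = None,
                    seed: int = 0, lmap: LandmarkMap | None = None,
                    motion: MotionParams | None = None, noise: NoiseParams | None = None,
                    n_si: int = study.DEFAULT_SI_FRAMES,
                    n_sii: int = study.DEFAULT_SII_FRAMES,
                    subject_sd: float = 0.2) -> Cohort:
    """Generate a full cohort: one control + three taste videos per subject.

    Ages are drawn from the study's age-frequency table, sex from its
    observed split, strip order uniformly from the three randomised
    sequences, and hedonic scores from the per-taste model.  Fully
    reproducible from the seed.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    hedonic = hedonic or HedonicModel()
    effects = effects if effects is not None else DEFAULT_EFFECTS
    rng = np.random.default_rng(seed)
    truth = CohortTruth(master_seed=seed, n_si=n_si, n_sii=n_sii,
                        motion=motion or MotionParams(), noise=noise or NoiseParams())
    ages = np.array(list(study.AGE_FREQUENCIES.keys()))
    age_p = np.array(list(study.AGE_FREQUENCIES.values()), dtype=float)
    age_p /= age_p.sum()
    p_female = study.SEX_COUNTS["female"] / sum(study.SEX_COUNTS.values())

    streams: list[LandmarkStream] = []
    records: list[SessionRecord] = []
    for j in range(n_subjects):
        sid = f"S{j:03d}"
        sub = SubjectTruth(
            subject_id=sid,
            age=int(rng.choice(ages, p=age_p)),
            sex="female" if rng.random() < p_female else "male",
            order_sequence=ORDER_SEQUENCES[int(rng.integers(0, 3))],
            amplitude_scale=float(rng.lognormal(0.0, subject_sd)),
            effects={t: dict(effects.get(t, {})) for t in TASTES})
        truth.subjects[sid] = sub
        taste_order = ["control"] + sub.order_sequence.split("-")
        for taste in taste_order:
            vseed = int(rng.integers(0, 2**31 - 1))
            stream, _ = generate_stream(truth, sid, taste, vseed, lmap=lmap)
            streams.append(stream)
            records.append(SessionRecord(
                subject_id=sid, age=sub.age, sex=sub.sex, taste=taste,
                order_sequence=sub.order_sequence,
                hedonic_score=hedonic.sample(taste, rng),
                video_id=stream.video_id, sections=stream.sections))
    return Cohort(streams=streams, records=records, truth=truth)
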