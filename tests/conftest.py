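import numpy as np
import pytest

from gustoface.io import LandmarkFrame, LandmarkStream, SectionAnnotation
from gustoface.maps import default_map
from gustoface.simulate import neutral_face_template


@pytest.fixture(scope="session")
def lmap():
    return default_map()


@pytest.fixture(scope="session")
def template(lmap):
    return neutral_face_template(lmap)


@pytest.fixture
def random_frame_factory(lmap):
    """Frames with standard-normal coordinates on all map ids.

    With ``symmetric_reference=True`` the nose tip sits on the midline and
    the inner eye corners mirror each other, so reflection symmetry of the
    rescaled measures is exact.
    """

    def make(rng: np.random.Generator, symmetric_reference: bool = False) -> LandmarkFrame:
        ids = np.array(lmap.all_ids(), dtype=np.int64)
        coords = rng.standard_normal((len(ids), 3))
        if symmetric_reference:
            pos = {int(i): k for k, i in enumerate(ids)}
            coords[pos[lmap.nose_tip], 0] = 0.0
            li, ri = pos[lmap.left_inner_eye_corner], pos[lmap.right_inner_eye_corner]
            coords[ri] = coords[li] * np.array([-1.0, 1.0, 1.0])
        return LandmarkFrame(frame_index=0, landmark_ids=ids, coords=coords)

    return make


@pytest.fixture
def constant_stream_factory(template):
    """Streams repeating the neutral template over annotated SI/SII sections."""

    def make(n_si: int = 10, n_sii: int = 10, invalid: set[int] = frozenset(),
             video_id: str = "v0", subject_id: str = "s0") -> LandmarkStream:
        n = n_si + n_sii
        frames = []
        for t in range(n):
            if t in invalid:
                frames.append(LandmarkFrame(t, np.empty(0, dtype=np.int64),
                                            np.empty((0, 3)), valid=False))
            else:
                frames.append(LandmarkFrame(t, template.landmark_ids.copy(),
                                            template.coords.copy(), valid=True))
        sections = SectionAnnotation(si_start=0, si_end=n_si - 1,
                                     sii_start=n_si if n_sii else None,
                                     sii_end=n - 1 if n_sii else None)
        return LandmarkStream(video_id=video_id, subject_id=subject_id,
                              frames=frames, sections=sections, fps=30.0)

    return make
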