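"""Published study-design constants used as generator defaults and test inputs.

These are the printed bookkeeping values of the reference taste-strip
study: the age-frequency distribution of the 64 analysed participants,
the sex split, the per-taste counts of hedonic ratings and analysable
videos, and the estimator's frame success rate.  The synthetic cohort
generator samples from these distributions by default so simulated
cohorts match the study's composition.
"""

#: Age (years) -> number of participants (n = 64).
AGE_FREQUENCIES = {5: 1, 6: 3, 7: 10, 8: 18, 9: 13, 10: 11, 11: 8}

#: Subject counts by sex.
SEX_COUNTS = {"female": 36, "male": 28}

#: Hedonic-scale ratings received per taste strip (all 64 subjects rated all strips).
HEDONIC_SCALES_PER_TASTE = {"control": 64, "sour": 64, "sweet": 64, "bitter": 64}

#: Analysable videos received per taste strip (197 in total).
VIDEOS_PER_TASTE = {"control": 51, "sour": 46, "sweet": 54, "bitter": 46}

#: Fraction of frames the face-mesh estimator failed to process.
FRAME_DROPOUT = 0.026

#: Default frames per video: ~10 s tasting section plus a post-tasting
#: section at 30 fps, matching the study's mean of ~485 processed
#: frames per video.
DEFAULT_FPS = 30.0
DEFAULT_SI_FRAMES = 300
DEFAULT_SII_FRAMES = 185
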