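{
  "_comment": "Default 53-landmark subset of a dense face-mesh (368+ point) estimator output. Indices follow MediaPipe face-mesh conventions for the brows, nose tip, inner eye corners, mouth corners and mid lips; the 18-point eye-contour rings are assembled from MediaPipe eye-region indices. The published study does not list its 53 indices, so this map is an approximation of the regions it outlines and is editable data, not code. Left/right is from the observer's point of view.",
  "left_eyebrow": [107, 66, 105, 63, 70],
  "right_eyebrow": [336, 296, 334, 293, 300],
  "left_eye_contour": [226, 130, 25, 110, 24, 23, 22, 26, 112, 243, 244, 190, 56, 28, 27, 29, 30, 247],
  "right_eye_contour": [446, 359, 255, 339, 254, 253, 252, 256, 341, 463, 464, 414, 286, 258, 257, 259, 260, 467],
  "nose_tip": 1,
  "left_inner_eye_corner": 133,
  "right_inner_eye_corner": 362,
  "left_mouth_corner": 61,
  "right_mouth_corner": 291,
  "upper_mid_lip": 13,
  "lower_mid_lip": 14
}
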