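"""Canonical label orders shared across the package.

The expression classes follow the seven universal facial expressions in the
fixed order used everywhere probabilities are serialized.  The body keypoints
follow the COCO 18-joint layout (index 0 = nose .. index 17 = left ear).
"""

from __future__ import annotations

EXPRESSION_LABELS: tuple[str, ...] = (
    "angry",
    "disgust",
    "fear",
    "happy",
    "sad",
    "surprise",
    "neutral",
)
N_EXPRESSIONS = len(EXPRESSION_LABELS)
SAD_INDEX = EXPRESSION_LABELS.index("sad")

KEYPOINT_LABELS: tuple[str, ...] = (
    "nose",
    "neck",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
    "right_eye",
    "left_eye",
    "right_ear",
    "left_ear",
)
N_KEYPOINTS = len(KEYPOINT_LABELS)

# head-region joints keep a residual fidget even when gross movement stops
HEAD_JOINTS: tuple[int, ...] = (0, 1, 14, 15, 16, 17)
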