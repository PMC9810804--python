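"""Perception front-end contracts.

The metric layer downstream consumes two per-frame streams: a 7-class facial
expression probability vector and an 18-joint body pose.  This module pins down
the contracts those streams must satisfy and ships two concrete pieces:

* a shape-checked specification of the expression-recognition CNN (a stack of
  eight convolution blocks over a 48x48 grayscale face crop, ending in
  dropout / fully-connected / softmax over the 7 classes), usable to validate
  any externally trained weight file before it is plugged in; and
* a deterministic mock backend parameterized by a severity profile, so the
  whole pipeline runs and is testable without trained weights or video.

Trained weights, face detection and pose estimation themselves are pluggable:
any object implementing :class:`InferenceBackend` can drive the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import ValidationError
from .labels import EXPRESSION_LABELS, N_KEYPOINTS

__all__ = [
    "ExpressionLabel",
    "EXPRESSION_LABEL_SET",
    "LayerSpec",
    "ArchitectureSpec",
    "FaceBox",
    "InferenceBackend",
    "MockBackend",
    "build_architecture_spec",
    "mock_backend",
]


@dataclass(frozen=True)
class ExpressionLabel:
    """One of the seven expression classes, with its fixed serialization index."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.index < len(EXPRESSION_LABELS)):
            raise ValidationError(f"expression index out of range: {self.index}")
        if EXPRESSION_LABELS[self.index] != self.name:
            raise ValidationError(
                f"label {self.name!r} does not sit at index {self.index}; "
                f"canonical order is {EXPRESSION_LABELS}"
            )


EXPRESSION_LABEL_SET: tuple[ExpressionLabel, ...] = tuple(
    ExpressionLabel(i, name) for i, name in enumerate(EXPRESSION_LABELS)
)


@dataclass(frozen=True)
class LayerSpec:
    """A single stage of the recognition network: kind + output shape."""

    kind: str
    name: str
    output_shape: tuple[int, ...]


# Output shapes of the eight convolution blocks, in order.  Pooling halves the
# spatial resolution after blocks 1, 3, 5 and 7 (0-based).
_CONV_BLOCK_SHAPES: tuple[tuple[int, int, int], ...] = (
    (48, 48, 64),
    (24, 24, 64),
    (24, 24, 128),
    (12, 12, 128),
    (12, 12, 256),
    (6, 6, 256),
    (6, 6, 512),
    (3, 3, 512),
)
_POOLED_BLOCKS = (1, 3, 5, 7)
_HEAD_SHAPE = (1, 1, 7)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer-by-layer output-shape specification of the expression CNN.

    Only shapes are specified (kernel sizes, strides and the dropout rate are
    free); the spec is sufficient to sanity-check the tensor shapes of a
    loaded weight file.
    """

    input_shape: tuple[int, int, int]
    layers: tuple[LayerSpec, ...]

    @property
    def output_shape(self) -> tuple[int, ...]:
        return self.layers[-1].output_shape

    @property
    def conv_block_shapes(self) -> tuple[tuple[int, ...], ...]:
        return tuple(l.output_shape for l in self.layers if l.kind == "conv2d")

    def to_json(self) -> str:
        payload = {
            "input_shape": list(self.input_shape),
            "layers": [
                {"kind": l.kind, "name": l.name, "output_shape": list(l.output_shape)}
                for l in self.layers
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        payload = json.loads(text)
        layers = tuple(
            LayerSpec(l["kind"], l["name"], tuple(l["output_shape"]))
            for l in payload["layers"]
        )
        return cls(input_shape=tuple(payload["input_shape"]), layers=layers)


def build_architecture_spec() -> ArchitectureSpec:
    """Build the fixed architecture of the expression-recognition CNN.

    Eight convolution blocks (conv2d -> batch normalization -> activation,
    with max pooling closing every second block) map a 48x48x1 grayscale face
    crop down to 3x3x512, and a dropout + fully-connected + softmax head emits
    the 1x1x7 class-probability vector.  Pure: repeated calls are equal.
    """
    layers: list[LayerSpec] = []
    for i, shape in enumerate(_CONV_BLOCK_SHAPES):
        suffix = "" if i == 0 else f"_{i}"
        layers.append(LayerSpec("conv2d", f"conv2d{suffix}", shape))
        layers.append(LayerSpec("batch_normalization", f"batch_normalization{suffix}", shape))
        layers.append(LayerSpec("activation", f"activation{suffix}", shape))
        if i in _POOLED_BLOCKS:
            pool_idx = _POOLED_BLOCKS.index(i)
            pool_suffix = "" if pool_idx == 0 else f"_{pool_idx}"
            layers.append(
                LayerSpec("max_pooling2d", f"max_pooling2d{pool_suffix}", shape)
            )
    layers.append(LayerSpec("dropout", "dropout", (3, 3, 512)))
    layers.append(LayerSpec("dense", "fc", _HEAD_SHAPE))
    layers.append(LayerSpec("softmax", "softmax", _HEAD_SHAPE))
    return ArchitectureSpec(input_shape=(48, 48, 1), layers=tuple(layers))


@dataclass(frozen=True)
class FaceBox:
    """A detected face in one frame, in normalized [0, 1] image coordinates.

    When several faces are detected the highest-confidence one is retained,
    matching a single-subject recording setup.
    """

    frame_index: int
    box: tuple[float, float, float, float]  # x, y, width, height
    confidence: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError("frame index must be >= 0")
        x, y, w, h = self.box
        if not (0.0 <= x and 0.0 <= y and w >= 0.0 and h >= 0.0
                and x + w <= 1.0 + 1e-9 and y + h <= 1.0 + 1e-9):
            raise ValidationError(f"face box outside unit square: {self.box}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence outside [0, 1]: {self.confidence}")


@runtime_checkable
class InferenceBackend(Protocol):
    """Contract every perception backend must satisfy.

    ``classify`` returns a valid 7-class probability vector (non-negative,
    summing to 1 within 1e-6) for every input.  ``estimate_pose`` marks
    undetected joints absent rather than inventing coordinates.
    """

    def classify(self, face_image: object) -> "np.ndarray": ...

    def estimate_pose(self, frame_image: object) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass
class MockBackend:
    """Deterministic stand-in backend driven by a severity profile in [0, 1].

    ``classify`` draws expression distributions whose mass concentrates on
    "sad" as ``profile`` approaches 1 and flattens toward uniform as it
    approaches 0.  ``estimate_pose`` advances a mean-reverting random walk of
    the 18 joints whose step amplitude shrinks with ``profile``.  The same
    (seed, profile) pair reproduces the same output sequence bit for bit.
    """

    seed: int
    profile: float
    kappa: float = 300.0
    alpha: float = 0.02
    amplitude_floor: float = 0.003
    _rng: np.random.Generator = field(init=False, repr=False)
    _positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.profile <= 1.0):
            raise ValidationError(f"profile must lie in [0, 1], got {self.profile}")
        # imported here to keep the severity laws in one place without a cycle
        from .synthetic import joint_anchors

        self._rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x6DD]))
        self._positions = joint_anchors().copy()

    def classify(self, face_image: object = None) -> np.ndarray:
        from .synthetic import severity_expression_target

        target = severity_expression_target(self.profile)
        return self._rng.dirichlet(self.kappa * target + 0.05)

    def estimate_pose(self, frame_image: object = None) -> tuple[np.ndarray, np.ndarray]:
        from .synthetic import joint_anchors, severity_step_scales

        scales = severity_step_scales(self.profile, self.alpha, self.amplitude_floor)
        steps = self._rng.normal(0.0, 1.0, size=(N_KEYPOINTS, 2)) * scales[:, None]
        anchors = joint_anchors()
        self._positions = np.clip(
            anchors + 0.95 * (self._positions - anchors) + steps, 0.0, 1.0
        )
        present = np.ones(N_KEYPOINTS, dtype=bool)
        return self._positions.copy(), present


def mock_backend(seed: int, profile: float, **kwargs) -> MockBackend:
    """Construct a deterministic :class:`MockBackend` (see its docstring)."""
    return MockBackend(seed=seed, profile=profile, **kwargs)
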