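"""Frame-level behavioral features: expression entropy and action entropy.

Expression entropy
    H(X) = -sum_i p(x_i) log p(x_i), the Shannon entropy of the 7-class
    facial-expression probability distribution aggregated over a session.
    Low H means flat, monotonous affect (probability mass piled on one
    class, typically "sad"); high H means lively, varied expression.

Action entropy
    Each of the 18 body keypoints gets a motion amplitude D(y_j): the mean
    Euclidean displacement of that joint between paired frames, in
    normalized image coordinates.  With Dz = sum_j D(y_j) and
    q_j = D(y_j) / Dz, the action entropy is G(Y) = -sum_j q_j log q_j.
    Low G means movement is concentrated in few joints (or absent); high G
    means the whole body participates.

Both entropies are normalized by the log of the category count (log 7 and
log 18) by default, so H, G lie in [0, 1] and can be mixed by a convex
weight downstream; pass ``normalized=False`` for nats.  The convention
0 * log 0 = 0 applies throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .labels import N_EXPRESSIONS, N_KEYPOINTS

__all__ = [
    "ExpressionDistribution",
    "ExpressionTrack",
    "KeypointFrame",
    "PoseTrack",
    "JointAmplitudes",
    "SessionFeatures",
    "aggregate_expression_distribution",
    "expression_entropy",
    "motion_amplitude",
    "joint_amplitudes",
    "action_entropy",
    "session_features",
]

_SUM_TOL = 1e-6


def _as_prob_vector(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (N_EXPRESSIONS,):
        raise ValidationError(
            f"expected {N_EXPRESSIONS} class probabilities, got shape {p.shape}"
        )
    if np.any(p < 0):
        raise ValidationError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"probabilities sum to {p.sum():.8f}, not 1 ± {_SUM_TOL}")
    return p


@dataclass(frozen=True)
class ExpressionDistribution:
    """A 7-vector of expression-class probabilities in the canonical order."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _as_prob_vector(self.probs))


@dataclass(frozen=True)
class ExpressionTrack:
    """Per-frame expression distributions for one session.

    ``frame_index`` is strictly increasing; ``probs`` has one row per frame.
    """

    frame_index: np.ndarray
    probs: np.ndarray
    session_id: int | str = 0
    patient_id: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_index, dtype=int)
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_EXPRESSIONS:
            raise ValidationError(f"probs must be (n, {N_EXPRESSIONS}), got {p.shape}")
        if idx.shape != (p.shape[0],):
            raise ValidationError("frame_index length must match probs rows")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        if p.size:
            if np.any(p < 0):
                raise ValidationError("probabilities must be non-negative")
            sums = p.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _SUM_TOL)
            if bad.size:
                raise ValidationError(
                    f"row {bad[0]} probabilities sum to {sums[bad[0]]:.8f}, not 1"
                )
        object.__setattr__(self, "frame_index", idx)
        object.__setattr__(self, "probs", p)

    def __len__(self) -> int:
        return self.frame_index.size


@dataclass(frozen=True)
class KeypointFrame:
    """18 joints of one frame: (x, y) in the unit square plus presence flags."""

    frame_index: int
    xy: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        pres = np.asarray(self.present, dtype=bool)
        if xy.shape != (N_KEYPOINTS, 2) or pres.shape != (N_KEYPOINTS,):
            raise ValidationError("keypoint frame must carry exactly 18 joints")
        if np.any((xy[pres] < 0) | (xy[pres] > 1)):
            raise ValidationError("present joints must lie in the unit square")
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "present", pres)


@dataclass(frozen=True)
class PoseTrack:
    """Frame-indexed 18-keypoint trajectories for one session.

    ``xy`` is (n, 18, 2); coordinates of absent joints are ignored.
    """

    frame_index: np.ndarray
    xy: np.ndarray
    present: np.ndarray
    session_id: int | str = 0
    patient_id: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_index, dtype=int)
        xy = np.asarray(self.xy, dtype=float)
        pres = np.asarray(self.present, dtype=bool)
        n = idx.size
        if xy.shape != (n, N_KEYPOINTS, 2) or pres.shape != (n, N_KEYPOINTS):
            raise ValidationError(
                f"pose arrays inconsistent: idx {idx.shape}, xy {xy.shape}, present {pres.shape}"
            )
        if n and np.any(np.diff(idx) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        if np.any((xy[pres] < 0) | (xy[pres] > 1)):
            raise ValidationError("present joints must lie in the unit square")
        object.__setattr__(self, "frame_index", idx)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "present", pres)

    @classmethod
    def from_frames(
        cls, frames: Iterable[KeypointFrame], session_id: int | str = 0, patient_id: str = ""
    ) -> "PoseTrack":
        frames = list(frames)
        idx = np.array([f.frame_index for f in frames], dtype=int)
        xy = np.stack([f.xy for f in frames]) if frames else np.empty((0, N_KEYPOINTS, 2))
        pres = (
            np.stack([f.present for f in frames]) if frames else np.empty((0, N_KEYPOINTS), bool)
        )
        return cls(idx, xy, pres, session_id=session_id, patient_id=patient_id)

    def __len__(self) -> int:
        return self.frame_index.size


@dataclass(frozen=True)
class JointAmplitudes:
    """Per-joint mean motion amplitudes D(y_j) and their total Dz."""

    amplitude: np.ndarray  # (18,) mean displacement per joint
    pair_count: np.ndarray  # (18,) number of valid frame pairs per joint

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        cnt = np.asarray(self.pair_count, dtype=int)
        if amp.shape != (N_KEYPOINTS,) or cnt.shape != (N_KEYPOINTS,):
            raise ValidationError("amplitudes must cover exactly 18 joints")
        if np.any(amp < 0):
            raise ValidationError("amplitudes must be non-negative")
        if np.any(amp[cnt == 0] != 0):
            raise ValidationError("joints with no valid pairs must have zero amplitude")
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "pair_count", cnt)

    @property
    def dz(self) -> float:
        return float(self.amplitude.sum())


@dataclass(frozen=True)
class SessionFeatures:
    """One session's behavioral summary: H, G and provenance counts."""

    session_id: int | str
    patient_id: str
    expression_entropy: float  # H
    action_entropy: float  # G
    n_expression_frames: int
    n_pose_pairs: int


def _shannon(weights: np.ndarray, n_categories: int, normalized: bool) -> float:
    total = weights.sum()
    if total <= 0:
        return 0.0
    p = weights / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / math.log(n_categories) if normalized else h


def aggregate_expression_distribution(track: ExpressionTrack) -> ExpressionDistribution:
    """Arithmetic mean of the per-frame distributions of a session."""
    if len(track) == 0:
        raise InsufficientDataError(
            f"no expression data for session {track.session_id!r}"
        )
    return ExpressionDistribution(track.probs.mean(axis=0))


def expression_entropy(
    dist: ExpressionDistribution | Sequence[float] | np.ndarray,
    normalized: bool = True,
) -> float:
    """Shannon entropy of a 7-class expression distribution.

    Normalized by log 7 by default so the result lies in [0, 1]; uniform
    input gives 1, a single dominant class gives 0.
    """
    p = dist.probs if isinstance(dist, ExpressionDistribution) else _as_prob_vector(dist)
    return _shannon(p, N_EXPRESSIONS, normalized)


def motion_amplitude(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean displacement of one joint between two frames."""
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    return math.hypot(bx - ax, by - ay)


def joint_amplitudes(track: PoseTrack, stride: int = 1) -> JointAmplitudes:
    """Mean per-joint displacement over frame pairs (t, t + stride).

    Only pairs where the joint is present in both frames contribute; a joint
    never co-present in any pair gets amplitude 0 with pair count 0.
    """
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    n = len(track)
    if n < 2:
        raise InsufficientDataError(
            f"insufficient pose data for session {track.session_id!r}: "
            f"{n} frame(s), need at least 2"
        )
    a, b = track.xy[:-stride], track.xy[stride:]
    valid = track.present[:-stride] & track.present[stride:]
    if a.shape[0] == 0:
        return JointAmplitudes(np.zeros(N_KEYPOINTS), np.zeros(N_KEYPOINTS, int))
    dist = np.linalg.norm(b - a, axis=2)  # (pairs, 18)
    counts = valid.sum(axis=0)
    sums = np.where(valid, dist, 0.0).sum(axis=0)
    amps = np.divide(sums, counts, out=np.zeros(N_KEYPOINTS), where=counts > 0)
    return JointAmplitudes(amps, counts.astype(int))


def action_entropy(
    amps: JointAmplitudes | Sequence[float] | np.ndarray,
    normalized: bool = True,
) -> float:
    """Shannon entropy of the joint-amplitude distribution q_j = D(y_j) / Dz.

    Normalized by log 18 by default.  A completely static subject (Dz = 0)
    returns 0: no movement is read as minimal action diversity.
    """
    d = amps.amplitude if isinstance(amps, JointAmplitudes) else np.asarray(amps, float)
    if d.shape != (N_KEYPOINTS,):
        raise ValidationError(f"expected {N_KEYPOINTS} amplitudes, got shape {d.shape}")
    if np.any(d < 0):
        raise ValidationError("amplitudes must be non-negative")
    return _shannon(d, N_KEYPOINTS, normalized)


def session_features(
    etrack: ExpressionTrack,
    ptrack: PoseTrack,
    stride: int = 1,
    normalized: bool = True,
    aggregation: str = "mean_distribution",
) -> SessionFeatures:
    """Compute H and G for one session.

    ``aggregation`` selects how per-frame expression distributions become one
    H value: ``"mean_distribution"`` (default) takes the entropy of the mean
    distribution; ``"per_frame_mean"`` averages per-frame entropies instead.
    """
    if aggregation not in ("mean_distribution", "per_frame_mean"):
        raise ValidationError(f"unknown aggregation mode {aggregation!r}")
    try:
        if aggregation == "mean_distribution":
            h = expression_entropy(aggregate_expression_distribution(etrack), normalized)
        else:
            if len(etrack) == 0:
                raise InsufficientDataError(
                    f"no expression data for session {etrack.session_id!r}"
                )
            h = float(
                np.mean([expression_entropy(row, normalized) for row in etrack.probs])
            )
        amps = joint_amplitudes(ptrack, stride)
        g = action_entropy(amps, normalized)
    except (ValidationError, InsufficientDataError) as err:
        raise type(err)(
            f"session {etrack.session_id!r} / patient {etrack.patient_id!r}: {err}"
        ) from err
    return SessionFeatures(
        session_id=etrack.session_id,
        patient_id=etrack.patient_id,
        expression_entropy=h,
        action_entropy=g,
        n_expression_frames=len(etrack),
        n_pose_pairs=max(len(ptrack) - stride, 0),
    )
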