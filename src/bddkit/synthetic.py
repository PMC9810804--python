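"""Synthetic multi-patient, multi-session behavioral cohorts.

A latent severity variable s in [0, 1] drives everything a real recording
would show more of, or less of, as depression deepens:

* Expression stream — per-frame 7-class distributions are Dirichlet draws
  around a target that interpolates between uniform (s = 0, lively affect)
  and sad-dominant (s = 1, flat affect), so expected expression entropy
  falls as s rises.
* Pose stream — the 18 joints perform mean-reverting random walks whose
  step amplitude both shrinks with s and concentrates: distal joints (legs,
  then arms) freeze first while a small head-region fidget persists, so
  both the total motion Dz and the action entropy G fall as s rises.
* Scale totals — SDS, SAS and HAMD are distinct increasing affine maps of
  the session's latent BDD B* (computed by the features module from the
  generated tracks) plus Gaussian noise, clipped to each scale's range.

Because the scale totals are built from B* = 1 - (λ* H* + (1 - λ*) G*) with
a known generating λ*, the λ-fitting procedure has an exact ground truth:
with zero noise the grid scan must recover λ* at grid resolution with mean
Pearson similarity 1.  Generation is fully deterministic given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import (
    ExpressionTrack,
    PoseTrack,
    SessionFeatures,
    session_features,
)
from .labels import HEAD_JOINTS, N_EXPRESSIONS, N_KEYPOINTS, SAD_INDEX
from .scales import ScaleRecord

__all__ = [
    "CohortSpec",
    "CohortSession",
    "SyntheticCohort",
    "severity_expression_target",
    "severity_step_scales",
    "joint_anchors",
    "generate_expression_track",
    "generate_pose_track",
    "generate_cohort",
]

# Rough standing-figure anchor positions (x, y) in the unit square, y down.
_ANCHORS = np.array(
    [
        (0.50, 0.12),  # nose
        (0.50, 0.22),  # neck
        (0.42, 0.23),  # right shoulder
        (0.39, 0.35),  # right elbow
        (0.37, 0.46),  # right wrist
        (0.58, 0.23),  # left shoulder
        (0.61, 0.35),  # left elbow
        (0.63, 0.46),  # left wrist
        (0.45, 0.50),  # right hip
        (0.44, 0.68),  # right knee
        (0.44, 0.86),  # right ankle
        (0.55, 0.50),  # left hip
        (0.56, 0.68),  # left knee
        (0.56, 0.86),  # left ankle
        (0.47, 0.10),  # right eye
        (0.53, 0.10),  # left eye
        (0.44, 0.11),  # right ear
        (0.56, 0.11),  # left ear
    ]
)

# How fast each joint's gross movement decays with severity: the head keeps a
# residual fidget, arms slow down, legs freeze first.
_JOINT_DECAY = np.array(
    [0.8, 0.8, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 0.8, 0.8, 0.8, 0.8]
)
_HEAD_MASK = np.zeros(N_KEYPOINTS)
_HEAD_MASK[list(HEAD_JOINTS)] = 1.0

# Distinct increasing affine maps from latent BDD to each scale's total.
_SCALE_AFFINE = {"sds": (30.0, 50.0), "sas": (28.0, 42.0), "hamd": (2.0, 45.0)}
_SCALE_CLIP = {"sds": (25.0, 100.0), "sas": (25.0, 100.0), "hamd": (0.0, 76.0)}


def joint_anchors() -> np.ndarray:
    """Anchor (rest) positions of the 18 joints in the unit square."""
    return _ANCHORS.copy()


def severity_expression_target(s: float) -> np.ndarray:
    """Target expression distribution at severity s: uniform at 0,
    sad-dominant at 1."""
    if not (0.0 <= s <= 1.0):
        raise ValidationError(f"severity must lie in [0, 1], got {s}")
    target = np.full(N_EXPRESSIONS, (1.0 - s) / N_EXPRESSIONS)
    target[SAD_INDEX] += s
    return target


def severity_step_scales(s: float, alpha: float, floor: float) -> np.ndarray:
    """Per-joint random-walk step scale at severity s.

    Gross movement alpha * (1 - s) decays per joint at the rates in
    ``_JOINT_DECAY``; a head-only floor keeps a residual fidget.  At s = 1
    with floor 0 every joint is static.
    """
    if not (0.0 <= s <= 1.0):
        raise ValidationError(f"severity must lie in [0, 1], got {s}")
    if alpha <= 0:
        raise ValidationError(f"alpha must be > 0, got {alpha}")
    if floor < 0:
        raise ValidationError(f"floor must be >= 0, got {floor}")
    return alpha * (1.0 - s) * np.exp(-_JOINT_DECAY * s) + floor * _HEAD_MASK


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for a synthetic cohort.

    Defaults describe a 40-patient cohort observed over 7 weekly treatment
    sessions with a generating mixing weight λ* = 0.94; severity starts high
    and relaxes monotonically over the course of treatment.
    """

    n_patients: int = 40
    n_sessions: int = 7
    frames_per_session: int = 200
    true_lambda: float = 0.94
    kappa: float = 80.0  # Dirichlet concentration of per-frame expressions
    alpha: float = 0.02  # gross per-step joint displacement scale
    amplitude_floor: float = 0.003  # residual head fidget step scale
    missingness: float = 0.02  # per-joint per-frame detection dropout
    scale_noise_sd: float = 2.0  # Gaussian sd added to each scale total
    modality_jitter_sd: float = 0.06  # session-level decoupling of face/body severity
    severity_start: tuple[float, float] = (0.5, 0.95)
    severity_relief: tuple[float, float] = (0.3, 0.6)  # fractional drop by last session
    stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_sessions < 1 or self.frames_per_session < 2:
            raise ValidationError("cohort dimensions too small")
        if not (0.0 <= self.true_lambda <= 1.0):
            raise ValidationError("true_lambda must lie in [0, 1]")
        if self.kappa < 0 or self.alpha <= 0 or self.amplitude_floor < 0:
            raise ValidationError("kappa >= 0, alpha > 0, floor >= 0 required")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValidationError("missingness must lie in [0, 1]")
        if self.scale_noise_sd < 0 or self.modality_jitter_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class CohortSession:
    """One generated (patient, session) with its tracks, record and latents."""

    patient_id: str
    session_id: int
    severity: float
    expression_track: ExpressionTrack
    pose_track: PoseTrack
    scale_record: ScaleRecord
    features: SessionFeatures
    h_latent: float
    g_latent: float
    f_latent: float
    b_latent: float


@dataclass(frozen=True)
class SyntheticCohort:
    """All sessions of a generated cohort plus the spec that produced them."""

    spec: CohortSpec
    sessions: tuple[CohortSession, ...]

    def features_list(self) -> list[SessionFeatures]:
        return [s.features for s in self.sessions]

    def scale_records(self) -> list[ScaleRecord]:
        return [s.scale_record for s in self.sessions]

    def latents_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": [s.patient_id for s in self.sessions],
                "session": [s.session_id for s in self.sessions],
                "severity": [s.severity for s in self.sessions],
                "H": [s.h_latent for s in self.sessions],
                "G": [s.g_latent for s in self.sessions],
                "F": [s.f_latent for s in self.sessions],
                "B": [s.b_latent for s in self.sessions],
            }
        )


def generate_expression_track(
    severity: float,
    n_frames: int,
    kappa: float,
    seed: int | np.random.Generator,
    session_id: int | str = 0,
    patient_id: str = "",
) -> ExpressionTrack:
    """Per-frame expression distributions at a given severity.

    Frames are Dirichlet(kappa * target + 0.05) draws around the severity
    target, so every frame is a valid distribution by construction and the
    expected entropy decreases in severity.
    """
    if n_frames < 1:
        raise ValidationError("need at least one frame")
    if kappa < 0:
        raise ValidationError(f"kappa must be >= 0, got {kappa}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    target = severity_expression_target(severity)
    alphas = kappa * target + 0.05
    probs = rng.dirichlet(alphas, size=n_frames)
    return ExpressionTrack(
        frame_index=np.arange(n_frames),
        probs=probs,
        session_id=session_id,
        patient_id=patient_id,
    )


def generate_pose_track(
    severity: float,
    n_frames: int,
    alpha: float,
    seed: int | np.random.Generator,
    amplitude_floor: float = 0.003,
    missingness: float | Sequence[float] = 0.0,
    session_id: int | str = 0,
    patient_id: str = "",
) -> PoseTrack:
    """18-joint trajectories at a given severity.

    Each joint performs a mean-reverting random walk around its anchor with
    per-step scale from :func:`severity_step_scales`, clipped to the unit
    square.  ``missingness`` (scalar or per-joint) is the probability that a
    joint is undetected in a frame.
    """
    if n_frames < 2:
        raise ValidationError("need at least two frames")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scales = severity_step_scales(severity, alpha, amplitude_floor)
    miss = np.broadcast_to(np.asarray(missingness, float), (N_KEYPOINTS,))
    if np.any((miss < 0) | (miss > 1)):
        raise ValidationError("missingness must lie in [0, 1]")
    steps = rng.normal(0.0, 1.0, size=(n_frames, N_KEYPOINTS, 2)) * scales[None, :, None]
    xy = np.empty((n_frames, N_KEYPOINTS, 2))
    pos = _ANCHORS.copy()
    for t in range(n_frames):
        pos = np.clip(_ANCHORS + 0.95 * (pos - _ANCHORS) + steps[t], 0.0, 1.0)
        xy[t] = pos
    present = rng.random((n_frames, N_KEYPOINTS)) >= miss[None, :]
    return PoseTrack(
        frame_index=np.arange(n_frames),
        xy=xy,
        present=present,
        session_id=session_id,
        patient_id=patient_id,
    )


def _severity_schedule(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-patient monotone decreasing severity over sessions: (P, S)."""
    s0 = rng.uniform(*spec.severity_start, size=spec.n_patients)
    relief = rng.uniform(*spec.severity_relief, size=spec.n_patients)
    t = (
        np.linspace(0.0, 1.0, spec.n_sessions)
        if spec.n_sessions > 1
        else np.zeros(1)
    )
    return s0[:, None] * (1.0 - relief[:, None] * t[None, :])


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort: tracks, measured features, latents and scales.

    The latent H*, G* stored per session are the values the features module
    actually measures on the generated tracks, so the affine scale link makes
    λ recovery exact in the noiseless case.  Identical specs yield identical
    cohorts.
    """
    root = np.random.SeedSequence(spec.seed)
    sched_rng = np.random.default_rng(root.spawn(1)[0])
    severities = _severity_schedule(spec, sched_rng)
    session_seeds = root.spawn(spec.n_patients * spec.n_sessions)
    sessions: list[CohortSession] = []
    k = 0
    for p in range(spec.n_patients):
        pid = f"p{p + 1:03d}"
        for sidx in range(spec.n_sessions):
            rng = np.random.default_rng(session_seeds[k])
            k += 1
            s = float(np.clip(severities[p, sidx], 0.0, 1.0))
            # the face and the body do not track the latent severity
            # identically; a small independent jitter decouples them
            s_expr = float(np.clip(s + rng.normal(0, spec.modality_jitter_sd), 0, 1))
            s_pose = float(np.clip(s + rng.normal(0, spec.modality_jitter_sd), 0, 1))
            etrack = generate_expression_track(
                s_expr, spec.frames_per_session, spec.kappa, rng,
                session_id=sidx + 1, patient_id=pid,
            )
            ptrack = generate_pose_track(
                s_pose, spec.frames_per_session, spec.alpha, rng,
                amplitude_floor=spec.amplitude_floor,
                missingness=spec.missingness,
                session_id=sidx + 1, patient_id=pid,
            )
            feats = session_features(etrack, ptrack, stride=spec.stride)
            h, g = feats.expression_entropy, feats.action_entropy
            f_lat = spec.true_lambda * h + (1.0 - spec.true_lambda) * g
            b_lat = 1.0 - f_lat
            totals = {}
            for name, (intercept, slope) in _SCALE_AFFINE.items():
                raw = intercept + slope * b_lat
                if spec.scale_noise_sd > 0:
                    raw += rng.normal(0.0, spec.scale_noise_sd)
                lo, hi = _SCALE_CLIP[name]
                totals[name] = float(np.clip(raw, lo, hi))
            record = ScaleRecord(
                patient_id=pid,
                session_id=sidx + 1,
                sds=totals["sds"],
                sas=totals["sas"],
                hamd=totals["hamd"],
            )
            sessions.append(
                CohortSession(
                    patient_id=pid,
                    session_id=sidx + 1,
                    severity=s,
                    expression_track=etrack,
                    pose_track=ptrack,
                    scale_record=record,
                    features=feats,
                    h_latent=h,
                    g_latent=g,
                    f_latent=f_lat,
                    b_latent=b_lat,
                )
            )
    return SyntheticCohort(spec=spec, sessions=tuple(sessions))
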