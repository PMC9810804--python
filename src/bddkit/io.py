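"""Readers and writers for the package's on-disk stream formats.

* Expression stream: CSV with header ``frame,angry,disgust,fear,happy,sad,
  surprise,neutral`` (this exact order).  Rows whose probabilities sum to
  1 ± 1e-2 are renormalized (with a log message) — softmax output serialized
  at low precision commonly drifts by that much — anything further off is
  rejected with its row number.
* Pose stream: JSON Lines, one object per frame:
  ``{"frame": int, "joints": [[x, y] or null] x 18}`` in COCO-18 order;
  ``null`` encodes an undetected joint.  Coordinates out of [0, 1] by at
  most 0.01 are clipped with a warning, anything further is rejected.
* Scales: CSV ``patient,session,sds,sas,hamd``.
* Session features: CSV ``patient,session,H,G,n_expression_frames,
  n_pose_pairs``.
* BDD series: CSV ``patient,session,F,B``; λ fit: JSON.

Floats are serialized with 9 significant digits, which makes a
write -> read -> write cycle byte-stable.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bdd import BDDSeries, LambdaFit
from .errors import ValidationError
from .features import ExpressionTrack, PoseTrack, SessionFeatures
from .labels import EXPRESSION_LABELS, N_KEYPOINTS
from .scales import ScaleRecord

__all__ = [
    "read_expression_csv",
    "write_expression_csv",
    "read_pose_jsonl",
    "write_pose_jsonl",
    "read_scales_csv",
    "write_scales_csv",
    "read_features_csv",
    "write_features_csv",
    "write_bdd_csv",
    "read_bdd_csv",
    "write_lambda_fit_json",
    "read_lambda_fit_json",
]

logger = logging.getLogger(__name__)

_EXPR_HEADER = ("frame", *EXPRESSION_LABELS)
_RENORM_TOL = 1e-2
_STRICT_TOL = 1e-4
_CLIP_TOL = 0.01


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def read_expression_csv(
    path: str | Path, session_id: int | str = 0, patient_id: str = ""
) -> ExpressionTrack:
    """Read a per-frame expression probability stream."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != _EXPR_HEADER:
            for got, want in zip(header, _EXPR_HEADER):
                if got.strip() != want:
                    raise ValidationError(
                        f"{path}: expected column {want!r}, found {got!r}; "
                        f"header must be {','.join(_EXPR_HEADER)}"
                    )
            raise ValidationError(
                f"{path}: header has {len(header)} columns, expected {len(_EXPR_HEADER)}"
            )
        frames: list[int] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_EXPR_HEADER):
                raise ValidationError(f"{path}: row {lineno} has {len(row)} fields")
            try:
                frame = int(row[0])
                probs = [float(v) for v in row[1:]]
            except ValueError as err:
                raise ValidationError(f"{path}: row {lineno}: {err}") from None
            total = sum(probs)
            if abs(total - 1.0) > _RENORM_TOL:
                raise ValidationError(
                    f"{path}: row {lineno} probabilities sum to {total:.6f}"
                )
            if abs(total - 1.0) > _STRICT_TOL:
                logger.info(
                    "%s: row %d renormalized (sum was %.6f)", path, lineno, total
                )
                probs = [p / total for p in probs]
            frames.append(frame)
            rows.append(probs)
    return ExpressionTrack(
        frame_index=np.array(frames, int),
        probs=np.array(rows, float).reshape(len(rows), len(EXPRESSION_LABELS)),
        session_id=session_id,
        patient_id=patient_id,
    )


def write_expression_csv(track: ExpressionTrack, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXPR_HEADER)
        for frame, probs in zip(track.frame_index, track.probs):
            writer.writerow([int(frame), *(_fmt(p) for p in probs)])


def read_pose_jsonl(
    path: str | Path, session_id: int | str = 0, patient_id: str = ""
) -> PoseTrack:
    """Read a per-frame 18-keypoint pose stream (JSON Lines)."""
    path = Path(path)
    frames: list[int] = []
    coords: list[np.ndarray] = []
    present: list[np.ndarray] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as err:
                raise ValidationError(f"{path}: line {lineno}: {err}") from None
            joints = obj.get("joints")
            if not isinstance(joints, list) or len(joints) != N_KEYPOINTS:
                n = len(joints) if isinstance(joints, list) else "no"
                raise ValidationError(
                    f"{path}: line {lineno} has {n} joints, expected {N_KEYPOINTS}"
                )
            xy = np.zeros((N_KEYPOINTS, 2))
            pres = np.zeros(N_KEYPOINTS, bool)
            for j, joint in enumerate(joints):
                if joint is None:
                    continue
                x, y = float(joint[0]), float(joint[1])
                for axis, v in (("x", x), ("y", y)):
                    if v < -_CLIP_TOL or v > 1.0 + _CLIP_TOL:
                        raise ValidationError(
                            f"{path}: line {lineno} joint {j} {axis}={v} "
                            f"outside [0, 1] by more than {_CLIP_TOL}"
                        )
                cx, cy = min(max(x, 0.0), 1.0), min(max(y, 0.0), 1.0)
                if (cx, cy) != (x, y):
                    logger.warning(
                        "%s: line %d joint %d clipped from (%g, %g)",
                        path, lineno, j, x, y,
                    )
                xy[j] = (cx, cy)
                pres[j] = True
            frames.append(int(obj["frame"]))
            coords.append(xy)
            present.append(pres)
    idx = np.array(frames, int)
    if idx.size and np.any(np.diff(idx) <= 0):
        bad = int(np.flatnonzero(np.diff(idx) <= 0)[0]) + 2
        raise ValidationError(f"{path}: non-monotone frame index at line {bad}")
    return PoseTrack(
        frame_index=idx,
        xy=np.stack(coords) if coords else np.empty((0, N_KEYPOINTS, 2)),
        present=np.stack(present) if present else np.empty((0, N_KEYPOINTS), bool),
        session_id=session_id,
        patient_id=patient_id,
    )


def write_pose_jsonl(track: PoseTrack, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for frame, xy, pres in zip(track.frame_index, track.xy, track.present):
            joints = [
                [float(_fmt(x)), float(_fmt(y))] if p else None
                for (x, y), p in zip(xy, pres)
            ]
            fh.write(json.dumps({"frame": int(frame), "joints": joints}) + "\n")


def read_scales_csv(path: str | Path) -> list[ScaleRecord]:
    df = pd.read_csv(path)
    missing = {"patient", "session", "sds", "sas", "hamd"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        ScaleRecord(
            patient_id=str(row.patient),
            session_id=int(row.session),
            sds=float(row.sds),
            sas=float(row.sas),
            hamd=float(row.hamd),
        )
        for row in df.itertuples()
    ]


def write_scales_csv(records: Sequence[ScaleRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient", "session", "sds", "sas", "hamd"])
        for r in records:
            writer.writerow(
                [r.patient_id, r.session_id, _fmt(r.sds), _fmt(r.sas), _fmt(r.hamd)]
            )


def write_features_csv(features: Iterable[SessionFeatures], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient", "session", "H", "G", "n_expression_frames", "n_pose_pairs"]
        )
        for f in features:
            writer.writerow(
                [
                    f.patient_id,
                    f.session_id,
                    _fmt(f.expression_entropy),
                    _fmt(f.action_entropy),
                    f.n_expression_frames,
                    f.n_pose_pairs,
                ]
            )


def read_features_csv(path: str | Path) -> list[SessionFeatures]:
    df = pd.read_csv(path)
    missing = {"patient", "session", "H", "G"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        SessionFeatures(
            patient_id=str(row.patient),
            session_id=int(row.session),
            expression_entropy=float(row.H),
            action_entropy=float(row.G),
            n_expression_frames=int(getattr(row, "n_expression_frames", 0)),
            n_pose_pairs=int(getattr(row, "n_pose_pairs", 0)),
        )
        for row in df.itertuples()
    ]


def write_bdd_csv(series_list: Sequence[BDDSeries], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient", "session", "F", "B"])
        for s in series_list:
            for sid, f, b in zip(s.session_ids, s.F, s.B):
                writer.writerow([s.patient_id, sid, _fmt(f), _fmt(b)])


def read_bdd_csv(path: str | Path) -> list[BDDSeries]:
    df = pd.read_csv(path)
    missing = {"patient", "session", "F", "B"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: list[BDDSeries] = []
    for pid, sub in df.groupby("patient", sort=True):
        sub = sub.sort_values("session")
        f = sub["F"].to_numpy(float)
        b = sub["B"].to_numpy(float)
        # 9-significant-digit serialization can leave B and 1 - F a hair
        # apart; B is rebuilt from F after a consistency check
        if np.any(np.abs(b - (1.0 - f)) > 1e-8):
            raise ValidationError(f"{path}: B column inconsistent with 1 - F")
        out.append(
            BDDSeries(
                patient_id=str(pid),
                session_ids=tuple(int(s) for s in sub["session"]),
                F=f,
                B=1.0 - f,
            )
        )
    return out


def write_lambda_fit_json(fit: LambdaFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_lambda_fit_json(path: str | Path) -> LambdaFit:
    return LambdaFit.from_dict(json.loads(Path(path).read_text()))
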