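"""Behavioral entropy, the BDD score, and λ fitting.

The two session-level entropies are mixed by a convex weight λ into the
behavioral entropy

    F(X, Y) = λ H(X) + (1 - λ) G(Y),

and the behavioral depression degree is its complement,

    B(X, Y) = 1 - F(X, Y),

so that flatter affect and less diverse movement (low H, low G) yield a
higher severity score.  λ is fitted by scanning a grid over [0, 1] and
maximizing the mean sample Pearson correlation between the pooled BDD values
and each of the three clinical scale series (SDS, SAS, HAMD).  Pearson r is
used signed — BDD is expected to co-move positively with all three scales —
and "similarity" is simply r expressed as a percentage when reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConstantSeriesError, InsufficientDataError, ValidationError
from .features import SessionFeatures

__all__ = [
    "BDDConfig",
    "BDDSeries",
    "LambdaFit",
    "behavioral_entropy",
    "bdd",
    "pearson",
    "fit_lambda",
    "compute_bdd_series",
]

SCALE_COLUMNS = ("sds", "sas", "hamd")


@dataclass(frozen=True)
class BDDConfig:
    """Mixing weight and fitting-grid configuration."""

    lam: float = 0.94
    grid_step: float = 0.01
    normalized: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValidationError(f"lambda must lie in [0, 1], got {self.lam}")
        n = round(1.0 / self.grid_step)
        if n < 1 or abs(n * self.grid_step - 1.0) > 1e-9:
            raise ValidationError(
                f"grid step {self.grid_step} does not divide 1 evenly"
            )

    @property
    def grid(self) -> np.ndarray:
        n = round(1.0 / self.grid_step)
        return np.linspace(0.0, 1.0, n + 1)


@dataclass(frozen=True)
class BDDSeries:
    """Per-session behavioral entropy F and BDD B for one patient, in
    treatment order."""

    patient_id: str
    session_ids: tuple
    F: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.F, dtype=float)
        b = np.asarray(self.B, dtype=float)
        if f.shape != b.shape or f.shape != (len(self.session_ids),):
            raise ValidationError("F, B and session_ids must have equal length")
        if np.any(np.abs(b - (1.0 - f)) > 1e-12):
            raise ValidationError("B must equal 1 - F")
        object.__setattr__(self, "F", f)
        object.__setattr__(self, "B", b)


@dataclass(frozen=True)
class LambdaFit:
    """Result of the λ grid scan.

    ``r`` maps each scale name to its per-λ Pearson r trace;
    ``mean_similarity`` is the across-scale mean of those traces, and
    ``best_lambda`` attains its maximum (ties broken toward the largest λ).
    """

    grid: np.ndarray
    r: dict[str, np.ndarray]
    mean_similarity: np.ndarray
    best_lambda: float
    best_mean_similarity: float
    n_points: int
    per_patient: bool = False

    def to_dict(self) -> dict:
        return {
            "grid": [float(x) for x in self.grid],
            "r_sds": [float(x) for x in self.r["sds"]],
            "r_sas": [float(x) for x in self.r["sas"]],
            "r_hamd": [float(x) for x in self.r["hamd"]],
            "mean": [float(x) for x in self.mean_similarity],
            "best_lambda": float(self.best_lambda),
            "best_mean": float(self.best_mean_similarity),
            "n_points": int(self.n_points),
            "per_patient": bool(self.per_patient),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LambdaFit":
        return cls(
            grid=np.asarray(d["grid"], float),
            r={
                "sds": np.asarray(d["r_sds"], float),
                "sas": np.asarray(d["r_sas"], float),
                "hamd": np.asarray(d["r_hamd"], float),
            },
            mean_similarity=np.asarray(d["mean"], float),
            best_lambda=float(d["best_lambda"]),
            best_mean_similarity=float(d["best_mean"]),
            n_points=int(d["n_points"]),
            per_patient=bool(d.get("per_patient", False)),
        )


def _check_unit(name: str, value: float) -> float:
    v = float(value)
    if not (0.0 <= v <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    return v


def behavioral_entropy(h: float, g: float, lam: float) -> float:
    """F = λH + (1 - λ)G, a convex mixture of the two entropies."""
    h = _check_unit("H", h)
    g = _check_unit("G", g)
    lam = _check_unit("lambda", lam)
    return lam * h + (1.0 - lam) * g


def bdd(f: float) -> float:
    """B = 1 - F: the behavioral depression degree."""
    f = _check_unit("F", f)
    return 1.0 - f


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length series.

    Raises ConstantSeriesError when either series has zero variance: the
    correlation is undefined there and is never silently reported as 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("series must be 1-d and of equal length")
    if xa.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {xa.size}")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    return float(dx @ dy / math.sqrt(sx * sy))


def _features_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        df = features.copy()
        required = {"patient", "session", "H", "G"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"features table missing columns: {sorted(missing)}")
        return df
    rows = [
        {
            "patient": f.patient_id,
            "session": f.session_id,
            "H": f.expression_entropy,
            "G": f.action_entropy,
        }
        for f in features
    ]
    return pd.DataFrame(rows)


def _scales_frame(scales) -> pd.DataFrame:
    if isinstance(scales, pd.DataFrame):
        df = scales.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "patient": r.patient_id,
                    "session": r.session_id,
                    "sds": r.sds,
                    "sas": r.sas,
                    "hamd": r.hamd,
                }
                for r in scales
            ]
        )
    missing = {"patient", "session", *SCALE_COLUMNS} - set(df.columns)
    if missing:
        raise ValidationError(f"scales table missing columns: {sorted(missing)}")
    return df


def _grid_correlations(
    h: np.ndarray, g: np.ndarray, scales: dict[str, np.ndarray], grid: np.ndarray
) -> dict[str, np.ndarray]:
    # B(λ) for the whole grid at once: (n_grid, n_points)
    b = 1.0 - (np.outer(grid, h) + np.outer(1.0 - grid, g))
    db = b - b.mean(axis=1, keepdims=True)
    sb = np.sqrt((db * db).sum(axis=1))
    out: dict[str, np.ndarray] = {}
    for name, series in scales.items():
        ds = series - series.mean()
        ss = math.sqrt(float(ds @ ds))
        if ss == 0.0:
            raise ConstantSeriesError(f"{name} series is constant; correlation undefined")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (db @ ds) / (sb * ss)
        # a λ where B(λ) is constant across points has undefined r; mark NaN
        r[sb == 0.0] = np.nan
        out[name] = r
    return out


def fit_lambda(
    features,
    scales,
    config: BDDConfig | None = None,
    *,
    per_patient: bool = False,
) -> LambdaFit:
    """Scan λ over a grid and maximize the mean Pearson r against the scales.

    Features and scale records are joined on (patient, session); every joined
    point must carry all three scale totals.  By default the correlations are
    pooled over all points of the cohort — one λ is fitted for everyone; with
    ``per_patient=True`` the r values are computed within each patient (with
    at least 3 sessions) and averaged, as a sensitivity analysis.
    """
    config = config or BDDConfig()
    fdf = _features_frame(features)
    sdf = _scales_frame(scales)
    merged = fdf.merge(sdf, on=["patient", "session"], how="inner")
    if len(merged) < 3:
        raise InsufficientDataError(
            f"need at least 3 (patient, session) points with features and scales, "
            f"got {len(merged)}"
        )
    if merged[list(SCALE_COLUMNS)].isna().any().any():
        bad = merged[merged[list(SCALE_COLUMNS)].isna().any(axis=1)].iloc[0]
        raise ValidationError(
            f"missing scale value for patient {bad['patient']!r} "
            f"session {bad['session']!r}"
        )
    grid = config.grid
    if per_patient:
        traces: list[dict[str, np.ndarray]] = []
        for _, sub in merged.groupby("patient", sort=True):
            if len(sub) < 3:
                continue
            traces.append(
                _grid_correlations(
                    sub["H"].to_numpy(),
                    sub["G"].to_numpy(),
                    {c: sub[c].to_numpy(float) for c in SCALE_COLUMNS},
                    grid,
                )
            )
        if not traces:
            raise InsufficientDataError("no patient has >= 3 sessions")
        r = {
            c: np.nanmean(np.stack([t[c] for t in traces]), axis=0)
            for c in SCALE_COLUMNS
        }
    else:
        r = _grid_correlations(
            merged["H"].to_numpy(),
            merged["G"].to_numpy(),
            {c: merged[c].to_numpy(float) for c in SCALE_COLUMNS},
            grid,
        )
    mean_sim = np.mean(np.stack([r[c] for c in SCALE_COLUMNS]), axis=0)
    finite = np.where(np.isfinite(mean_sim), mean_sim, -np.inf)
    best_value = finite.max()
    best_idx = int(np.flatnonzero(finite == best_value).max())  # ties -> largest λ
    return LambdaFit(
        grid=grid,
        r=r,
        mean_similarity=mean_sim,
        best_lambda=float(grid[best_idx]),
        best_mean_similarity=float(mean_sim[best_idx]),
        n_points=len(merged),
        per_patient=per_patient,
    )


def compute_bdd_series(
    features: Sequence[SessionFeatures], lam: float
) -> BDDSeries:
    """Per-session F and B for one patient's sessions, in the given order."""
    lam = _check_unit("lambda", lam)
    features = list(features)
    if not features:
        raise InsufficientDataError("no sessions to score")
    patients = {f.patient_id for f in features}
    if len(patients) > 1:
        raise ValidationError(f"sessions span multiple patients: {sorted(patients)}")
    f_vals = np.array(
        [behavioral_entropy(f.expression_entropy, f.action_entropy, lam) for f in features]
    )
    return BDDSeries(
        patient_id=features[0].patient_id,
        session_ids=tuple(f.session_id for f in features),
        F=f_vals,
        B=1.0 - f_vals,
    )
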