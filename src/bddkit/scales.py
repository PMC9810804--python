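"""Clinical scale scoring, severity banding, and longitudinal reports.

Three instruments are supported:

* SDS (Zung self-rating depression scale): 20 items scored 1-4.  Severity
  cut-offs (below 50 none, 50-59 mild, 60-69 moderate to severe, >= 70
  severe) apply to the index score floor(1.25 x raw sum), so item-level
  scoring defaults to index mode; pass mode="raw" for the raw sum.
* SAS (Zung self-rating anxiety scale): identical structure to the SDS.
* HAMD (Hamilton depression rating scale): clinician-rated items scored 0-4;
  totals are accepted as given.  The published bands (< 8 none, 18-35 mild
  or moderate, > 35 severe) leave 8-17 unassigned; this package maps 8-17 to
  "mild", which is how totals in that range are described clinically.

Percent changes are reported as 100 x (baseline - end) / baseline, rounded
half-up to one decimal, so a positive value is an improvement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .bdd import BDDSeries
from .errors import ValidationError

__all__ = [
    "ScaleRecord",
    "SeverityBand",
    "score_sds",
    "score_sas",
    "classify_severity",
    "percent_change",
    "patient_report",
]

logger = logging.getLogger(__name__)

N_ZUNG_ITEMS = 20
HAMD_DEFAULT_ITEMS = 24


@dataclass(frozen=True)
class ScaleRecord:
    """One session's SDS / SAS / HAMD totals (item vectors optional)."""

    patient_id: str
    session_id: int | str
    sds: float
    sas: float
    hamd: float
    sds_items: tuple[int, ...] | None = None
    sas_items: tuple[int, ...] | None = None
    hamd_items: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("sds", "sas", "hamd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} total must be non-negative, got {v}")
        if self.sds_items is not None and score_sds(self.sds_items) != self.sds:
            raise ValidationError("sds total does not match its items (index mode)")
        if self.sas_items is not None and score_sas(self.sas_items) != self.sas:
            raise ValidationError("sas total does not match its items (index mode)")
        if self.hamd_items is not None:
            if any(not (0 <= i <= 4) for i in self.hamd_items):
                raise ValidationError("HAMD items must lie in 0-4")
            if sum(self.hamd_items) != self.hamd:
                raise ValidationError("hamd total does not match its items")


@dataclass(frozen=True)
class SeverityBand:
    """One severity band of a scale: label plus [low, high) total range.

    Half-open ranges keep the bands contiguous over real-valued totals while
    reproducing the published integer cut-offs exactly.
    """

    scale: str
    label: str
    low: float
    high: float  # exclusive

    def __contains__(self, total: float) -> bool:
        return self.low <= total < self.high


_BANDS: dict[str, tuple[SeverityBand, ...]] = {
    "sds": (
        SeverityBand("sds", "no depression", 0, 50),
        SeverityBand("sds", "mild depression", 50, 60),
        SeverityBand("sds", "moderate to severe depression", 60, 70),
        SeverityBand("sds", "severe depression", 70, math.inf),
    ),
    "sas": (
        SeverityBand("sas", "no anxiety", 0, 50),
        SeverityBand("sas", "mild anxiety", 50, 60),
        SeverityBand("sas", "moderate to severe anxiety", 60, 70),
        SeverityBand("sas", "severe anxiety", 70, math.inf),
    ),
    "hamd": (
        SeverityBand("hamd", "no depression", 0, 8),
        SeverityBand("hamd", "mild depression", 8, 18),
        SeverityBand("hamd", "mild or moderate depression", 18, 36),
        SeverityBand("hamd", "severe depression", 36, math.inf),
    ),
}


def _score_zung(items: Sequence[int], mode: str, scale: str) -> int:
    if len(items) != N_ZUNG_ITEMS:
        raise ValidationError(
            f"{scale} requires exactly {N_ZUNG_ITEMS} items, got {len(items)}"
        )
    for i, item in enumerate(items):
        if item != int(item) or not (1 <= item <= 4):
            raise ValidationError(f"{scale} item {i} out of range 1-4: {item}")
    raw = int(sum(items))
    if mode == "raw":
        return raw
    if mode == "index":
        return math.floor(1.25 * raw)
    raise ValidationError(f"unknown scoring mode {mode!r}; use 'raw' or 'index'")


def score_sds(items: Sequence[int], mode: str = "index") -> int:
    """Total SDS score from 20 items scored 1-4 (index score by default)."""
    return _score_zung(items, mode, "SDS")


def score_sas(items: Sequence[int], mode: str = "index") -> int:
    """Total SAS score from 20 items scored 1-4 (index score by default)."""
    return _score_zung(items, mode, "SAS")


def classify_severity(scale: str, total: float) -> SeverityBand:
    """Map a scale total to its severity band (bands are exhaustive and
    non-overlapping over each scale's representable totals)."""
    key = scale.lower()
    if key not in _BANDS:
        raise ValidationError(f"unknown scale {scale!r}; expected one of {list(_BANDS)}")
    if total < 0:
        raise ValidationError(f"scale total must be non-negative, got {total}")
    for band in _BANDS[key]:
        if total in band:
            return band
    raise ValidationError(f"total {total} falls in no {scale} band")  # pragma: no cover


def percent_change(baseline: float, end: float) -> float:
    """100 x (baseline - end) / baseline, rounded half-up to one decimal.

    Positive values mean the quantity decreased (improvement)."""
    if baseline <= 0:
        raise ValidationError(f"baseline must be > 0, got {baseline}")
    b = Decimal(str(baseline))
    e = Decimal(str(end))
    pct = (b - e) / b * Decimal(100)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _direction(baseline: float, end: float) -> int:
    if end < baseline:
        return 1  # decreased
    if end > baseline:
        return -1
    return 0


def patient_report(
    scale_records: Sequence[ScaleRecord], bdd_series: BDDSeries
) -> dict:
    """Longitudinal per-patient report: baseline/end totals, bands, percent
    changes, and whether BDD moved in the same direction as each scale.

    With a single session the report carries the totals only (a warning is
    logged and change statistics are omitted).  Agreement flags are None when
    either series did not change.
    """
    records = sorted(scale_records, key=lambda r: r.session_id)
    if not records:
        raise ValidationError("no scale records")
    patients = {r.patient_id for r in records}
    if len(patients) > 1 or bdd_series.patient_id not in patients:
        raise ValidationError(
            f"scale records {sorted(patients)} do not match BDD series "
            f"{bdd_series.patient_id!r}"
        )
    report: dict = {
        "patient": bdd_series.patient_id,
        "n_sessions": len(records),
        "scales": {},
        "bdd": {},
    }
    single = len(records) < 2
    if single:
        logger.warning(
            "patient %s has a single session; change statistics omitted",
            bdd_series.patient_id,
        )
    b_base, b_end = float(bdd_series.B[0]), float(bdd_series.B[-1])
    report["bdd"] = {"baseline": b_base, "end": b_end}
    if not single:
        report["bdd"]["pct_decrease"] = percent_change(b_base, b_end)
    bdd_dir = _direction(b_base, b_end)
    agreement: dict[str, bool | None] = {}
    for name in ("sds", "sas", "hamd"):
        base = float(getattr(records[0], name))
        end = float(getattr(records[-1], name))
        entry = {
            "baseline": base,
            "end": end,
            "baseline_band": classify_severity(name, base).label,
            "end_band": classify_severity(name, end).label,
        }
        if not single:
            entry["pct_decrease"] = percent_change(base, end)
            d = _direction(base, end)
            agreement[name] = (d == bdd_dir) if (d != 0 and bdd_dir != 0) else None
        report["scales"][name] = entry
    if not single:
        report["agreement"] = agreement
    return report
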