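"""Visual-field records, severity classification and reliability filtering.

A :class:`VisualFieldRecord` is one perimetry exam: identifiers, the 52
total-deviation (TD) values in canonical grid order, the mean deviation (MD)
as reported by the device, and optional reliability indices.  MD is always
taken verbatim from the input — it is never recomputed from TD, because the
device's MD is a normative-variance-weighted mean whose weights are not
public.  The synthetic generator defines its MD as the unweighted mean of the
52 TD values and documents that divergence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig

TD_MIN_DB = -40.0
TD_MAX_DB = 15.0

VISIT_TYPES = ("presentation", "interim", "final")


class SeverityClass(str, Enum):
    SEVERE = "severe"
    MODERATE = "moderate"
    MILD = "mild"
    NORMAL = "normal"


def classify_severity(md: float, config: AnalysisConfig = DEFAULT_CONFIG) -> SeverityClass:
    """Classify a mean deviation into the four severity strata.

    severe: ``md < -15``; moderate: ``-15 <= md < -7``; mild ``-7 <= md < -2``;
    normal ``md >= -2`` (default cutpoints; configurable).  Total on all finite
    MD values: the four half-open classes partition the real line.
    """
    if not math.isfinite(md):
        raise ValueError(f"MD must be finite, got {md!r}")
    lo, mid, hi = config.severity_cutpoints
    if md < lo:
        return SeverityClass.SEVERE
    if md < mid:
        return SeverityClass.MODERATE
    if md < hi:
        return SeverityClass.MILD
    return SeverityClass.NORMAL


@dataclass
class VisualFieldRecord:
    patient_id: str
    eye: str  # "OD" | "OS"
    visit_day: int
    visit_type: str  # presentation | interim | final
    td: np.ndarray  # 52 values, dB, canonical grid order
    md: float
    fixation_loss_pct: float | None = None
    false_pos_pct: float | None = None
    false_neg_pct: float | None = None

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, dtype=float)
        if self.td.shape != (52,):
            raise ValueError(f"td must have 52 values, got shape {self.td.shape}")
        if not np.all(np.isfinite(self.td)):
            raise ValueError("td contains non-finite values")
        if self.td.min() < TD_MIN_DB or self.td.max() > TD_MAX_DB:
            raise ValueError(
                f"td values outside [{TD_MIN_DB}, {TD_MAX_DB}] dB for "
                f"{self.patient_id}/{self.eye} day {self.visit_day}"
            )
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be OD or OS, got {self.eye!r}")
        if self.visit_type not in VISIT_TYPES:
            raise ValueError(f"unknown visit_type {self.visit_type!r}")
        if self.visit_day < 0:
            raise ValueError("visit_day must be >= 0")
        if self.visit_type == "presentation" and self.visit_day != 0:
            raise ValueError("presentation visit must be at day 0")
        if not math.isfinite(self.md):
            raise ValueError("md must be finite")

    @property
    def eye_id(self) -> str:
        return f"{self.patient_id}:{self.eye}"

    @property
    def has_reliability(self) -> bool:
        return not (
            self.fixation_loss_pct is None
            and self.false_pos_pct is None
            and self.false_neg_pct is None
        )

    def severity(self, config: AnalysisConfig = DEFAULT_CONFIG) -> SeverityClass:
        return classify_severity(self.md, config)


@dataclass
class ReliabilityReport:
    """Partition of a record set by the reliability filter.

    ``kept`` and ``excluded`` are disjoint and their union is the input in
    original order.  ``unverified`` is the subset of ``kept`` that carried no
    reliability metadata at all (kept by policy, flagged for the report).
    """

    kept: list[VisualFieldRecord] = field(default_factory=list)
    excluded: list[VisualFieldRecord] = field(default_factory=list)
    unverified: list[VisualFieldRecord] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "kept": len(self.kept),
            "excluded": len(self.excluded),
            "unverified": len(self.unverified),
        }


def reliability_filter(
    records: list[VisualFieldRecord],
    fl_max: float = DEFAULT_CONFIG.fl_max,
    fp_max: float = DEFAULT_CONFIG.fp_max,
    fn_max: float = DEFAULT_CONFIG.fn_max,
) -> ReliabilityReport:
    """Keep a record iff every *available* reliability index is strictly below
    its threshold (fixation loss < 33%, false pos/neg < 15% by default).

    Records with no reliability metadata are kept and flagged ``unverified``.
    """
    if min(fl_max, fp_max, fn_max) <= 0:
        raise ValueError("reliability thresholds must be positive")
    report = ReliabilityReport()
    for rec in records:
        if not rec.has_reliability:
            report.kept.append(rec)
            report.unverified.append(rec)
            continue
        checks = (
            (rec.fixation_loss_pct, fl_max),
            (rec.false_pos_pct, fp_max),
            (rec.false_neg_pct, fn_max),
        )
        ok = all(v is None or v < thr for v, thr in checks)
        (report.kept if ok else report.excluded).append(rec)
    return report


def assign_visit_types(
    records: list[VisualFieldRecord],
    config: AnalysisConfig = DEFAULT_CONFIG,
    rebase_days: bool = True,
) -> list[VisualFieldRecord]:
    """Label visits per eye: first exam = presentation, last exam inside the
    final window = final, everything else interim.

    Days are optionally rebased so each eye's first exam is day 0.  Ties on
    the same day are broken by input order (the earlier row is presentation).
    Records are returned in the original order with ``visit_type`` rewritten.
    """
    by_eye: dict[str, list[int]] = {}
    for pos, rec in enumerate(records):
        by_eye.setdefault(rec.eye_id, []).append(pos)
    out = list(records)
    lo, hi = config.final_window
    for positions in by_eye.values():
        positions = sorted(positions, key=lambda p: (records[p].visit_day, p))
        day0 = records[positions[0]].visit_day
        days = [records[p].visit_day - day0 if rebase_days else records[p].visit_day
                for p in positions]
        final_pos = None
        for p, d in zip(positions, days):
            if lo <= d <= hi:
                final_pos = p  # last qualifying visit wins
        for p, d in zip(positions, days):
            if p == positions[0]:
                vt = "presentation"
            elif p == final_pos:
                vt = "final"
            else:
                vt = "interim"
            rec = records[p]
            out[p] = VisualFieldRecord(
                patient_id=rec.patient_id, eye=rec.eye, visit_day=d, visit_type=vt,
                td=rec.td, md=rec.md, fixation_loss_pct=rec.fixation_loss_pct,
                false_pos_pct=rec.false_pos_pct, false_neg_pct=rec.false_neg_pct,
            )
    return out


def cohort_summary(
    records: list[VisualFieldRecord],
    by: str = "visit_type",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-visit-group MD summary: n, mean +/- SD, quartiles, IQR, and counts
    plus percentages per severity class."""
    if not records:
        raise ValueError("cohort_summary requires a non-empty record set")
    rows = []
    groups: dict[str, list[VisualFieldRecord]] = {}
    for rec in records:
        groups.setdefault(getattr(rec, by), []).append(rec)
    order = [g for g in VISIT_TYPES if g in groups] if by == "visit_type" else sorted(groups)
    for name in order:
        recs = groups[name]
        if not recs:
            warnings.warn(f"group {name!r} is empty; omitted from summary")
            continue
        md = np.array([r.md for r in recs])
        q1, q2, q3 = np.percentile(md, [25, 50, 75])
        row = {
            "group": name,
            "n": len(recs),
            "md_mean": md.mean(),
            "md_sd": md.std(ddof=1) if len(recs) > 1 else 0.0,
            "md_q1": q1,
            "md_q2": q2,
            "md_q3": q3,
            "md_iqr": q3 - q1,
        }
        for cls in SeverityClass:
            n_cls = sum(r.severity(config) is cls for r in recs)
            row[f"n_{cls.value}"] = n_cls
            row[f"pct_{cls.value}"] = 100.0 * n_cls / len(recs)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
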