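"""Decomposition of visual fields onto a frozen archetype basis.

Each field's TD vector is expressed as the best convex combination of the
model's archetypes; the coefficients, scaled by 100, are the percent weights
(PW), which are non-negative and sum to 100.  A PW of at least 9% (before any
display rounding) counts as clinically meaningful; the abnormal meaningful
set excludes the normal archetype (AT1, the highest-average-TD pattern).  A
field with MD >= -2 dB that still carries an abnormal meaningful archetype is
flagged as a residual deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._simplex import simplex_coefficients
from .aa import ArchetypalAnalysis
from .config import DEFAULT_CONFIG
from .model import ArchetypeModel
from .records import VisualFieldRecord

MD_NORMAL_DB = -2.0


@dataclass
class Decomposition:
    pw: np.ndarray  # (k,) percent weights, sum to 100
    rss: float  # residual of this field against the basis
    normal_index: int  # 0-based index of the normal archetype
    cutoff_pct: float = DEFAULT_CONFIG.meaningful_cutoff_pct
    record: VisualFieldRecord | None = None

    def __post_init__(self) -> None:
        self.pw = np.asarray(self.pw, dtype=float)

    @property
    def k(self) -> int:
        return self.pw.shape[0]

    @property
    def dominant_at(self) -> int:
        """1-based index of the largest PW (ties to the lowest index)."""
        return int(np.argmax(self.pw)) + 1

    @property
    def meaningful_set(self) -> set[int]:
        return meaningful_ats(self, self.cutoff_pct)

    @property
    def abnormal_meaningful_set(self) -> set[int]:
        return self.meaningful_set - {self.normal_index + 1}


def _basis(model: ArchetypeModel | ArchetypalAnalysis) -> tuple[np.ndarray, int]:
    if isinstance(model, ArchetypeModel):
        return model.archetypes, model.normal_index
    return model.archetypes_, model.normal_index_


def decompose(
    vf: VisualFieldRecord | np.ndarray,
    model: ArchetypeModel | ArchetypalAnalysis,
    cutoff_pct: float = DEFAULT_CONFIG.meaningful_cutoff_pct,
    mirrored: bool = False,
) -> Decomposition:
    """Decompose one field into percent weights over the model's archetypes.

    ``mirrored`` states the orientation convention of the input TD vector and
    must match the model's; a mismatch is a hard error rather than a silent
    misalignment of nasal and temporal points.
    """
    Z, normal_index = _basis(model)
    if isinstance(model, ArchetypeModel) and model.mirrored != mirrored:
        raise ValueError(
            "orientation mismatch: model mirrored="
            f"{model.mirrored}, field mirrored={mirrored}"
        )
    record = vf if isinstance(vf, VisualFieldRecord) else None
    td = vf.td if isinstance(vf, VisualFieldRecord) else np.asarray(vf, dtype=float)
    if td.shape != (Z.shape[1],):
        raise ValueError(f"field has {td.shape} TD values, model expects {Z.shape[1]}")
    W, _ = simplex_coefficients(td[None, :], Z, max_iter=800)
    w = W[0]
    resid = td - w @ Z
    return Decomposition(
        pw=100.0 * w,
        rss=float(resid @ resid),
        normal_index=normal_index,
        cutoff_pct=cutoff_pct,
        record=record,
    )


def decompose_records(
    records: list[VisualFieldRecord],
    model: ArchetypeModel | ArchetypalAnalysis,
    cutoff_pct: float = DEFAULT_CONFIG.meaningful_cutoff_pct,
    mirrored: bool = False,
) -> list[Decomposition]:
    """Vectorised decomposition of many records against one frozen basis."""
    Z, normal_index = _basis(model)
    if isinstance(model, ArchetypeModel) and model.mirrored != mirrored:
        raise ValueError("orientation mismatch between model and fields")
    if not records:
        return []
    X = np.stack([r.td for r in records])
    W, _ = simplex_coefficients(X, Z, max_iter=800)
    R = X - W @ Z
    return [
        Decomposition(
            pw=100.0 * W[i],
            rss=float(R[i] @ R[i]),
            normal_index=normal_index,
            cutoff_pct=cutoff_pct,
            record=records[i],
        )
        for i in range(len(records))
    ]


def meaningful_ats(dec: Decomposition, cutoff_pct: float | None = None) -> set[int]:
    """1-based archetype indices whose unrounded PW is >= the cutoff (9% by
    default; the cutoff is inclusive, so exactly 9.0% counts and 8% does not)."""
    cutoff = dec.cutoff_pct if cutoff_pct is None else cutoff_pct
    if not 0 < cutoff < 100:
        raise ValueError("cutoff must lie in (0, 100)")
    return {int(i) + 1 for i in np.flatnonzero(dec.pw >= cutoff)}


def count_abnormal(dec: Decomposition) -> int:
    """Number of meaningful archetypes other than the normal pattern."""
    return len(dec.abnormal_meaningful_set)


def residual_deficit(vf: VisualFieldRecord, dec: Decomposition) -> bool:
    """True iff the field is 'normal' by MD (>= -2.00 dB) yet decomposes into
    at least one abnormal archetype of meaningful PW."""
    return vf.md >= MD_NORMAL_DB and bool(dec.abnormal_meaningful_set)


def decompositions_to_frame(decs: list[Decomposition]) -> pd.DataFrame:
    """Per-field table: identifiers, pw_1..pw_k, dominant AT, meaningful list,
    abnormal count and residual-deficit flag (for CLI export)."""
    rows = []
    for dec in decs:
        rec = dec.record
        row: dict[str, object] = {
            "patient_id": rec.patient_id if rec else None,
            "eye": rec.eye if rec else None,
            "visit_day": rec.visit_day if rec else None,
            "visit_type": rec.visit_type if rec else None,
            "md": rec.md if rec else None,
        }
        for j in range(dec.k):
            row[f"pw_{j + 1}"] = dec.pw[j]
        row["rss"] = dec.rss
        row["dominant_at"] = dec.dominant_at
        row["meaningful_ats"] = "|".join(f"AT{i}" for i in sorted(dec.meaningful_set))
        row["n_abnormal_meaningful"] = count_abnormal(dec)
        row["residual_deficit"] = (
            residual_deficit(rec, dec) if rec is not None else None
        )
        rows.append(row)
    return pd.DataFrame(rows)
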