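"""Cohort-level summaries and hypothesis tests.

Covers the archetype-level dataset summaries (relative weights, average TD,
prevalence of meaningful archetypes), the AT1-weight/MD association
(Spearman), the prognosis split of eyes by mean presentation AT1 percent
weight with MD-over-time group curves, and generic two-group comparisons
(Mann-Whitney rank-sum, chi-square).  Analyses are eye-level, as is common in
this literature; patient ids are carried so users can cluster-bootstrap
confidence intervals instead of the default t-based ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .config import DEFAULT_CONFIG, AnalysisConfig
from .decomposition import Decomposition, count_abnormal
from .records import VisualFieldRecord

ALPHA = 0.05


# ----------------------------------------------------------------- archetypes
def relative_weights(decompositions: list[Decomposition]) -> np.ndarray:
    """RW per archetype: mean percent weight over all fields (sums to 100)."""
    if not decompositions:
        raise ValueError("relative_weights requires at least one decomposition")
    k = decompositions[0].k
    normal = decompositions[0].normal_index
    if any(d.k != k or d.normal_index != normal for d in decompositions):
        raise ValueError("decompositions come from different models")
    return np.mean([d.pw for d in decompositions], axis=0)


def average_td(archetype: np.ndarray) -> float:
    """Unweighted mean TD (dB) of one archetype vector."""
    archetype = np.asarray(archetype, dtype=float)
    if archetype.shape != (52,):
        raise ValueError("archetype must have 52 values")
    return float(archetype.mean())


def at_prevalence(
    decompositions: list[Decomposition],
    scope: str | None = None,
) -> pd.DataFrame:
    """Per archetype: how many fields carry it at meaningful PW, and the
    distribution of abnormal meaningful-AT counts per field.

    ``scope`` filters to one visit type (requires record-annotated
    decompositions).  Returns a table with one row per archetype plus
    summary attributes ``abnormal_count_distribution`` and
    ``pct_no_abnormal`` in ``DataFrame.attrs``.
    """
    decs = decompositions
    if scope is not None:
        decs = [d for d in decs if d.record is not None and d.record.visit_type == scope]
    if not decs:
        import warnings

        warnings.warn(f"no decompositions in scope {scope!r}", RuntimeWarning)
        return pd.DataFrame(columns=["archetype", "n_meaningful", "pct_meaningful"])
    n = len(decs)
    k = decs[0].k
    rows = []
    for j in range(1, k + 1):
        count = sum(j in d.meaningful_set for d in decs)
        rows.append(
            {"archetype": f"AT{j}", "n_meaningful": count, "pct_meaningful": 100.0 * count / n}
        )
    df = pd.DataFrame(rows)
    counts = [count_abnormal(d) for d in decs]
    dist = pd.Series(counts).value_counts().sort_index().to_dict()
    df.attrs["abnormal_count_distribution"] = dist
    df.attrs["pct_no_abnormal"] = 100.0 * sum(c == 0 for c in counts) / n
    df.attrs["mean_abnormal"] = float(np.mean(counts))
    df.attrs["sd_abnormal"] = float(np.std(counts, ddof=1)) if n > 1 else 0.0
    return df


# ---------------------------------------------------------------- correlation
def pw_md_correlation(
    pw: np.ndarray, md: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between an archetype's PW and MD.

    Ties are handled by average ranks (the default of the underlying
    implementation).  Raises on constant input, where the correlation is
    undefined.
    """
    pw = np.asarray(pw, dtype=float)
    md = np.asarray(md, dtype=float)
    if pw.shape != md.shape or pw.ndim != 1:
        raise ValueError("pw and md must be 1-D arrays of equal length")
    if pw.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(pw == pw[0]) or np.all(md == md[0]):
        raise ValueError("correlation undefined for constant input")
    res = scipy.stats.spearmanr(pw, md)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------- group testing
def compare_groups(
    a, b=None, kind: str = "ranksum"
) -> tuple[float, float]:
    """Two-sided two-group test: ``ranksum`` (Mann-Whitney U) on two samples,
    or ``chisq`` on a contingency table passed as ``a``."""
    if kind == "ranksum":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("ranksum requires two non-empty samples")
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if kind == "chisq":
        table = np.asarray(a, dtype=float)
        res = scipy.stats.chi2_contingency(table)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def t_confidence_interval(sample: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-based CI for the mean (falls back to a point interval for n = 1)."""
    sample = np.asarray(sample, dtype=float)
    m = float(sample.mean())
    if sample.size < 2:
        return (m, m)
    half = float(
        scipy.stats.t.ppf(0.5 + level / 2, sample.size - 1)
        * sample.std(ddof=1)
        / np.sqrt(sample.size)
    )
    return (m - half, m + half)


# ------------------------------------------------------------ prognosis split
@dataclass
class PrognosisSplit:
    mean_presentation_pw: float
    above_eyes: list[str]
    below_eyes: list[str]
    md_by_window: pd.DataFrame  # window x group: n, mean MD, CI
    final_pw: dict[str, tuple[float, tuple[float, float]]]  # group -> (mean, CI)
    final_pw_pvalue: float
    md_pvalues: dict[str, float] = field(default_factory=dict)  # window -> ranksum p


def _window_of(rec: VisualFieldRecord, config: AnalysisConfig) -> str | None:
    if rec.visit_type == "presentation":
        return "presentation"
    if rec.visit_type == "final":
        return "final"
    if 0 < rec.visit_day <= config.interim_break_day:
        return "interim_early"
    if config.interim_break_day < rec.visit_day <= config.interim_end_day:
        return "interim_late"
    return None


def prognosis_split(
    presentation_decs: list[Decomposition],
    records: list[VisualFieldRecord],
    final_decs: list[Decomposition] | None = None,
    at_index: int = 1,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> PrognosisSplit:
    """Split eyes by mean presentation PW of one archetype (AT1 by default)
    and compare MD over time between the groups.

    Only eyes that also have a final visit contribute to the mean divider.
    Eyes exactly at the mean go to the 'above' group.  Per visit window and
    group the mean MD with a 95% t-CI is computed, with a rank-sum p-value
    for the group difference; final-visit PW of the same archetype is
    summarised per group when final-visit decompositions are supplied.
    """
    j = at_index - 1
    eyes_with_final = {r.eye_id for r in records if r.visit_type == "final"}
    pres_pw: dict[str, float] = {}
    for dec in presentation_decs:
        if dec.record is None or dec.record.visit_type != "presentation":
            raise ValueError("presentation_decs must be record-annotated presentation fields")
        pres_pw[dec.record.eye_id] = float(dec.pw[j])
    eligible = {e: p for e, p in pres_pw.items() if e in eyes_with_final}
    if not eligible:
        raise ValueError("no eyes with both presentation and final visits")
    mean_pw = float(np.mean(list(eligible.values())))
    above = sorted(e for e, p in eligible.items() if p >= mean_pw)
    below = sorted(e for e, p in eligible.items() if p < mean_pw)
    if not above or not below:
        raise ValueError(
            f"degenerate split: all eligible eyes fall on one side of the mean "
            f"presentation AT{at_index} PW ({mean_pw:.2f}%)"
        )
    group_of = {e: "above" for e in above}
    group_of.update({e: "below" for e in below})

    rows = []
    md_pvalues: dict[str, float] = {}
    windows = ("presentation", "interim_early", "interim_late", "final")
    for window in windows:
        samples: dict[str, list[float]] = {"above": [], "below": []}
        for rec in records:
            grp = group_of.get(rec.eye_id)
            if grp is None or _window_of(rec, config) != window:
                continue
            samples[grp].append(rec.md)
        for grp in ("above", "below"):
            vals = np.array(samples[grp])
            if vals.size == 0:
                continue
            lo, hi = t_confidence_interval(vals)
            rows.append(
                {
                    "window": window,
                    "group": grp,
                    "n": vals.size,
                    "md_mean": vals.mean(),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        if samples["above"] and samples["below"]:
            _, p = compare_groups(samples["above"], samples["below"], kind="ranksum")
            md_pvalues[window] = p

    final_pw: dict[str, tuple[float, tuple[float, float]]] = {}
    final_pw_pvalue = float("nan")
    if final_decs:
        fin: dict[str, list[float]] = {"above": [], "below": []}
        for dec in final_decs:
            if dec.record is None:
                continue
            grp = group_of.get(dec.record.eye_id)
            if grp is not None and dec.record.visit_type == "final":
                fin[grp].append(float(dec.pw[j]))
        for grp, vals in fin.items():
            if vals:
                arr = np.array(vals)
                final_pw[grp] = (float(arr.mean()), t_confidence_interval(arr))
        if fin["above"] and fin["below"]:
            _, final_pw_pvalue = compare_groups(fin["above"], fin["below"], kind="ranksum")

    return PrognosisSplit(
        mean_presentation_pw=mean_pw,
        above_eyes=above,
        below_eyes=below,
        md_by_window=pd.DataFrame(rows),
        final_pw=final_pw,
        final_pw_pvalue=final_pw_pvalue,
        md_pvalues=md_pvalues,
    )
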