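"""Patient-grouped cross-validated choice of the number of archetypes.

All fields of a patient (both eyes, all visits) share a fold, so the test
score measures generalisation to unseen patients rather than to repeat exams
of seen ones.  For each candidate ``k`` the model is fitted on the training
folds and held-out fields are decomposed onto the frozen basis (no refit), the
way new fields are scored clinically; the residual sum of squares of those
reconstructions is the test RSS.  The elbow rule turns the usual visual
"where does the curve flatten" judgment into an explicit default: the
smallest ``k`` whose relative improvement over ``k - 1`` drops below 2% and
stays below for all larger ``k``.  The suggestion is advisory; the curve is
always returned in full.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aa import ArchetypalAnalysis, compute_rss
from .records import VisualFieldRecord


@dataclass
class FoldAssignment:
    fold_of_patient: dict[str, int]  # patient id -> fold 1..n_folds
    n_folds: int

    def fold_of_record(self, rec: VisualFieldRecord) -> int:
        return self.fold_of_patient[rec.patient_id]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.fold_of_patient.values():
            sizes[f - 1] += 1
        return sizes


def assign_folds(
    records: list[VisualFieldRecord] | list[str],
    n_folds: int = 10,
    seed: int | None = 0,
) -> FoldAssignment:
    """Deal patients into folds: shuffle by seed, then round-robin.

    Accepts records or bare patient ids.  Fold sizes differ by at most one
    patient, and the assignment depends only on the set of patients and the
    seed, not on record order.
    """
    ids = [r.patient_id if isinstance(r, VisualFieldRecord) else r for r in records]
    patients = sorted(set(ids))
    if len(patients) < n_folds:
        raise ValueError(
            f"need at least {n_folds} patients for {n_folds} folds, got {len(patients)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of_patient = {
        patients[p]: (i % n_folds) + 1 for i, p in enumerate(order)
    }
    return FoldAssignment(fold_of_patient=fold_of_patient, n_folds=n_folds)


@dataclass
class RssCurve:
    ks: list[int]
    train_rss: list[float]  # mean over folds, per k
    test_rss: np.ndarray  # (len(ks), n_folds), per-fold held-out RSS
    chosen_k: int | None = None
    rationale: str = ""
    no_plateau: bool = False
    failures: list[tuple[int, int, str]] = field(default_factory=list)  # (k, fold, msg)

    @property
    def mean_test_rss(self) -> np.ndarray:
        return np.nanmean(self.test_rss, axis=1)

    @property
    def sd_test_rss(self) -> np.ndarray:
        return np.nanstd(self.test_rss, axis=1, ddof=1)

    def flattening_k(self, threshold: float = 0.02) -> int:
        """The k at which the curve flattens: the last k whose relative mean
        test-RSS improvement over k-1 still reaches the threshold (equal to
        the elbow suggestion minus one when a plateau exists)."""
        values = self.mean_test_rss
        last = self.ks[0]
        for i in range(1, len(self.ks)):
            if (values[i - 1] - values[i]) / values[i - 1] >= threshold:
                last = self.ks[i]
        return last

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "k": self.ks,
                "train_rss_mean": self.train_rss,
                "test_rss_mean": self.mean_test_rss,
                "test_rss_sd": self.sd_test_rss,
            }
        )
        for f in range(self.test_rss.shape[1]):
            df[f"test_rss_fold{f + 1}"] = self.test_rss[:, f]
        return df


def rss_curve(
    records: list[VisualFieldRecord],
    folds: FoldAssignment,
    k_values: range | list[int] = range(2, 21),
    seed: int | None = 0,
    n_restarts: int = 2,
    max_iter: int = 30,
    elbow_threshold: float = 0.02,
    **fit_kwargs,
) -> RssCurve:
    """Grouped cross-validated RSS for each candidate number of archetypes."""
    ks = sorted(int(k) for k in k_values)
    X = np.stack([r.td for r in records])
    rec_folds = np.array([folds.fold_of_record(r) for r in records])
    min_train = min(
        int(np.sum(rec_folds != f)) for f in range(1, folds.n_folds + 1)
    )
    if ks[-1] >= min_train:
        raise ValueError(
            f"k_max={ks[-1]} must be smaller than the smallest training split "
            f"({min_train} fields)"
        )
    seeds = np.random.SeedSequence(seed).generate_state(len(ks) * folds.n_folds)
    train_rss = []
    test_rss = np.full((len(ks), folds.n_folds), np.nan)
    failures: list[tuple[int, int, str]] = []
    for ki, k in enumerate(ks):
        fold_train = []
        for f in range(1, folds.n_folds + 1):
            train = X[rec_folds != f]
            test = X[rec_folds == f]
            est = ArchetypalAnalysis(
                n_archetypes=k,
                n_restarts=n_restarts,
                max_iter=max_iter,
                random_state=int(seeds[ki * folds.n_folds + (f - 1)] % (2**31)),
                **fit_kwargs,
            )
            try:
                est.fit(train)
            except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                failures.append((k, f, str(exc)))
                continue
            fold_train.append(est.rss_)
            if len(test):
                W = est.transform(test)
                test_rss[ki, f - 1] = compute_rss(test, W, est.archetypes_)
        train_rss.append(float(np.mean(fold_train)) if fold_train else np.nan)
    curve = RssCurve(
        ks=ks, train_rss=train_rss, test_rss=test_rss, failures=failures
    )
    curve.chosen_k, curve.rationale, curve.no_plateau = suggest_elbow(
        curve, rel_improvement_threshold=elbow_threshold
    )
    return curve


def suggest_elbow(
    curve: RssCurve | np.ndarray,
    rel_improvement_threshold: float = 0.02,
    ks: list[int] | None = None,
) -> tuple[int, str, bool]:
    """Suggest the elbow of an RSS curve.

    Returns the smallest k whose relative test-RSS improvement over k-1 falls
    below the threshold and stays below for all larger k, with a rationale
    string.  If improvements never drop below the threshold, the largest k is
    returned with the ``no_plateau`` flag set.  The suggestion is advisory
    only — it is printed alongside the full curve, never auto-applied.
    """
    if isinstance(curve, RssCurve):
        values = curve.mean_test_rss
        ks = curve.ks
    else:
        values = np.asarray(curve, dtype=float)
        if ks is None:
            ks = list(range(2, 2 + len(values)))
    if len(values) < 3:
        raise ValueError("elbow suggestion needs at least 3 curve points")
    improvements = (values[:-1] - values[1:]) / values[:-1]
    below = improvements < rel_improvement_threshold
    for i in range(len(below)):
        if below[i:].all():
            k = ks[i + 1]
            return (
                k,
                f"first sustained relative improvement < {rel_improvement_threshold:.0%} at k={k}",
                False,
            )
    warnings.warn("RSS curve shows no plateau; returning k_max", RuntimeWarning)
    return ks[-1], "no plateau: improvements never fell below threshold", True
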