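"""Synthetic longitudinal visual-field cohorts with known archetypal structure.

Every pipeline stage in this package is validated against cohorts generated
here, because the ground truth — which defect patterns were planted, with
what mixture weights, and how they drifted over visits — is known exactly.

Each eye draws a presentation mixture over a library of planted TD patterns
from a Dirichlet distribution; at each later visit a fraction of the
abnormal mixture mass shifts multiplicatively toward the normal pattern
(recovery; a negative rate models progression); the TD vector is the convex
mixture of the templates plus i.i.d. Gaussian test-retest noise per point;
and MD is defined as the unweighted mean of the 52 TD values (the device's
proprietary variance-weighted MD is deliberately not imitated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .grid import GRID
from .records import TD_MAX_DB, TD_MIN_DB, VisualFieldRecord

NORMAL_LEVEL_DB = 2.4  # baseline TD of the healthy template

# name -> (mask predicate on (x, y) degrees, default depth dB)
_COORDS = GRID.active_coords
_X, _Y = _COORDS[:, 0], _COORDS[:, 1]

_PATTERN_DEFS: dict[str, tuple[np.ndarray, float]] = {
    "normal": (np.ones(52, dtype=bool), NORMAL_LEVEL_DB),
    "enlarged_blind_spot": (
        (np.abs(_X - 15) <= 6) & (np.abs(_Y) <= 9),
        -12.0,
    ),
    "superior_arcuate": (
        (_Y >= 15) | ((_Y == 9) & (_X <= -9)),
        -22.0,
    ),
    "inferior_nasal_wedge": ((_X <= -9) & (_Y < 0), -20.0),
    "superior_nasal_wedge": ((_X <= -9) & (_Y > 0), -20.0),
    "inferior_altitudinal": (_Y < 0, -26.0),
    "global_depression_mild": (np.ones(52, dtype=bool), -5.0),
    "global_loss_severe": (np.ones(52, dtype=bool), -32.0),
    "peripheral_rim": (np.maximum(np.abs(_X), np.abs(_Y)) >= 21, -28.0),
}

PATTERN_NAMES = tuple(_PATTERN_DEFS)

#: Affinely independent subset used for identifiable parameter-recovery
#: benchmarks (the three constant patterns are collinear and excluded).
RECOVERY_PATTERNS = (
    "normal",
    "enlarged_blind_spot",
    "superior_arcuate",
    "inferior_nasal_wedge",
    "inferior_altitudinal",
)

#: Default Dirichlet concentrations: mass favours the normal pattern, sparse
#: abnormal components give near-pure defect fields and an MD distribution
#: spanning normal through severe.
DEFAULT_MIXING: dict[str, float] = {
    "normal": 1.2,
    "enlarged_blind_spot": 0.4,
    "superior_arcuate": 0.3,
    "inferior_nasal_wedge": 0.3,
    "superior_nasal_wedge": 0.3,
    "inferior_altitudinal": 0.25,
    "global_depression_mild": 0.4,
    "global_loss_severe": 0.2,
    "peripheral_rim": 0.2,
}


@dataclass(frozen=True)
class PlantedPattern:
    name: str
    td: np.ndarray  # (52,) template, dB
    mask: np.ndarray  # (52,) bool region of the defect
    depth: float  # dB value planted inside the mask


def make_pattern_library(
    depth_overrides: dict[str, float] | None = None,
) -> list[PlantedPattern]:
    """The nine named defect templates on the 24-2 grid.

    Each template equals the healthy baseline (+2.4 dB) outside its region
    mask and the pattern's depth inside it.  ``depth_overrides`` replaces the
    depth of named patterns; unknown names are an error.
    """
    overrides = dict(depth_overrides or {})
    unknown = set(overrides) - set(_PATTERN_DEFS)
    if unknown:
        raise ValueError(f"unknown pattern name(s): {sorted(unknown)}")
    library = []
    for name, (mask, depth) in _PATTERN_DEFS.items():
        depth = overrides.get(name, depth)
        td = np.full(52, NORMAL_LEVEL_DB)
        td[mask] = depth
        library.append(PlantedPattern(name=name, td=td, mask=mask.copy(), depth=depth))
    return library


@dataclass
class SyntheticCohortSpec:
    n_patients: int = 100
    eyes_per_patient: int = 2
    visit_days: tuple[int, ...] = (0, 40, 110, 210)
    pattern_names: tuple[str, ...] = PATTERN_NAMES
    mixing: dict[str, float] | None = None  # Dirichlet concentration per pattern
    recovery_drift: float = 0.35  # fraction of abnormal mass recovered per 75 days
    noise_sd: float = 1.0  # dB, i.i.d. per point
    depth_overrides: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.eyes_per_patient < 1:
            raise ValueError("cohort must contain at least one eye")
        if self.visit_days[0] != 0:
            raise ValueError("visit schedule must start at day 0")
        if list(self.visit_days) != sorted(set(self.visit_days)):
            raise ValueError("visit_days must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if "normal" not in self.pattern_names:
            raise ValueError("the pattern set must include 'normal'")
        if self.mixing is not None:
            missing = set(self.pattern_names) - set(self.mixing)
            if missing:
                raise ValueError(f"mixing missing concentrations for {sorted(missing)}")
            if min(self.mixing[n] for n in self.pattern_names) <= 0:
                raise ValueError("Dirichlet concentrations must be > 0")

    @property
    def alphas(self) -> np.ndarray:
        mixing = self.mixing if self.mixing is not None else DEFAULT_MIXING
        return np.array([mixing[n] for n in self.pattern_names], dtype=float)


def recovery_benchmark_spec(
    n_patients: int = 50, seed: int = 0, noise_sd: float = 1.0
) -> SyntheticCohortSpec:
    """The 5-pattern identifiable benchmark: sparse Dirichlet(0.3) mixtures
    of affinely independent templates, 2 eyes x 3 visits per patient."""
    return SyntheticCohortSpec(
        n_patients=n_patients,
        eyes_per_patient=2,
        visit_days=(0, 80, 200),
        pattern_names=RECOVERY_PATTERNS,
        mixing={name: 0.3 for name in RECOVERY_PATTERNS},
        recovery_drift=0.35,
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class CohortTruth:
    """Ground truth aligned with the generated record list."""

    pattern_names: tuple[str, ...]
    templates: np.ndarray  # (k, 52)
    weights: np.ndarray  # (n_records, k), rows on the simplex
    eye_ids: list[str]
    visit_days: list[int]
    spec: SyntheticCohortSpec

    @property
    def normal_column(self) -> int:
        return self.pattern_names.index("normal")


def _drift(w: np.ndarray, normal_col: int, rate: float, dt_days: float) -> np.ndarray:
    """Move abnormal mixture mass multiplicatively toward the normal pattern."""
    factor = (1.0 - rate) ** (dt_days / 75.0)
    w = w.copy()
    abnormal = np.arange(w.size) != normal_col
    w[abnormal] *= factor
    w[normal_col] = 1.0 - w[abnormal].sum()
    return w


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[VisualFieldRecord], CohortTruth]:
    """Generate a longitudinal cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    library = {p.name: p for p in make_pattern_library(spec.depth_overrides)}
    templates = np.stack([library[n].td for n in spec.pattern_names])
    normal_col = spec.pattern_names.index("normal")
    alphas = spec.alphas
    lo, hi = 150, 365  # final-visit window, days

    records: list[VisualFieldRecord] = []
    all_w: list[np.ndarray] = []
    eye_ids: list[str] = []
    days_out: list[int] = []
    eyes = ("OD", "OS")[: spec.eyes_per_patient]
    width = max(3, len(str(spec.n_patients)))
    final_day = None
    for d in spec.visit_days:
        if lo <= d <= hi:
            final_day = d  # last qualifying visit wins
    for p in range(spec.n_patients):
        pid = f"P{p + 1:0{width}d}"
        for eye in eyes:
            w = rng.dirichlet(alphas)
            prev_day = 0
            for day in spec.visit_days:
                if day > 0:
                    w = _drift(w, normal_col, spec.recovery_drift, day - prev_day)
                prev_day = day
                td = w @ templates
                if spec.noise_sd > 0:
                    td = td + rng.normal(0.0, spec.noise_sd, size=52)
                td = np.clip(td, TD_MIN_DB, TD_MAX_DB)
                if day == 0:
                    vtype = "presentation"
                elif day == final_day:
                    vtype = "final"
                else:
                    vtype = "interim"
                records.append(
                    VisualFieldRecord(
                        patient_id=pid,
                        eye=eye,
                        visit_day=day,
                        visit_type=vtype,
                        td=td,
                        md=float(td.mean()),
                    )
                )
                all_w.append(w.copy())
                eye_ids.append(f"{pid}:{eye}")
                days_out.append(day)
    truth = CohortTruth(
        pattern_names=tuple(spec.pattern_names),
        templates=templates,
        weights=np.stack(all_w),
        eye_ids=eye_ids,
        visit_days=days_out,
        spec=spec,
    )
    return records, truth


# ---------------------------------------------------------------- recovery
@dataclass
class RecoveryScore:
    matching: np.ndarray  # estimated-archetype index matched to each truth pattern
    similarities: np.ndarray  # cosine similarity per matched pair
    pw_mae: float | None  # mean |estimated PW - 100 * true weight|, percent points
    partial: bool = False


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    return An @ Bn.T


def score_recovery(
    model,
    truth: CohortTruth,
    decompositions=None,
) -> RecoveryScore:
    """Match estimated archetypes to planted templates and score the fit.

    The matching is the optimal one-to-one assignment on cosine distance
    (order-free, so shuffled archetypes score identically).  When
    decompositions aligned with the truth records are supplied, the percent
    weights are compared entry-wise with the planted mixture weights.
    ``model`` may be an ArchetypeModel, a fitted estimator, or a raw (k, 52)
    array.
    """
    if hasattr(model, "archetypes"):
        Z = np.asarray(model.archetypes, dtype=float)
    elif hasattr(model, "archetypes_"):
        Z = np.asarray(model.archetypes_, dtype=float)
    else:
        Z = np.atleast_2d(np.asarray(model, dtype=float))
    k_true = truth.templates.shape[0]
    partial = Z.shape[0] != k_true
    sim = cosine_similarity_matrix(truth.templates, Z)
    rows, cols = scipy.optimize.linear_sum_assignment(1.0 - sim)
    matching = np.full(k_true, -1, dtype=int)
    matching[rows] = cols
    sims = sim[rows, cols]
    pw_mae = None
    if decompositions is not None:
        matched = matching[matching >= 0]
        est = np.stack([np.asarray(d.pw, dtype=float) for d in decompositions])
        est_matched = est[:, matched]
        true_pw = 100.0 * truth.weights[:, rows]
        pw_mae = float(np.abs(est_matched - true_pw).mean())
    return RecoveryScore(
        matching=matching, similarities=sims, pw_mae=pw_mae, partial=partial
    )
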