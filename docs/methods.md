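# Methods

## The model

A 24-2 visual field is summarised by its 52 total-deviation (TD) values (the
54-point grid minus the two blind-spot points), each the difference in dB
between measured and age-normal sensitivity at one location. Archetypal
analysis represents a matrix `X` (fields × 52) by the convex factorisation

    X ≈ A Z,   Z = B X,

where the `k` rows of `Z` are *archetypes* — extreme, clinically recognisable
patterns of field loss — and the rows of `A` and `B` are constrained to the
probability simplex (non-negative, summing to one). Because `Z = B X`, every
archetype is itself a convex combination of observed fields and therefore a
realisable field, which is what makes the patterns readable by clinicians.
Scaling a field's coefficients by 100 gives its *percent weights* (PW); the
mean PW of an archetype over a dataset is its *relative weight* (RW), and the
unweighted mean of an archetype's 52 values is its *average TD*. Archetypes
are stored and labelled in descending RW order; the archetype with the
highest average TD (in practice also the highest RW — a disagreement raises a
warning) is designated the normal pattern, AT1.

## Fitting

The residual sum of squares `‖X − A B X‖²` is minimised by alternating two
updates, each of which cannot increase the objective:

* **Coefficient step.** Each row of `A` solves an exact simplex-constrained
  least-squares projection of its field onto the current archetypes.
* **Generator step.** `B` takes accelerated projected-gradient steps (FISTA
  with a monotone safeguard that keeps the best iterate and restarts momentum
  on any objective increase) on the true objective, with each row projected
  onto the simplex by the standard sort-and-threshold algorithm.

Consequently the recorded RSS path is non-increasing to solver tolerance — a
property the tests assert on every fit. At the end of each restart the
coefficient rows are polished by an exact KKT solve on their active support;
the Gram system of that solve is condition-guarded: if its condition number
exceeds `max_kappa` (default 1000) the smallest diagonal ridge bringing it to
the bound is added and recorded in the fit metadata. A restart stops when
the relative RSS improvement falls below `min_improvement` (default √eps ≈
1.5e-8) or after `max_iterations` (default 100). Fits run `n_restarts`
(default 5) random initialisations — each archetype initialised at a distinct
observed field — and keep the lowest-RSS solution, ties (within 1e-12) going
to the lowest restart index for determinism. All randomness flows from one
user-supplied seed.

The classical penalty-row device (append a large constant row so an ordinary
least-squares solve is driven toward sum-one coefficients, then clip and
renormalise) is the historical formulation of these subproblems;
`penalty_weight` is retained and validated as an option field, but the exact
projection solver supersedes it because the clip-and-renormalise step cannot
guarantee the monotone-descent and oracle-agreement tolerances this package
promises. Per-observation weights are deliberately not implemented; the API
reserves the parameter and rejects non-uniform values.

Decomposition of a new field onto a frozen model reuses the same exact
solver (projected gradient plus KKT polish), so percent weights are
non-negative, sum to 100 within 1e-6, and match a 0.01-step simplex grid
search within one percent point on small bases (asserted in tests).

## Model-order selection

Ten-fold cross-validation is grouped by patient: all visits and both eyes of
a patient share a fold (patients shuffled by seed, dealt round-robin; fold
sizes differ by at most one patient). For each candidate `k` (default 2–20)
the model is fitted on the training folds and held-out fields are decomposed
onto the frozen basis — no refitting — mirroring how new fields are scored
clinically. The elbow rule makes the visual "where does the curve flatten"
judgment explicit: the suggested `k` is the smallest whose relative mean
test-RSS improvement over `k−1` falls below 2% and stays below for all larger
`k`; `flattening_k` (the suggestion minus one, i.e. the last `k` with a
substantial improvement) marks where the plateau begins. If no plateau
exists the largest `k` is returned with a flag. The suggestion is advisory:
the CLI prints the full curve and a production model order is pinned in
configuration rather than trusted to the heuristic.

Held-out RSS at the planted model order sits above the pure noise floor
`n·52·σ²`, because archetypes estimated from noisy data contract slightly
inside the data hull; at the cohort sizes used in the test suite
(~200–500 fields) the measured excess is roughly 10–25% and shrinks with
training size. The selection signal — a large drop up to the planted order
and sub-2% improvements beyond it — is unaffected.

## Clinical conventions

* Severity strata on MD: severe `< −15`, moderate `[−15, −7)`, mild
  `[−7, −2)`, normal `≥ −2` dB.
* Reliability: keep a field only if every available index is strictly below
  its threshold (fixation losses < 33%, false positives/negatives < 15%);
  fields with no reliability metadata are kept and flagged "unverified",
  since deposited tables typically had the filter applied upstream.
* A PW ≥ 9% (unrounded, before display rounding) is clinically meaningful;
  the abnormal meaningful set excludes AT1. A final-visit field with
  MD ≥ −2.00 dB but a non-empty abnormal meaningful set is a residual
  deficit.
* Visit typing per eye: first exam is the presentation (days rebased to 0),
  the last exam within 150–365 days (five to twelve months) is the final
  visit, everything else interim; interim windows split at day 75.
* The prognosis split divides eyes (restricted to those with a final visit)
  at the cohort mean presentation AT1 PW; eyes exactly at the mean go to the
  "above" group. Group MD trajectories carry t-based 95% CIs; group
  differences use two-sided Mann-Whitney tests at α = 0.05. Analyses are
  eye-level without inter-eye correlation adjustment, as is usual in this
  literature; patient ids are retained so users can cluster-bootstrap.
* MD is always taken verbatim from the input table, never recomputed from
  TD: the device's MD is a normative-variance-weighted mean with proprietary
  weights.
* Left-eye fields are not mirrored by default; a `mirror_left_eyes` flag
  reflects the grid horizontally for users who want eye-pooled pattern
  symmetry, and the flag is recorded in every model's metadata. Decomposing
  a field against a model with a different orientation convention is a hard
  error.

## The synthetic cohort generator

The generator emulates a papilledema clinic cohort: ~100–250 eyes (default
100 patients × 2 eyes), visits at days 0/40/110/210, TD vectors built as
convex mixtures of planted defect templates plus i.i.d. Gaussian test-retest
noise (default 1 dB), and MD defined as the unweighted mean of the 52 TD
values. Nine templates are defined on the grid: normal (+2.4 dB constant),
enlarged blind spot (depression confined to the points adjacent to the
blind-spot locations), superior arcuate, inferior and superior nasal wedges,
inferior altitudinal, mild global depression (−5 dB), severe global loss
(−32 dB), and a peripheral rim defect; each is the healthy baseline outside
its region mask and its depth inside it. Presentation mixtures draw from a
Dirichlet whose default concentrations favour the normal pattern with sparse
abnormal components, which yields near-pure defect fields and an MD
distribution spanning all four severity strata at n ≥ 200. Recovery is a
multiplicative drift: per 75-day interval a fixed fraction (default 0.35) of
the abnormal mixture mass moves to the normal pattern, so eyes with more
presentation normal mass remain better at every later visit — the planted
monotone AT1–MD coupling that the prognosis-split and correlation tests
detect. Negative rates model progression.

Three of the nine templates are constant fields and hence collinear, so the
full 9-pattern library is deliberately *not* identifiable by archetypal
analysis; it exists to exercise the clinical statistics on realistic
severity mixes. Parameter-recovery benchmarks use the 5-pattern subset
(normal, enlarged blind spot, superior arcuate, inferior nasal wedge,
inferior altitudinal), which is affinely independent and well separated:
with Dirichlet(0.3) mixing, 1 dB noise and 240–480 fields, fits at the
planted order recover the templates at cosine similarity > 0.95 and percent
weights within 5 points MAE (asserted in the acceptance tests).

What the generator does not emulate — and what passing tests therefore do
not demonstrate about real perimetry: eccentricity-dependent and
floor-censored test-retest noise (real variability grows in damaged
regions), learning and fatigue effects, lens-rim artefacts, the device's
weighted MD, irregular real-world visit schedules, and defect geometries
outside the nine templates. Results on clinic data should be validated
against the deposited tables the pipeline was designed to read.

## Numerical choices and degenerate inputs

* TD values are validated to [−40, +15] dB; the generator clips noisy values
  into that range.
* Fitting requires `n ≥ k` distinct fields (with `n = k` each field becomes
  its own archetype) and rejects an all-zero matrix.
* Dominant-archetype ties break toward the lower index (higher RW).
* Rows whose TD cells are non-numeric or out of range are rejected
  individually at parse time with row-level diagnostics, never silently
  dropped; CSV values are written with `repr` precision so a write/read
  cycle is bit-exact.
* A degenerate prognosis split (all eyes on one side of the mean) and a
  constant-input correlation raise errors naming the problem.
* Problem sizes in the test suite and acceptance script (240–800 fields, CV
  over k = 2–8, 1–3 restarts) are the package's own choices to keep the
  checks fast while leaving the measured properties comfortably inside
  their tolerances; the estimator defaults (k up to 20, 5 restarts, 100
  iterations) are what a production fit should use.

## Known limitations

* Archetype solutions are local optima; published relative weights for a
  given dataset can vary across seeds by a few percent points even at the
  same model order. Restarts mitigate but do not eliminate this.
* Fitting `k` far above the data's effective rank splits high-mass vertices
  (e.g. the normal pattern) across near-duplicate archetypes and dilutes
  their RW; choose the order from the cross-validated curve.
* No multiple-testing correction is applied to the cohort statistics, and
  eye-level analyses ignore inter-eye correlation (see above).
* Weighted or robust archetypal-analysis variants, temporal smoothing of PW
  trajectories, and information-criterion model selection are out of scope.
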