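# vfarch

Archetypal analysis of longitudinal 24-2 visual fields in idiopathic
intracranial hypertension (IIH).

IIH raises intracranial pressure, swells the optic disc (papilledema) and
damages the visual field. Clinicians usually track a single global index —
the mean deviation (MD, dB) — which hides *where* the field is damaged and
misses regional deficits that persist after MD has returned to normal.
`vfarch` is for neuro-ophthalmology researchers who want a quantitative,
pattern-level description of field loss and recovery from ordinary clinic
perimetry exports.

## The model

Stack the 52 total-deviation values of each field (the 54-point 24-2 grid
minus the two blind-spot points) into a matrix `X`. Archetypal analysis
finds the convex factorisation

    X ≈ A Z,  Z = B X,  rows of A and B on the probability simplex,

so each archetype (AT, a row of `Z`) is an extreme but realisable pattern of
loss, and each field is a convex mixture of archetypes. A field's
coefficients × 100 are its percent weights (PW, summing to 100); an
archetype's mean PW over a dataset is its relative weight (RW), and AT1 —
the archetype with the highest average TD — is the normal pattern. The fit
alternates exact simplex-constrained least-squares updates (monotone in RSS)
over several random restarts; the number of archetypes is chosen from a
patient-grouped ten-fold cross-validated RSS curve. A PW ≥ 9% counts as
clinically meaningful; a final-visit field with MD ≥ −2 dB that still
carries a meaningful abnormal archetype is a *residual deficit*. Because
clinic datasets are rarely redistributable, the package ships a synthetic
longitudinal cohort generator with planted archetypal structure, so every
stage can be validated against known ground truth.

## Worked example

```python
import numpy as np
from vfarch import (ArchetypalAnalysis, decompose_records, relative_weights,
                    pw_md_correlation, recovery_benchmark_spec, simulate_cohort)

records, truth = simulate_cohort(recovery_benchmark_spec(n_patients=40, seed=1))
X = np.stack([r.td for r in records])

est = ArchetypalAnalysis(n_archetypes=5, n_restarts=3, random_state=1).fit(X)
decs = decompose_records(records, est)
rw = relative_weights(decs)
print("AT1 RW %.1f%%, average TD %.1f dB" %
      (rw[est.normal_index_], est.average_td_[est.normal_index_]))

pres = [(r, d) for r, d in zip(records, decs) if r.visit_type == "presentation"]
rho, p = pw_md_correlation(np.array([d.pw[est.normal_index_] for _, d in pres]),
                           np.array([r.md for r, _ in pres]))
print("presentation AT1 PW vs MD: Spearman rho %.2f (p=%.2g)" % (rho, p))
```

prints

```
AT1 RW 45.7%, average TD 2.2 dB
presentation AT1 PW vs MD: Spearman rho 0.46 (p=1.9e-05)
```

Reading: the fitted normal pattern carries 45.7% of the cohort's mixture
mass against a planted share of 48.1%, and its average TD (2.2 dB) sits at
the healthy baseline (+2.4 dB planted). The AT1-PW/MD correlation is
positive but moderate in this benchmark because its five planted defects
differ widely in how much MD they cost; on cohorts dominated by global
depression components (the generator's 9-pattern default) the same statistic
runs above 0.7, the regime seen in clinic data. The same pipeline runs on
real tables via
`read_vf_table` (CSV/XLSX, 52 TD columns plus MD) and from the shell:

```bash
vfarch simulate --n-patients 40 --patterns five --seed 1 --out cohort.csv
vfarch fit --input cohort.csv --k 5 --seed 1 --out model.json
vfarch select-k --input cohort.csv --k-min 2 --k-max 8 --out-csv curve.csv
vfarch decompose --model model.json --input cohort.csv --out decomp.csv
vfarch report --model model.json --input cohort.csv --out-dir report/
vfarch render --model model.json --out-dir figs/
```

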