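# cupfa

Functional anteversion of the acetabular cup under sagittal pelvic motion:
a geometric model, its cubic response-surface surrogate, a pooled population
pelvic-tilt reference, and a rule-based planner that recommends a
patient-specific intra-operative cup anteversion for total hip arthroplasty
(THA).

## The problem

Cup malposition is a leading cause of instability after THA, but the static
"safe zone" ignores that the pelvis rotates in the sagittal plane between
standing and sitting while the implanted cup stays fixed in the acetabulum.
The cup's *functional anteversion* (FA) — the transverse-plane anteversion it
actually presents in a given posture — therefore differs from the planned
anteversion by an amount that depends on planned inclination *I*, planned
anteversion *A*, and sagittal pelvic tilt *PT* (positive = posterior tilt, as
in sitting). Patients with stiff or abnormally oriented pelves can have
adequate cup position on the table yet deficient sitting FA (posterior
instability risk) or excessive standing FA (anterior impingement risk).

This package is aimed at surgeons and biomechanics researchers doing
pre-operative planning from standing and sitting lateral radiographs.

## The model

The cup is represented by the unit normal to its face in a global frame
(x lateral, y anterior, z superior), starting from the neutral pose
(anterior pelvic plane parallel to the coronal plane, normal pointing
inferiorly). Planned position and posture are applied as successive
rotations — inclination in the coronal plane, anteversion about the vertical
axis, pelvic tilt about the lateral axis — and the result is projected onto
the axial plane:

    FA(I, A, PT) = atan2( sin I · sin A · cos PT + cos I · sin PT ,  sin I · cos A )

Around this core the package provides:

* **`cupfa.geometry`** — the exact model: `functional_anteversion`,
  `delta_fa`, `profile_fa` (standing/sitting/change triple for one patient).
* **`cupfa.surrogate`** — `CubicDeltaFA`, a scikit-learn-style regressor for
  the complete 20-term cubic in (I, A, PT); `generate_grid` evaluates ΔFA on
  the 1° iteration grid (I 30–60°, A 15–25°, PT 0–30°), and
  `CubicDeltaFA.published()` ships the canonical published coefficient set.
* **`cupfa.population`** — subject-count-weighted pooling of published
  standing/sitting/change pelvic-tilt means (packaged six-study table,
  n = 378: 0.3° / 25.8° / 25.4°).
* **`cupfa.planner`** — classifies the patient's FA triple against the
  population triple (default ±5° band) and matches one of eight clinical
  scenarios, returning a quantitative adjustment to intra-operative
  anteversion or an articulation-options flag for very stiff pelves.
* **`cupfa.fixtures`** — synthetic patient profiles (correlated bivariate
  normal on standing/sitting tilt) and scenario-covering fixture search.

## Worked example

```python
from cupfa import (CupPlan, PelvicTilt, SpinopelvicProfile,
                   functional_anteversion, default_reference, recommend)

# a cup planned at 40 deg inclination / 20 deg anteversion, pelvis tilted
# posteriorly by 15 deg:
fa = functional_anteversion(CupPlan(40, 20), PelvicTilt(15))
print(round(fa, 1))            # 34.2  -> the cup "gains" 14.2 deg of anteversion

# a stiff-pelvis patient: standing tilt 10 deg, barely moves when sitting
rec = recommend(CupPlan(40, 20),
                SpinopelvicProfile.from_degrees(10, 12),
                default_reference())
print(rec.scenario_id)         # 7
print(rec.articulation_flag)   # True  -> consider dual mobility / constrained liner
print(rec.adjusted_anteversion_deg)  # 20.0 (no cup adjustment; unpredictable effect)
```

The same numbers from the command line:

```sh
cupfa fa -i 40 -a 20 -t 15          # {"functional_anteversion_deg": 34.2, ...}
cupfa reference                      # pooled population tilts 0.3 / 25.8 / 25.4
cupfa plan -i 40 -a 20 --standing 10 --sitting 12
cupfa fit --out surrogate.json       # cubic fit on the 1-degree grid, R^2 >= 0.999
cupfa surface --out surface.csv -a 20
```

A 34.2° sitting FA against a planned 20° illustrates why a fixed
intra-operative target cannot serve every spine–hip relationship: the
planner quantifies, per patient, how far their standing/sitting FA triple
sits from the population's and converts the concerning discrepancy into a
new anteversion target.

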