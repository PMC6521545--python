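# Methods

## Geometric model

The acetabular cup is modelled by the unit vector normal to its face in a
global, room-fixed frame: x lateral, y anterior, z superior. In the neutral
pose the anterior pelvic plane is parallel to the coronal plane and the cup
normal points inferiorly, (0, 0, −1). Three rotations are composed in order:

1. planned inclination I — rotation in the coronal (x–z) plane, swinging the
   opening laterally: R_y(−I);
2. planned anteversion A — rotation about the vertical axis, swinging the
   opening anteriorly: R_z(A);
3. sagittal pelvic tilt PT — rotation about the lateral axis, R_x(PT), with
   positive tilt posterior (the pelvis rolls backwards into sitting).

The tilted normal is projected onto the axial plane and the functional
anteversion (FA) is the signed angle of the anterior over the lateral
component:

    FA(I, A, PT) = atan2( sin I sin A cos PT + cos I sin PT , sin I cos A ).

ΔFA = FA − A is the anteversion the posture adds to the plan. At PT = 0 the
projection recovers the planned anteversion exactly, and FA is strictly
increasing in PT throughout the planning domain.

**Axis and sign conventions.** The rotation order and plane assignments admit
several natural readings; the one above is the unique natural convention that
reproduces the two standard worked values of the model (FA = 34.2° at
I = 40°, A = 20°, PT = 15°; FA = 27.5° at I = 35°, A = 20°, PT = 6°). The
implementation computes FA twice — through the explicit vector pipeline and
through the closed form — and the tests additionally check both against an
independently written 3×3 rotation-matrix oracle at 10⁻⁹ degrees.

**Validity window and degeneracies.** Inclination is hard-limited to the open
interval (0°, 90°): at either bound the axial projection of the cup normal
loses its lateral component and the anteversion angle is undefined. Default
validation windows are I ∈ [10°, 80°], A ∈ [−10°, 50°], PT ∈ [−45°, 60°],
all overridable per call. Anterior (negative) tilt is accepted because pooled
population standing tilts are slightly anterior in several source cohorts.
A cup normal whose axial projection has non-positive lateral component raises
an explicit degenerate-orientation error rather than returning a wrapped
angle. All public angles are degrees; radians exist only inside trig calls.

## Cubic response surface

`generate_grid` evaluates geometric ΔFA on an inclusive 1° Cartesian grid,
I 30–60°, A 15–25°, PT 0–30° (31 × 11 × 31 = 10,571 points; the grid spec is
configurable). `CubicDeltaFA` fits the complete third-degree polynomial in
(I, A, PT) — 20 monomials including the constant — by ordinary least squares.
Design columns are standardised before the solve for conditioning and the
shift is folded back into the constant term, so reported coefficients are in
raw units. Monomials are ordered by total degree descending then
lexicographic exponent triple, making serialised coefficient files stable;
JSON round-trips are bit-exact.

On the default grid the fit attains R² ≈ 0.9999 and a mean absolute residual
of ≈ 0.055°, with a maximum residual below 0.5° — the cubic is a presentation
convenience, not the engine: the planner always uses the exact closed form,
and the published coefficient set is retained for parity with the deployed
planning tool and as a cross-check. Its residual at PT = 0 (where the true
ΔFA is exactly zero) is about −0.13°, a useful regression value for the
serialisation and evaluation path.

Rank deficiency (e.g. a variable held constant on the grid) raises a
singularity error naming the collapsed variable. Polynomial degree is
exposed as a parameter; degree 3 is the shipped default because higher
orders buy no accuracy worth the extra terms on this domain.

## Population reference

The planner's baseline is a subject-count-weighted pooling of published
cohort means of standing and sitting pelvic tilt. The packaged table holds
six cohorts (n = 378); its pooled means are standing 0.3°, sitting 25.8°,
change 25.4°. The change column is pooled from each study's *reported*
change mean, not recomputed as the difference of pooled poses: studies
report the change independently and the two readings differ in general.
Means — not extremes or SD-trimmed subsets — define the reference: the
source cohorts are cross-sectional and their extremes likely over-represent
pathologic pelvic mechanics, and SDs are hard to compare across studies with
different radiographic technique. Per-study SDs are carried through the IO
layer (``NR`` marks a study that did not report one) but never affect the
reference; they parameterise the synthetic sampler only.

## Planner

For a given cup plan, the patient's FA triple (standing, sitting, change =
sitting − standing) and the population's FA triple at the same plan are
computed from the exact model. Each quantity is labelled *greater* /
*appropriate* / *less* within a tolerance band (default ±5° on each
quantity, boundary classified inward; the band is configurable — nothing in
the source material quantifies "greater/less than average", and 5° mirrors
the granularity of the classical safe-zone discussion while keeping the
no-change scenario reachable). The label triple is looked up in the
eight-row clinical scenario table; the 19 unlisted combinations return
"unhandled" with a manual-review narrative rather than a guessed adjustment.

Adjustments are the raw FA discrepancy of the concerning quantity:
decrease by the standing excess (row 1), increase by the sitting deficit
(row 3), by the larger of the sitting and change deficits (row 4), or by the
change deficit (row 5); rows 2, 7 and 8 leave the plan unchanged, row 7
additionally flagging alternative articulations (dual mobility, constrained
liner, large heads). Adjusted anteversion outside the validation window is
clamped, with a warning recorded in the narrative.

**Constrained decrease (row 6).** The standing-excess decrease stops before
the patient's sitting FA would fall below the population sitting FA. The
population value is held at the *originally planned* anteversion: it is the
fixed clinical target of the stopping rule. Recomputing it at each candidate
anteversion would move both sides of the comparison in lockstep — FA is
strictly monotone in tilt at fixed cup position, so the sign of the gap
would never change and the rule would be vacuous (always or never binding).
The scan runs in 0.1° steps from zero, returning the last non-violating
decrease; a bisection oracle confirms the scan in the tests.

**Exact mode.** FA is mildly nonlinear in A, so the raw-discrepancy
correction under- or over-shoots slightly. An optional mode (off by default)
root-solves for the anteversion at which the concerning patient FA equals
the population FA target at the planned position (Brent's method on the
validation window), falling back to the raw discrepancy when the target is
unreachable within the window.

**A structural fact about the label space.** Because change ≡ sitting −
standing for patient and population alike, the change discrepancy is
identically the sitting minus the standing discrepancy. Row 2 (*greater,
less, appropriate*) needs a change tolerance larger than the sum of the pose
tolerances; row 5 (*appropriate, appropriate, less*) needs one smaller.
No tolerance band therefore realises both, and row 2 — clinically described
as an unlikely combination — is the vacuous one: no spinopelvic profile can
reach it, under any band. The row is kept in the table (its pattern matches
correctly if presented directly) and the fixture constructor fails loudly
when asked to realise it.

## Synthetic profiles

`sample_profiles` draws (standing, sitting) tilt pairs from a correlated
bivariate normal — the simplest joint model matching the reported per-pose
means and SDs. Defaults: standing 0.3° ± 7.9°, sitting 25.8° ± 10.4°
(pooled from the packaged table, using the studies that report SDs),
correlation 0.4. No source cohort reports the standing–sitting correlation;
0.4 encodes the expectation that posturally stiff or mobile pelves are so in
both poses, and is configurable. The sampler emulates marginal location and
scale of real cohorts; it does not model skew, truncation at anatomical
limits, measurement error of radiographic landmarking, or the spine
parameters (sacral slope, lumbar lordosis) that correlate with tilt — so
passing distributional tests says nothing about those features of real data.
Sampling is deterministic under a seed; moment-recovery tests run at
n = 10,000 with 3-standard-error tolerances.

`scenario_fixtures` inverts the classifier by scanning tilt offsets (±30°
at 1°) around the reference pose and keeping the first profile mapping to
each scenario id; with the default band the seven non-vacuous rows are found
and round-trip through the planner.

## Numerical choices

* FA agreement between vector pipeline, closed form and matrix oracle:
  10⁻⁹ °; unit-norm preservation: 10⁻¹²; non-unit input to the tilt rotation
  is rejected beyond 10⁻⁹.
* Least squares via `numpy.linalg.lstsq` on standardised columns; the refit
  is deterministic and recovers the published coefficients from noise-free
  samples to ~10⁻¹² relative.
* Scenario search and constrained decrease use fixed grids/steps (1° and
  0.1°), so all planner outputs are deterministic; reports round to one
  decimal, with rounding of adjustments to surgical increments left to the
  caller.
* Problem sizes in the tests — the full 10,571-point grid, 1,000-point
  oracle sweeps, 10,000-draw sampler checks — run in a few seconds total.

## Limitations

* The geometric model treats the pelvis as a rigid body with purely sagittal
  rotation between poses; coronal/axial pelvic motion, femoral kinematics and
  combined (cup + stem) anteversion are out of scope.
* The population reference is a weighted mean of heterogeneous cohorts
  measured with differing radiographic technique; it carries no uncertainty.
* The planner proposes a target; it says nothing about how to achieve it
  intra-operatively, and its tolerance band is a design parameter, not a
  clinically validated threshold.
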