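# Methods

This note documents the models, parameter choices and numerical decisions
behind `avflow`, in the order the pipeline runs them: synthetic geometry,
pulsatile wall shear, anatomical characterisation, WSS metrics, and the
cohort statistics.

## Units and conventions

Coordinates and diameters are in mm, curvature in mm⁻¹, angles in degrees,
wall shear in Pa, volumetric flow in ml/min at every user-facing interface
(SI internally).  Arclength `s` along each limb starts at the
anastomosis-patch boundary and increases away from the junction.  The
packaged cohort table stores its curvature column verbatim as published;
the printed magnitudes (0.013–0.075) are dimensionally consistent with
mm⁻¹ for arm vessels (radii of curvature 13–77 mm), and the synthetic
generator treats them as mm⁻¹; the fixture values themselves are never
rescaled.

## Synthetic end-to-side AVF lumens

Each limb (feeding artery, distal artery, draining vein) follows a planar
centreline composed of a straight juxta-anastomotic run into the junction
followed by a constant-curvature arc.  The straight run models the
mobilised, sutured vessel ends; its length adapts to the junction
geometry — roughly the arclength over which the vein and artery surfaces
remain merged, `(r_vein + r_artery)/sin θ`, plus one vein diameter of
anastomosis patch plus the 5 mm angle-fit window with margin — so that the
anastomosis angle stays well defined for curved vessels and the angle
estimator always sees straight centreline.  A consequence worth noting for
round-trip comparisons: the windowed mean curvature of a limb is the arc
curvature diluted by the straight fraction inside the window, and the
package's tests compare recovered values against that windowed truth, not
against the raw arc curvature.

The single watertight surface is produced by sampling the signed-distance
union `min_limb(dist(x, centreline_limb) − r_limb)` on a regular grid of
spacing `mesh_edge_target` (default 0.5 mm; reduce towards `D/8` for
vessels under ~3.5 mm) and triangulating the zero level set with marching
cubes.  This replaces a CSG boolean union: it is watertight and
outward-orientable by construction, has no sliver intersections to
remesh, and its geometric error is O(h²/8r) ≈ 0.02 mm at default
resolution — well inside the 2% diameter tolerance the round trip
demands.  Swept tubes (`build_tube`) are instead meshed directly from
parallel-transport frames with flat end caps, and reject sweeps with
`κ·r ⩾ 1` (self-intersection).

Face labels: each face goes to its nearest limb; the anastomosis patch is
every face within one vein diameter of the junction seam, where the seam
is recovered from the grid as the set of points lying on two limb surfaces
at once.  Distance to the seam, not to the junction point, matters: at
shallow anastomosis angles the merged region extends far along both
vessels.

Designs are validated against: positive diameters, angle ∈ (0, 180)°,
κ ⩾ 0, κ·L < π per limb (no self-intersecting arc), limb lengths ⩾ 20 mm
and exceeding the straight run, and a junction impossibility rule (vein
diameter above twice the feeding-artery diameter, the widest opening an
end-to-side suture line can span).  Veins wider than the artery — the
common case — are accepted.

## Pulsatile wall shear (rigid tube)

Blood is Newtonian with μ = 3.5 mPa·s and ρ = 1050 kg/m³ (configurable);
the default cardiac period is 1.0 s.  A flow waveform is a steady
component plus complex harmonics; the physiologic preset uses two
harmonics (first at `pulsatility`·Q₀ with −90° phase, second at 40% of
that) which keeps Q(t) > 0 and gives the skewed systolic peak of arterial
flow.  For each harmonic n with Womersley number α = R√(nΩρ/μ), the
axisymmetric rigid-tube solution gives the wall shear per unit flow
amplitude through Bessel functions of complex argument; the
pressure-gradient amplitude is eliminated in favour of the harmonic's
flow, so the series reproduces the prescribed waveform exactly.  The
steady term is τ₀ = 4μQ₀/(πR³) and the α→0 limit of every harmonic factor
is the same quasi-steady value (verified to 1%).  If the Bessel evaluation
ever returns non-finite values (extreme α), the implementation falls back
to a spectral-in-time finite-difference solve of the radial momentum
equation and warns.  An independent time-stepping finite-difference oracle
(≥ 200 radial nodes, ≥ 20 periods from rest, implicit Euler) agrees with
the analytic wall shear to better than 0.2% and is exercised in the test
suite and the acceptance script.

Rigid walls are assumed throughout, as is common for mature venous
segments; no turbulence or secondary-flow structure exists in these
analytic fields, so oscillatory and transverse metrics on synthetic data
reflect only the waveform, not junction-induced disturbance.  This is the
main respect in which passing tests say nothing about real post-junction
flow; the metric definitions themselves are exercised against closed-form
fields instead.

## Anatomical characterisation

*Centrelines* are extracted by cross-section marching: cut the mesh with
the plane normal to the current direction, take the area centroid of the
closed intersection polygon containing the current point, relax the
direction (factor 0.7) and step 1 mm.  A second pass re-cuts every station
with tangents estimated from the first pass, which removes the tilt of the
chord-based start-up planes; accuracy on analytic tubes is ~10⁻³ mm
(cylinder) and < 0.01 mm (arc).  The march stops at an open section (end
cap), a 2× area jump (junction), or when the centroid comes within the
local radius plus a margin of the anastomosis patch.

*Diameters* are equivalent-circle values D = 2√(A/π) from the section
area — chosen over maximum-inscribed-sphere because it is what a
cross-sectional area measurement yields and is robust to non-circular
sections; the cut plane is normal to the local tangent with no further
obliquity correction.  Stations whose section touches the anastomosis
patch, or whose cut is open, are missing and excluded from means.

*Curvature* uses local quadratic regression in arclength: coordinates are
pre-smoothed with a boxcar whose half-width (`window/4`) shrinks near the
ends so the average stays symmetric (a one-sided average displaces
endpoints toward the concave side and invents curvature), then each point
gets a quadratic fit over ±`window/2` (default window 10 mm) whose
derivatives give κ = |r′×r″|/|r′|³.  The estimator is exactly invariant
under rigid motions and recovers 1/R on arcs to < 1% away from the
endpoints; with 0.1 mm point noise the windowed mean stays within 10%.

*Angle*: straight lines are fitted (principal component) to the first
5 mm of the feeding-artery centreline (directed downstream, into the
junction) and of the vein centreline (directed away); the angle between
them is reported in (0, 180)°, larger meaning a more obtuse junction.

*Segmentation*: each limb is binned into consecutive 10 mm arclength
segments from the patch boundary outward; faces join the bin of their
nearest centreline station; a trailing bin shorter than 10 mm is kept and
flagged partial; the anastomosis patch is one separate segment, so the
segments partition the surface exactly.

*Summaries*: diameters and curvatures are sampled every 1 mm and averaged
over 0–100 mm (feeding artery, draining vein) and 0–50 mm (distal
artery), truncated to the available limb length.

## WSS metrics

All time integrals are trapezoidal with periodic closure (the last sample
wraps to the first); series with a coverage gap exceeding T/4 are
rejected.  Per face: TAWSS = (1/T)∫‖τ_w‖dt; OSI = ½(1 − ‖∫τ_w dt‖ /
∫‖τ_w‖dt), clipped into [0, 0.5]; transWSS = (1/T)∫|τ_w·(n×p)|dt with p
the unit mean-shear direction.  Faces with no mean direction (pure
oscillation) have transWSS *missing*, not zero — "no transverse shear"
and "undefined transverse direction" must not be conflated — with the
count logged.  WSSG is the magnitude of the intrinsic surface gradient of
the TAWSS scalar, fitted per face from its edge-connected neighbours by
least squares in the tangent plane (exact for linear fields; the
alternative time-average-of-instantaneous-gradient definition was
considered and can be built from the same primitive).  LNH is the cosine
of the velocity–vorticity angle on volumetric snapshots, taken at peak
systole, which is operationally defined as the argmax of the inlet
waveform (ties to the earliest sample).  Segment aggregation uses
area-weighted means (face-count weighting would bias towards finely
meshed regions), excludes missing faces, and reports the anastomosis
segment separately.

## Lumped pressure network

A three-node Poiseuille network (resistances 8μL/πR⁴): inlet → anastomosis
node through the feeding artery; anastomosis → venous outlet (pressure
reference 0) through a suture-line constriction — one vein diameter long
at half the vein radius, scaled by `anastomosis_resistance_scale` — in
series with the vein; distal artery from the anastomosis node to a bed at
`distal_pressure` (the pressure collaterals maintain in the distal arm,
default 0 = unperfused dead end).  Forward flow reproduces
P_feeding > P_anastomosis > P_vein-inlet > P_outlet.  Shrinking the
constriction scale (a very large anastomotic area) lowers the anastomotic
pressure; once it falls below the collateral-maintained distal pressure
the distal artery back-feeds the fistula and the steal flag is raised.
Distal flow reversal is impossible without a collateral source, which is
why the flag requires a positive `distal_pressure` to ever fire.

## Cohort statistics

The packaged 17-fistula table ships verbatim with a SHA-256 integrity
check.  Group summaries use the population SD (divisor n), which is the
convention the published summary values of this table follow (divisor
n−1 gives 1.51 and 21.7 where 1.45 and 20.9 are expected).  The high-flow
dichotomy is inclusive: outflow ⩾ 1000 ml/min.  ROC AUC is the
Mann–Whitney concordance with ties counted ½, computed by exhaustive pair
counting and cross-checked against the trapezoidal area under the
empirical ROC curve (and, in tests, against an independent library
implementation).  On the packaged table the feeding-artery-curvature AUC
under this standard tie rule is 0.8125; conventions that break the single
tied pair concordantly give 0.8194 — both are reported in the
documentation, the standard rule is used.  Orientation is chosen so
reported single-variable AUCs are ⩾ 0.5, with the sign recorded.  The
combined score is the linear predictor of an unpenalised logistic
regression on z-scored variables evaluated in-sample (an L2-penalised fit
is substituted, and flagged, under separation); in-sample it can only
improve on its best component, which is the property the tests assert.
Group comparisons default to the exact-tie-corrected rank-sum test (small
n, no normality assumption), with Welch's t available; p-values are
descriptive output, never acceptance quantities.

The cohort generator draws each anatomical variable per outflow group
from truncated normals (rejection sampling, 100 attempts) whose default
locations and scales are the packaged cohort's High/Low-group values, and
assigns outflow from group-conditional truncated normals on either side
of 1000 ml/min, so the category column restates the dichotomy rule.  One
integer seeds the whole table.  What it emulates: marginal group
differences and their detectability (AUC ≈ Φ(δ/√2) for a standardised
shift δ, recovered within 0.02 at n = 2000/group).  What it does not:
inter-variable correlations, measurement error structure, or any causal
link between anatomy and flow — conclusions about those do not follow
from passing tests.

## Problem sizes

Default meshes run at 0.5 mm edge target (≈ 50k faces per fistula), field
series at 64 time samples, the geometry round-trip suite at 12 designs
spanning the packaged cohort's ranges, and generator recovery at
2000/group — sizes at which every documented tolerance is met with
margin on a single CPU in minutes.

## Known limitations

No image segmentation, no 3-D Navier–Stokes or turbulence modelling, no
compliant walls, no skin surface (so no vessel-depth criterion).
Synthetic wall-shear fields are axially aligned and harmonic-driven;
junction-induced secondary flow, helicity and oscillation are not
emulated, only their metrics defined and verified on closed forms.  The
anastomosis patch extent (one vein diameter around the junction seam) is
a modelling choice; published sources rarely state theirs.
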