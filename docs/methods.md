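# Methods

This note documents the models behind `stereogaze`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions

All geometry lives in a right-handed screen coordinate system: origin at
the screen centre, +z toward the subject, +x to the subject's left, +y
down. Lengths are millimetres; angles returned to callers are degrees.
Gaze directions are described by Fick angles, horizontal first:
`h = atan2(d_x, −d_z)`, `v = atan2(d_y, hypot(d_x, d_z))`, so positive
angles are to the left and down. The Fick choice matters only through
off-axis cross-coupling, which is below 0.1° inside the rig's ±21° × ±10°
measurement range.

## The rig

The default `SceneGeometry` reproduces a desktop stereo tracker: two
cameras (16-mm lens, 2.4-µm pixels → 6667 px focal length; 1420 × 1420-px
tracking ROI of a 3088 × 2064 sensor) on a rail 150 mm below the bottom
edge of a 527 × 296-mm monitor and 40 mm in front of it, ±60 mm from the
vertical midline, aimed at the design eye position (0, 0, 650); two IR
sources 60 mm further out; 50-Hz sampling.

One deliberate deviation from a literal reading of that layout: the
LED-board centres sit 30 mm **below** the camera optical axes. If lights
and camera centres were exactly collinear, the two reflection planes that
each camera contributes to the corneal-centre reconstruction would
coincide (both would contain the entire rail line), and the reconstruction
would be geometrically degenerate. Any physical mounting of finite-size
boards breaks collinearity; the simulator makes the offset explicit and
configurable.

## The model eye

`ModelEye` is a schematic eye: a spherical corneal cap of radius
r = 7.72 mm whose best-fit centre `c` lies on the optical axis, a centre
of rotation (COR) 13.5 mm behind the corneal vertex (so
c = COR + (13.5 − r)·OA), a pupil in a plane 3.6 mm behind the vertex
(classic schematic-eye anterior-chamber value), an effective
corneal/aqueous refractive index of 1.3375 (keratometric convention), and
per-eye Fick offsets κ = (κ_h, κ_v) between optical and visual axis.
Realistic defaults: κ_h ≈ 5° with the optical axes deviating temporally
(negative for the left eye in this sign convention), κ_v ≈ 1.5°,
interocular distance 63 mm, pupil radius 2 mm.

**Glints.** The specular reflection of a point source on a sphere
(Alhazen's problem) is solved by a bracketed 1-D root solve on the
in-plane polar angle in the plane spanned by light, camera and `c` —
robust, with no quartic-root selection. Glints are physical only on the
corneal cap: the cap half-angle is 53° about the optical axis (anatomical
limbus ≈ 50° plus a small specular tear-film margin). With the rig
geometry this keeps all four glints alive over the full ±21° × ±10° target
grid (maximum apex angle ≈ 51.5°, consistent with the physical system
tracking that range) while a ~40° temporal eye rotation pushes a glint off
the cap and produces the NaN features seen in practice.

**The virtual pupil — two models.** What the cameras see is the pupil
refracted by the cornea. `pupil_model="refracted"` traces, per camera, the
exact finite-angle Snell solution (1-D in-plane root solve; residual
|n₁ sin θ₁ − n₂ sin θ₂| < 1e−9). This reveals a genuine aberration of
pupil/corneal-reflection trackers: the apparent pupil centre is displaced
slightly off the optical axis in a viewpoint-dependent way, which moves
the reconstructed optical axis by ~0.05–0.3° across the gaze range and
cannot be absorbed by a single-point κ. The reconstruction — like the
method it implements — assumes instead a single entrance-pupil point fixed
on the optical axis. `pupil_model="rigid"` (the default) generates data
under exactly that assumption: the virtual pupil is one point on the
optical axis at the paraxial refracted depth of the pupil plane (3.05 mm
behind the vertex for the defaults, computed by marginal-ray tracing),
rotating rigidly with the eye. The rigid model is the regime the
validation targets (noiseless round trips are then exact to solver
tolerance); the refracted model quantifies the model error the real device
inherits.

**Aspheric perturbation.** Real corneas flatten peripherally. The optional
`asphericity` parameter scales the local corneal radius as
r·(1 + q·θ²_apex) (vertex held fixed) in the glint solve only; the
reconstruction keeps assuming a sphere. With q ≈ 0.15 the peripheral gaze
error visibly exceeds the central error, reproducing the qualitative
degradation beyond ±14° without modelling a full ellipsoidal cornea.

## Reconstruction

* `c`: intersection of the two (camera, light, glint-ray) planes per
  camera gives a ray through each camera toward `c`; the two rays are
  triangulated (midpoint of the common perpendicular; its length is kept
  as a quality gap). The corneal radius is never used.
* `p_v`: triangulation of the back-projected pupil rays; when a
  calibration supplies K = ‖c − p_v‖, the estimate is refined to the point
  at distance K from `c` minimizing the summed squared ray distance. The
  constrained problem is solved through its Lagrange system — p(λ) =
  (A − λI)⁻¹(b − λc) with a Newton iteration on the multiplier (the radial
  distance is monotone in λ below the smallest eigenvalue of A), falling
  back to bracketed bisection and, if the constraint is unreachable, to
  radial projection.
* κ calibration is two-pass: pass 1 estimates K as the median unconstrained
  ‖c − p_v‖ over the calibration frames; pass 2 re-derives the optical
  axes under the fixed-K constraint and takes κ as the per-axis median of
  (Fick angles of `s₀ − c`) − (Fick angles of the optical axis). Medians
  make both passes robust to occasional bad frames.
* Camera-2 features are linearly interpolated onto camera-1 timestamps
  (the rig's ~0.1-s timestamp asynchrony); NaN samples poison the
  timestamps they bracket rather than being interpolated across.

**Calibration epoch.** The default single-point calibration lasts 10 s
(500 frames). Noise propagation in this geometry is anisotropic: the
cameras sit ~26° below the line of sight, so triangulation *depth* errors
rotate the optical axis mostly vertically, at roughly 3° per frame for
0.3-px feature noise; a few hundred frames are needed before the medians
stabilize the vertical κ component and the K estimate (whose error couples
into κ_v at ≈ 5.5°/mm). Since calibration is the only subject-specific
step, a generous epoch is cheap. (For reference, the physical device's
effective feature noise is far below 0.3 px — per-sample gaze precision of
a few tenths of a degree implies sub-0.05-px centroiding — so 0.3 px is a
deliberately heavy test condition.)

**Vergence anchoring.** The visual axis is anchored at `c` (the nodal
point of a schematic eye lies within ~0.6 mm of `c`), and a fixating eye
points the `c`-anchored visual axis exactly at the target, so noiseless
gaze recovery is exact for any κ. A subtlety follows for vergence: the
measured vergence is the angle between the two visual axes, while the
target vergence is the cosine-law angle of the COR triangle. With κ = 0
the COR lies on the visual axis and the two agree identically; with
κ ≈ ±5° the corneal centres sit ~5.78·sin κ ≈ 0.5 mm off the COR–target
lines and the two definitions differ by up to ~0.1° (growing with vergence
demand) under perfect fixation. This is a property of the definitions, not
of the estimator — the physical system has the same offset, invisible at
its ~0.5–0.9° vergence accuracy. Exactness checks of the vergence chain
therefore use κ = 0 eyes; cohort simulations use realistic κ and absorb
the offset in the regression.

**Vergence response.** A simulated subject realizes vergence
`gain × demand + disparity` (default gain 1, disparity 0): the excess is
split equally between the eyes, and because the `c`-anchored aiming feeds
back on itself, the applied per-eye offset is iterated until the realized
excess is exact to 1e−12. A positive (eso) disparity of δ makes true
vergence exceed target vergence by exactly δ.

## Feature extraction

The image stage mirrors the tracker's pipeline on 200 × 200-px eye ROIs:
binarize below the pupil threshold → 8-connected components → area filter
→ largest candidate (ties broken toward the ROI centre) → least-squares
ellipse fit on the sub-pixel contour (centre and π·a·b as position and
area); if a pupil was found, binarize above the glint threshold, area
filter, drop candidates **above** the pupil image centre (with the lights
below the eyes, real glints cannot project there), keep the two nearest
the pupil, sort by x (glint 1 = lower x = light 1). Frames with no
surviving pupil or fewer than two glints yield NaN records — never dropped
rows. Optional global 8-bit histogram equalization precedes thresholding.
Thresholds and area bounds are operator-tuned quantities with no canonical
values; the defaults in `DetectionParams` suit the synthetic renderer's
contrast and must be re-tuned for real imagery.

The synthetic renderer paints a mid-gray background, a dark iris disk, a
darker pupil ellipse and Gaussian glint spots — enough structure to
exercise every branch of the detector (area filters, position filter,
ordering, equalization), but not eyelids, eyelashes, specular sclera
reflections or motion blur, which are the dominant failure modes on real
video. Passing the image-stage tests therefore validates the algorithmic
contract, not robustness to real-world artefacts.

## Mirror-based rig calibration

Lights and monitor are behind the cameras' line of sight, so they are
located via a planar mirror: the mirror pose is fitted (total least
squares) to its own triangulated surface dots; virtual images of the
lights and of a screen-mounted dot pattern are triangulated and reflected
into real space; the screen frame comes from a plane fit plus a rigid 2-D
(Kabsch) registration of the known dot layout. Intrinsic/extrinsic camera
calibration is consumed from the scene file, not computed. Calibration
shots are modelled on the full sensor — the 1420-px ROI is a tracking-time
crop, and the mirror targets would not fit inside its ~12° field of view.

## Analysis defaults

* Fixation window: [onset + 0.6 s, onset + duration − 0.5 s), half-open;
  at 50 Hz and 2-s trials, 45 samples. Windows with SD_x or SD_y > 2° are
  outliers; windows with < 10 valid samples are invalid.
* SD uses divisor n (population form, as the metric is defined), not
  n − 1; S2S uses divisor n − 1 over the n − 1 displacements.
* BCEA uses k = 1.14; for a bivariate normal the ellipse covers
  1 − e^(−k) ≈ 0.680 of samples (checked by Monte Carlo).
* The ±14° central/peripheral boundary is inclusive into "central".
* MAE is reported componentwise (x, y) and vectorially (r, the mean
  Euclidean error).
* Mixed models are Gaussian random-intercept fits (REML, via statsmodels
  MixedLM); the subject-intercept correction subtracts the fixed intercept
  plus each subject's conditional-mean deviation before recomputing the
  vergence MAE. No multiple-testing correction is applied. Degenerate
  inputs are handled explicitly (perfect fits return exact point estimates
  with undefined SEs; zero-variance paired differences return t = 0, p = 1
  or a flagged infinite t).

## Problem sizes used in validation

The automated checks run, per invocation: a 35-target noiseless grid round
trip at 1 frame per camera (exactness is frame-wise, so more frames add
nothing), 20 seeded 10-s calibration runs at 0.3-px noise, 100 random
windows against brute-force metric formulas plus a 10⁶-sample BCEA Monte
Carlo, and 5-subject cohorts with 1.2-s trials for the depth-series
regression and the 5-level pupil series. These sizes give stable medians
and standard errors while keeping a full run to a few minutes on one CPU.

## Known limitations

* The rigid entrance-pupil default sidesteps the refraction aberration it
  itself can simulate; real-device errors from that aberration (and from
  corneal asphericity) are available only as perturbation studies.
* Head pose is fixed; there is no head tracking or compensation.
* The fixation simulator has no microsaccades, drift or blinks — precision
  metrics on synthetic data reflect injected pixel noise only, so SD/S2S
  values are not predictions of human fixational stability.
* Saccade onsets are smooth interpolations used solely to exercise the
  0.6-s trim; no saccade dynamics are modelled (50 Hz would undersample
  them anyway).
* Depth-from-vergence assumes symmetric fixation on the perpendicular
  bisector of the interocular baseline; it is an interpretation aid, not a
  3-D vergence-point estimator.
* Fixation disparity is modelled as a constant per-subject offset; real
  disparity varies nonlinearly with vergence demand, which is exactly why
  the subject-intercept correction is only a first-order account.
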