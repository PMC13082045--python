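# Methods

This note documents the models, numerical choices and limitations behind
`exorun`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Musculoskeletal model

The skeleton is a planar rigid-body tree with the full 20-coordinate layout
of common 3-D gait models: a pelvis-ground joint with three rotational and
two translational coordinates, a 3-rotation lumbar joint, and one rotational
coordinate per hip, knee, ankle, metatarsophalangeal (MTP), shoulder and
elbow on each side. Out-of-plane coordinates (pelvis list/rotation, lumbar
bending/rotation) exist in the state layout but are locked to zero, so the
dynamics are effectively sagittal-plane while the documented 20-DOF count is
preserved. Sign conventions: x forward, y up; hip/shoulder/elbow flexion
positive, knee flexion negative, ankle/MTP dorsiflexion positive.

Segment masses, lengths and inertias follow standard anthropometric
regression values (gait2392-flavored, arms separated from the torso),
stored in one versioned config (`exorun/data/default_model.yaml`). The
generic model (1.80 m, 75.17 kg) scales linearly: lengths with the height
ratio, masses with the mass ratio, inertias with mass·length². Scaled to
the study anthropometry (1.78 m, 73 kg) the leg length (thigh + shank) is
0.92 m, which anchors the %-of-leg-length slack convention.

Dynamics are evaluated with a batched planar recursive Newton-Euler pass;
the implicit residual form `M(q)q̈ + bias − τ` feeds the collocation
transcription directly. The implementation is verified against free-fall,
static equilibrium, mass-matrix symmetry/positive-definiteness, and energy
conservation of a passive pendulum (drift < 1e-6 relative over 1 s).

Passive rotational spring-dampers at the lumbar and MTP joints stand in for
ligament/soft-tissue forces (defaults 10 N·m/rad + 1 N·m·s/rad lumbar,
25 N·m/rad + 0.4 N·m·s/rad MTP).

## Muscles

Eighteen Hill-type muscle-tendon units actuate the legs: iliopsoas, gluteus
maximus, rectus femoris, biarticular hamstrings, vasti, biceps femoris
short head, gastrocnemius, soleus, tibialis anterior per side. To represent
trained runners, maximum isometric forces are twice generic values and the
active force-length operating range is widened by 50% (the widening rescales
length deviation from the optimum by 1/1.5 — symmetric about the optimum;
an asymmetric extension of only the descending limb would be an alternative
reading, noted as an open choice).

Curves are C1-smooth closed forms chosen for differentiability: a Gaussian
active force-length curve, a log-sinh force-velocity curve (exactly 1
isometric, ≈0 at maximum shortening, saturating eccentric plateau),
exponential passive-fiber and tendon curves with smooth non-negativity
clamps. Muscle paths use constant moment arms per (muscle, coordinate)
pair from literature-scale values in `exorun/data/muscles.csv`; MTU length
is affine in the coordinates with reference length `l_slack + l_opt·cos α`
at the standing pose. Activation dynamics are first-order with smoothly
blended time constants (0.015 s activation / 0.060 s deactivation).

Inside the optimizer all tendons are rigid: with a pure-scipy NLP the two
extra implicit states per compliant muscle cost more than they buy at the
mesh sizes used here. Compliant-tendon fiber equilibrium is implemented and
tested (`mtu_equilibrium_residual`) for analysis use.

The metabolic model is a smoothed Bhargava-2004-style sum of
activation/maintenance heat (mass · (40 f_slow + 133 f_fast) · a W),
shortening heat (0.25 · F · |v| when shortening, smoothly gated), positive
mechanical work, and an optional basal term, with a soft non-negativity
clamp. Muscle masses derive from F_max via a 0.6 MPa specific tension.
Coefficients live in `muscles.METABOLIC_COEFFS` and are swappable. Reported
costs are muscle-only (no whole-body basal) by default; a basal rate can be
added via `OcpConfig.basal_rate_w_kg`, and percent changes are insensitive
to that choice only when it is left at zero — which is why zero is the
default for the design-sweep tables.

## Contact and exotendon

Foot-ground contact uses four smoothed Hunt-Crossley spheres per foot
(heel, forefoot, two at the MTP joint; radius 0.035 m, stiffness 10 MPa,
dissipation 1.0 s/m, friction μs = μd = 0.8, viscous 0.5, transition
velocity 0.2 m/s). The normal force is Hertzian (`(4/3)E√r d^{3/2}`) with
Hunt-Crossley velocity dependence, made differentiable across lift-off by a
smooth-max penetration blend (width 1e-4 m) and a tanh gate; friction is
`N·(μd·tanh(v/v_t) + μv·v)`. The exact Hertz constant and smoothing widths
are package choices — parameter values map into the force law through this
documented closed form.

The exotendon is a linear extension spring between calcaneal anchor points:
`tension = k·max(0, d − l)` on the 3-D anchor distance, where a constant
0.25 m mediolateral offset between the feet stands in for the missing
mediolateral degree of freedom. The optimizer uses a softplus-smoothed
variant (width 1e-3 m; max error < k·width/2); all analysis paths use the
exact piecewise law. Slack lengths are specified in % of leg length
(converted at 0.92 m).

## Tracking optimization

The half-gait-cycle tracking problem minimizes the weighted integral of
squared kinematic tracking error, squared GRF tracking error (normalized by
body weight), squared activations and squared per-muscle metabolic rates
(weights 1e-6, 14, 8.0, 4e-5). Two deliberate interpretations: tracking
differences are squared (required for a meaningful least-squares minimum),
and GRF errors are expressed in body-weight units (the weight's units were
otherwise ambiguous). A small regularization (1e-3 on normalized torque)
keeps the five ideal upper-body torque actuators well-posed; it is reported
as its own term in the objective breakdown.

Transcription is trapezoidal direct collocation in implicit-dynamics form:
states are coordinates, speeds, accelerations and activations; controls are
excitations and torques; constraints are the Newton-Euler residual at every
node, trapezoidal defects, activation-rate defects, exact linear half-cycle
symmetry (left-right involution on coordinates, speeds and activations) and
a linear average-speed constraint on pelvis translation. Hermite-Simpson
transcription was considered and rejected: it roughly doubles the
constraint dimension for little accuracy gain at the coarse meshes that are
practical with a scipy-based solver.

The NLP is solved with `scipy.optimize.minimize(method="trust-constr")` in
two stages: a tracking-dominant warm start (kinematic weight boosted 1e4,
effort weights scaled by 0.1, 150 iterations) settles every condition into
the reference-gait basin, then the true weights run from that iterate. The
effort-dominated objective is multi-modal, and without the warm start the
natural and assisted conditions can land in unrelated local minima, which
corrupts percent-change comparisons.
Constraint Jacobians and objective gradients are exact to machine precision
via complex-step differentiation with a two-color node scheme (variables at
even/odd nodes per slot perturbed simultaneously; one batched complex
evaluation yields the entire sparse Jacobian). Convergence is declared on
feasibility (scaled constraint violation < 1e-3); solutions report the
violation and solver message verbatim. Everything is deterministic for a
given config and seed.

Default problem sizes: 8 mesh intervals per half cycle in the tests and the
acceptance script (801 decision variables), a deliberate desk-scale choice;
`OcpConfig.mesh_intervals` raises it. At this mesh the solver reaches
feasibility ≈1e-12 in a few hundred iterations (minutes per solve on one
CPU).

### What the coarse mesh does and does not show

With the synthetic reference gait at 4 m/s and 0.70 s stride, the natural
solve lands near 19 W/kg average muscle metabolic rate — the right order of
magnitude for running at this speed. Exotendon conditions reduce the
predicted cost, but the magnitudes at 8 mesh intervals are several times
larger than finer-scale predictions (tens of percent where ≈−10% is the
reference-scale figure). Two causes: the coarse mesh under-resolves the
stance-phase GRF transient and so under-charges the muscles for it, and
even with the warm start the local minimum reached under assistance is not
guaranteed comparable to the natural one (a zero-stiffness device, which
leaves the dynamics bit-identical to natural, reproduces the natural cost
exactly, confirming the spring coupling itself is clean). These runs
validate mechanism, convergence and the sign of the effect, not effect-size
calibration.

## Design sweep

`run_sweep` solves every grid design at each stride-duration multiplier
(0.90, 0.95, 1.00, 1.05 by default) and keeps the minimum-cost converged
stride per design; failed designs leave explicit holes in the output table.
Gait-cycle zero for tension profiles is the first upcrossing of right
vertical GRF through 5% body weight (heel strike); profiles are resampled
to 101 points (0–100% inclusive). Reported peak tensions come from the
exact mesh-point law, not the resampled profile, to avoid interpolation
clipping. The four named designs (medium-original 120 N/m @ 25%, long-stiff
240 @ 37.5%, short-stiff 240 @ 12.5%, long-compliant 30 @ 37.5%) are
reporting conveniences — selection for experiments was a judgment call, so
`rank_designs` reports candidates and the argmin but never auto-decides.

## Experiment analysis

Gas exchange converts to power with the Brockway equation
(16.58 kJ/L·V̇O₂ + 4.51 kJ/L·V̇CO₂); the citation chain for the original
protocol does not pin a formula, so this conventional choice is documented
here and swappable. Powers are time-weighted (trapezoidal) means over the
final 60 s of a trial, normalized by body mass; net power subtracts a
standing baseline processed identically; the mean RER over the same window
drives the >1.0 exclusion rule. Exclusions propagate as missing values
(never zeros) and statistics drop incomplete pairs listwise.

Marker tension applies the exact spring law to the 3-D Euclidean distance
between the two shoe markers (200 Hz). Foot strikes are vertical-position
minima with prominence (1 cm) and minimum-period (0.4 s) guards; each cycle
is time-normalized to 101 points, averaged within runner, then across
runners; a minimum of five usable cycles is enforced. Marker gaps ≤5
samples are linearly interpolated; longer gaps drop the cycle with a count.

The statistical family is Shapiro-Wilk on within-subject differences,
two-sided paired t, Bonferroni ×4 (in-lab conditions) or ×3 (track
metrics: 5-km time, mean heart rate, cadence; differences are exotendon −
natural, so a faster assisted run is negative).

## Synthetic data

The gait generator produces periodic coordinate trajectories from
literature-shaped control points (hip ≈ −20..40°, knee ≈ 0..−100°, ankle ≈
−20..15°) via periodic cubic splines, a 0.35 duty factor per leg, and a
single-peak sinusoidal vertical GRF per stance scaled so the stride impulse
equals m·g·T exactly; fore-aft GRF is a zero-impulse braking/propulsion
sinusoid. Pelvis height is derived from the model's foot geometry so the
stance foot lightly penetrates the ground (≈6 mm) — roughly consistent with
the contact model — with a 3 cm flight clearance bump. Average speed is
exact by construction.

The calorimetry generator uses a mean net running cost of 15.8 W/kg
(SD 1.6) so that the headline −0.9 W/kg condition effect is −5.7%; the
default multiplicative condition effects are medium-original 0.943,
short-stiff 0.962, long-compliant/long-stiff 0.981, with between-subject
effect SD 0.057 and log-normal multiplicative breath noise (SD 0.06) at
0.75 Hz breathing. RER is drawn per trial (mean 0.88, SD 0.035) with an
optional exceedance rate to exercise the exclusion rule. These defaults are
the study conditions; they live in `CalorimetrySpec` and are not tuned per
test.

What the generators do **not** emulate: kinematic inconsistency between
marker noise and GRFs, breath-by-breath autocorrelation and drift,
within-trial non-stationarity, and subject-specific gait geometry. Passing
tests therefore demonstrate pipeline correctness and calibration under the
stated noise model, not robustness to every artifact of real recordings.

## Known limitations

- Constant moment arms: no coordinate-dependent moment-arm polynomials yet;
  the config format leaves room for them.
- Coarse-mesh effect sizes overshoot (see above); sweeping the full 5×5×4
  grid at fine meshes is hours of CPU and is not part of the default tests.
- The planar model cannot express mediolateral anchor dynamics; the
  constant 0.25 m offset is a first-order stand-in.
- `trust-constr` occasionally stops at the iteration cap with feasibility
  long since achieved; costs at the cap can differ at the percent level
  from a fully optimal point, which is one reason design comparisons use a
  shared iteration budget.
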