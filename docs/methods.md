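# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package.

## Robot model

The manipulandum is a planar five-bar linkage: two actuated base joints on
the x-axis (separation `d`), two proximal links, two distal links closing at
the handle.  Generalized coordinates are the two actuated base angles
`q = (q1, q2)`; the passive elbows are eliminated analytically through the
loop-closure constraint.  The workspace is horizontal, so there is no
gravity term and the equations of motion are

    M(q) q̈ + C(q, q̇) q̇ = u.

`M(q)` is assembled from per-body velocity maps: every link COM velocity and
angular rate is a linear function of q̇ obtained by differentiating the
closure construction, so

    M(q) = Σᵢ mᵢ BᵢᵀBᵢ + Iᵢ wᵢwᵢᵀ + m_e JᵀJ,

with `J` the endpoint Jacobian and `m_e` the handle/sensor lump.  `C` uses
the Christoffel symbols of `M`; the configuration gradient `∂M/∂q` is taken
by central differences (step 1e-6 rad).  Because the Christoffel
construction uses the *same* numerical gradient, `Ṁ − 2C` is skew-symmetric
identically and torque-free simulations conserve kinetic energy to the
integrator tolerance (asserted to 1e-6 relative over 1 s; typically ~1e-8).

Forward dynamics integrate `q̈ = M⁻¹(u − Cq̇)` with adaptive RK45
(`rtol 1e-8`, `atol 1e-10`), dense output resampled at 200 Hz, torque series
interpolated with a cubic spline.  Inverse-dynamics inputs derived from an
endpoint plan use the analytic relation `q̇ = J⁻¹ẋ` and
`q̈ = J⁻¹(ẍ − J̇q̇)` with `J̇` from finite differences of `J` over `q`; the
inverse→forward round trip reproduces a 0.14 m minimum-jerk reach endpoint
to < 1e-4 m (typically ~1e-6 m).

The closure branch is fixed elbow-out (left elbow left of the base→endpoint
ray, right elbow right of it, endpoint above the elbow line); inverse
kinematics never switches branch.  Singular configurations are detected by
the condition number of the closure matrix and of `J` (limit 1e8) and raise
explicit errors.

### Effective endpoint mass

For a unit direction `u = (cos θ, sin θ)` the effective mass is the
projection of the endpoint-space inertia,

    m_r(q, θ) = uᵀ J⁻ᵀ M(q) J⁻¹ u.

It is exactly the point mass whose kinetic energy at the endpoint velocity
equals the full linkage's kinetic energy when the direction is that of the
actual motion — an algebraic identity the suite asserts on 1000 random
states to 1e-10 relative.  The polar profile is π-periodic and its extremes
are the eigenvalues of `J⁻ᵀMJ⁻¹`.

### Default parameters and calibration

The hardware values of the original device are unpublished.  The shipped
nominal set is a plausible desk-scale device (base separation 0.12 m,
proximal links 0.30 m, distal 0.42 m, handle lump 0.8 kg) with most of the
drive-train mass on the left chain, which makes the endpoint inertia
laterally anisotropic.  A bounded least-squares calibration over an inertia
scale and the robot-base placement relative to the body midline matches the
effective mass along the lateral hit direction to 1.5 kg at the right-court
centre and 1.0 kg at the left-court centre (residual < 2e-8 kg; the problem
is underdetermined, so the shipped constants are one point on the solution
manifold, frozen in `linkage.CALIBRATED_INERTIA_SCALE` and
`geometry.ROBOT_BASE_OFFSET`).  Both courts lie inside the reachable
workspace with Jacobian condition numbers near 1.  Because the parameters
are a stand-in, absolute torque magnitudes are not comparable to hardware;
all model-level claims are about kinematic errors and mass ratios, which the
calibration pins down.

## Pong generator

The game runs on a 5 ms (200 Hz) loop.  Courts are 0.2 m squares: a frontal
court centred on the midline (delay τ = 80 ms) and two lateral courts
meeting at the midline (τ = 120 ms).  The *visual paddle* is the hand
delayed by τ (linear interpolation of the hand history; the first τ seconds
show the initial state) and the ball physics interact with the visual
paddle; the delay is thus applied on the hand→game channel while the ball is
rendered live, which matches the two-paddles description of the task.
Collisions follow `v⁺ = 0.7·R(θ)v⁻ + 0.42·v_paddle` with `R` the reflection
about the paddle line; far-wall bounces add a uniform ±0.13 m/s perturbation
to the along-wall velocity component; ball speed decays linearly at
0.05 m/s² (unprinted constant, package choice); each collision emits a 5 ms
haptic pulse `f = 0.05·Δv_ball`, time-shifted by τ in delayed sessions.
Balls leaving the near edge are re-served from the court centre toward the
far wall (0.4 m/s, random heading within ±0.5 rad) after a 0.3 s pause.

### Artificial player

The player predicts the ball's return to an aim point near the court centre
(deterministic extrapolation with the known friction law; the transverse
component is corrected after the far-wall bounce if the stroke has not
started) and executes a reciprocal minimum-jerk out-and-back stroke along
the hit axis.  For a symmetric stroke under delay τ, the visual and
proprioceptive speeds cross τ/2 after the true peak; the player places the
contact at `crossing + δ`, so the timing offset δ < 0 / = 0 / > 0 generates
the accelerating / crossing / decelerating hit categories, i.e. negative /
zero / positive mass modifiers.  With τ = 0 the crossing coincides with the
peak-speed instant.

Per-stroke noise: timing jitter (SD 8 ms), amplitude jitter (SD 5 mm), aim
jitter along the hit axis (SD 4 cm, clamped ±8 cm — contacts are mid-court
only *on average*) and stroke-direction wobble (SD 0.12 rad).  The latter
two give the per-hit reference mass `m_v = m_r(q_hit, θ_hit)` a realistic
spread, which matters because the outlier rule is keyed to the SD of the
visual-mass sample.  Stroke defaults: amplitude 0.14 m, out-phase 0.45 s
(peak speed ≈ 0.58 m/s), retraction 0.35 s ending *behind* the near edge —
the court confines the ball, not the hand, and parking the hand outside the
ball's corridor prevents spurious follow-through collisions.  A 0.3 s
refractory debounces the contact detector, and new preparation moves never
cut into the trajectory within 0.25 s of a collision, so the velocity trace
around each hit is an uncorrupted minimum-jerk profile.  Strokes that cannot
be prepared in time are skipped and the ball is lost (logged as a miss);
rallies are therefore serve-paced at roughly 35–50 hits/min.

Sessions are fully reproducible: one seeded generator drives serves, bounce
noise and stroke jitters, and identical (config, player, seed) give
byte-identical logs.

### What the generator does not emulate

Real arms have their own inertia and muscle dynamics; the hand here follows
kinematic minimum-jerk plans exactly (plus the explicit jitters).  There is
no trial-by-trial adaptation (an optional linear δ decay exists, default
off), no auditory channel, no closed-loop within-stroke corrections, and
misses are resolved by re-serves rather than opponent play.  Passing tests
therefore show that the estimation and prediction stages recover what the
generator put in — not that human players behave like the generator.

## Estimation

Hand velocities are smoothed with a zero-phase (forward–backward)
fifth-order Butterworth low-pass at 20 Hz; zero phase keeps hit-time values
unshifted.  For each hit in the analysis window (default: last 5 minutes),
`v_p` is the smoothed hand speed at `t_hit` and `v_v` the smoothed hand
velocity at `t_hit − τ`, both projected on the motion direction at the hit —
the same direction used for `m_r`, which keeps the kinetic-energy identity
`½(m_r+m̂)v_p² = ½m_r v_v²` exact per hit.  Hits earlier than τ after
session start are skipped; hits with `v_p < 0.02 m/s` are rejected before
the ratio is formed (the 10-SD filter alone does not guard the division).
Hits whose `m_p` lies more than ten SDs of the visual-mass sample from its
mean are removed; with a zero-spread visual sample only exact matches are
retained (documented convention).  Fusion weights are inverse empirical
variances over the window's hits (the source of σ² is not otherwise
specified); a single zero-variance channel takes all the weight, two raise
an error.  The session-level modifier uses the fused `E(m)` against
`m_r = mean(m_v)`; the per-hit closed form is also exposed.

Inverse-variance fusion shrinks the modifier toward zero whenever the
proprioceptive sample is noisier than the visual one — with the default
jitters, session-level `|m̂|` comes out around 0.05–0.3 kg for
`|δ| ≈ 20 ms`, and the deceleration side is damped more because `v_p` is
smaller and more variable there.

## Reach prediction

Blind reaches are straight minimum-jerk movements (0.14 m to three targets
45° apart; default duration 0.6 s — unprinted, and the suite checks the
sign law over 0.4–1.0 s).  "Adding the mass modifier" augments the endpoint
point mass — the only placement that adds exactly m̂ to the effective mass
in every direction and configuration.  Torques from inverse dynamics on the
augmented model are replayed open-loop on the true model; the outcome is
read at the end of the planned duration (no stopping controller — the reach
is blind by construction), with the peak-excursion extent also emitted.
The augmented endpoint mass must stay positive (m̂ > −0.377 kg with the
calibrated defaults), otherwise the model is rejected as nonphysical.
Extent error is approximately linear in m̂ near zero (≈ 0.13 mm per gram
at the right-court targets) and strictly monotone over [−0.3, +0.7] kg.

## Cohort replications

A cohort draws per-subject timing offsets δ ~ N(mean, SD), simulates one
delayed pong session per subject, estimates m̂ from the end-of-adaptation
window, and simulates pre (m̂ = 0) and post (estimated m̂) reach batteries;
observed changes add seeded Gaussian endpoint noise (SD 5 mm) because blind
reaches are inherently noisy.  Lateral cohorts reach in both courts.  The
variance ledger compares a group-level predictor (every subject assigned the
group-mean m̂) against the individual-timing predictor on the observed
changes, as `1 − SS_res/SS_tot`.  Desk-scale defaults are 2.5–3 minute
sessions with a 2-minute window and 4–8 subjects; the estimator is
insensitive to the window length, and the tests use these sizes so the whole
suite stays within a few minutes.

Session metrics: the timing metric locates each stroke's smoothed-speed peak
within ±0.2 s of the hit (repositioning moves live further away) and
averages `t_hit − t_peak`, so with τ = 0 it recovers the generative δ; the
visuomotor gain is the arm/visual-paddle path-length ratio from movement
initiation (5 % of stroke peak speed, exposed in config) to contact; the
spatial mismatch is the mean hand-to-visual-paddle distance at hits
(`|v|·τ` for constant-velocity motion).

## Numerical conventions and degenerate inputs

* Coordinates: +x rightward, +y away from the body, angles CCW from +x;
  robot frame = body frame minus the calibrated base offset.
* Closure failures, workspace violations and singular Jacobians raise typed
  errors (`ClosureError`, `WorkspaceError`, `SingularityError`) rather than
  returning NaNs; reach batteries and cohorts log failures and continue.
* Effective mass is invariant under θ → θ + π by construction (quadratic
  form); profiles are sampled on uniform angular grids.
* All randomness flows through `numpy.random.default_rng` seeds recorded in
  session headers.

## Known limitations

* The linkage parameters and base placement are calibrated stand-ins; only
  quantities pinned by the calibration targets (effective-mass levels and
  ratios) are meaningful in absolute terms.
* Joint friction and motor dynamics are not modelled.
* The artificial player's timing offset is imposed, not learned; adaptation
  dynamics within the game are out of scope.
* The outlier rule follows the stated 10-SD-of-visual-mass convention; with
  an unrealistically stereotyped player (no aim or direction variability)
  that rule can remove genuine signal, which is why the generator's spatial
  variability defaults are part of the study conditions.
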