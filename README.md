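# pongmass

Event-based mass perception in a delayed virtual pong game.

When people play pong holding the handle of a planar robot while the visual
scene lags their hand by a fixed delay τ, they effectively play with two
paddles: a *proprioceptive* paddle (the hand, undelayed) and a *visual*
paddle (the hand delayed by τ).  At each ball collision the two channels
report different paddle speeds.  If the brain estimates the inertia of what
it is holding only at such energy-exchange events — and insists that the
estimated kinetic energy transferred be the same in both modalities — then
the velocity mismatch is absorbed into a perceptual *mass modifier*

    m̂ = m_r · (v_v² − v_p²) / v_p²,

where `m_r` is the true effective endpoint mass of the robot at the hit
configuration along the motion direction, `v_v` and `v_p` the visual and
proprioceptive paddle speeds at the hit.  Hits during hand acceleration
(`v_v < v_p`) give negative modifiers, hits at the crossing give zero, hits
during deceleration give positive ones.  Per session the two per-hit mass
samples, `m_v = m_r` and `m_p = m_r v_v²/v_p²`, are fused by
maximum-likelihood (inverse-variance) weighting,

    E(m) = w_v·mean(m_v) + w_p·mean(m_p),   w_i ∝ 1/σ_i²,   m̂ = E(m) − m_r,

and the misperceived mass predicts the outcome of *blind* (open-loop)
reaches: torques planned on a robot model augmented by m̂ and replayed on the
true model overshoot the target for m̂ > 0 (hypermetria) and undershoot for
m̂ < 0 (hypometria).

The package is aimed at computational sensorimotor-control researchers who
want a fully synthetic, testable replication of this pipeline:

* `pongmass.linkage` — five-bar-linkage kinematics and Euler–Lagrange
  dynamics: inertia matrix M(q), Coriolis matrix, Jacobian, the
  direction-dependent effective endpoint mass
  `m_r(q, θ) = uᵀ J⁻ᵀ M(q) J⁻¹ u`, inverse/forward dynamics, and a
  calibration routine for the (unpublished) hardware parameters.
* `pongmass.pong` — an event-driven delayed pong simulator with a parametric
  artificial player whose hit-timing offset δ realizes the three hit-timing
  categories; collision law `v⁺ = 0.7·R(θ)v⁻ + 0.42·v_paddle`, linear ball
  friction, ±0.13 m/s far-wall bounce noise, 5 ms haptic pulses
  `f = 0.05·Δv`, 200 Hz logs.
* `pongmass.estimation` — zero-phase 5th-order 20 Hz Butterworth velocity
  smoothing, hit-event extraction, the 10-SD outlier rule, ML fusion and the
  mass modifier (`MassModifierEstimator`).
* `pongmass.reach` — minimum-jerk planning, model augmentation, feedforward
  replay, extent/lateral error measures.
* `pongmass.pipeline` — whole-experiment cohort replications (frontal,
  lateral-right, lateral-left groups), timing/gain/mismatch session metrics
  and the variance-explained decomposition.

## Worked example

```python
import numpy as np
from pongmass import (PongConfig, PlayerModel, run_pong_session,
                      MassModifierEstimator, ReachSpec, reach_battery,
                      DEFAULT_LINKAGE, court_for_group)

config = PongConfig(court_side="LP_R")            # right lateral court, tau = 120 ms
player = PlayerModel(timing_offset=0.02)          # hits ~20 ms into deceleration (t3)
session = run_pong_session(config, player, duration=300.0, seed=7)
print(f"{len(session.hits)} hits in {session.header['duration']/60:.0f} min "
      f"({session.misses} misses)")

est = MassModifierEstimator(window_minutes=5.0).fit(session).estimate_
print(f"reference effective mass m_r = {est.m_r:.2f} kg")
print(f"fused apparent mass   E(m)  = {est.E_m:.2f} kg")
print(f"mass modifier         m_hat = {est.m_hat:+.2f} kg "
      f"({est.n_hits_retained} hits retained)")

court = court_for_group("LP_R")
specs = [ReachSpec(start=tuple(court.reach_start), target=tuple(t))
         for t in court.reach_targets()]
outcomes, summary = reach_battery(DEFAULT_LINKAGE, est.m_hat, specs)
for i, o in enumerate(outcomes):
    print(f"target {i}: extent error {o.extent_error*1000:+.1f} mm")
print(f"mean extent error {summary['mean_extent_error']*1000:+.1f} mm (hypermetria)")
```

Output:

```
171 hits in 5 min (192 misses)
reference effective mass m_r = 1.57 kg
fused apparent mass   E(m)  = 1.67 kg
mass modifier         m_hat = +0.10 kg (171 hits retained)
target 0: extent error +8.3 mm
target 1: extent error +13.3 mm
target 2: extent error +15.2 mm
mean extent error +12.3 mm (hypermetria)
```

A player who tends to strike ~20 ms into the deceleration phase sees the
visual paddle moving faster than the hand at contact, over-estimates the
robot's mass by about 0.10 kg in the right court (true effective mass
≈ 1.5 kg there), and consequently overshoots blind reaches by ≈ 1.2 cm.
Setting `timing_offset=-0.02` flips both signs; the left court
(`court_side="LP_L"`, effective mass ≈ 1.0 kg) scales the effect down.

Four console commands wrap the same stages: `simulate-pong`,
`estimate-mass`, `predict-reach`, `run-experiment` (see `--help`).

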