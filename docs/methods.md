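# Methods

## The model in brief

A simulated walker with a 1 m circular body repeatedly approaches a doorway
(widths 3 / 2.5 / 2 m, labelled wide / medium / narrow) at the end of a
4 m × 10 m corridor.  Two levels of control are modelled:

1. **Cortico-basal-ganglia level** — an actor-critic reinforcement learner.
   The *state* is a 50-component binary view vector φ: a 120° fan of gaze
   sectors, each set to 1 if its ray meets the door line inside the opening.
   The *critic* is V = tanh(W·φ), trained by the temporal-difference (TD)
   error δ = r + γV(t) − V(t−1), the model's dopamine correlate.  The
   *actor* is the GO/EXPLORE/NOGO (GEN) policy: the displacement update

   ΔX(t) = A_G·sig(λ_G s)·ΔX(t−1) + A_E·χ·exp(−s²/σ²) − A_N·sig(λ_N s)·ΔX(t−1)

   with χ ~ U[−0.5, 0.5] per component, A_G = 2.5, A_N = A_E = 1,
   λ_G = −λ_N = 1, and s the switching signal.  δ trains the value weights;
   the value difference δ_V = V(t) − V(t−1) switches the GEN regimes.
   Parkinsonian conditions clamp the *learning* signal — PD OFF:
   δ ← min(δ, δ_lim); PD ON: δ ← min(δ, δ_lim) + δ_med — and change the
   discount γ (a serotonin correlate) and exploration width σ (a
   norepinephrine correlate) per the published condition tables.

2. **Spinal level** — three pools of adaptive Hopf oscillators (2 for the
   hip, 3 per knee) learn one 500-sample, 1 s gait cycle of hip/knee angle
   teach signals.  Each oscillator adapts its frequency ω and output weight
   α to one Fourier component of the forcing error F = P_teach − Q_learned;
   phase variables ψ (intra-pool) and ψ^G (inter-pool, hip-referenced)
   record and hold the phase relations.  After convergence the forcing is
   removed and the network free-runs the rhythm at a fixed cadence of 2
   steps/s.

The two levels meet at the gain k = A_k·tanh(c_k‖v‖) (A_k = 3, c_k = 1):
the commanded velocity scales the oscillator output weights, hence the hip
excursion, hence the stride through the two-link leg (thigh 0.5 m, shank
0.6 m):

L_STR = 2(l₁+l₂)·sin(θ_ext2/2) + 2(l₁+l₂)·sin(θ_ext3/2),

where θ_ext2, θ_ext3 are the hip-angle extrema of the cycle; step mode
keeps the first term only.  The agent advances by L_STR along the unit
velocity; a backward command (v_y < 0) moves it by a 0.0001 m placeholder
instead, so each iteration is one stride and one second.

## The freezing mechanism

Condition parameters shape the value landscape and the policy's reaction to
it.  Controls learn a map that rises toward the (rewarding) door; PD
clamping forces almost every update negative, producing an inverted map
with a collision-carved trough before the doorway.  Walking down a value
gradient makes δ_V consistently nonzero, which (i) suppresses the EXPLORE
term once |δ_V| is comparable to σ and (ii) leaves the contractive
GO−NOGO part (net factor < 1 near δ_V = 0), so the displacement — and with
it the stride — shrinks toward zero: a freezing episode.  The tiny σ of the
PD OFF and freezer presets makes the suppression hairtrigger; the larger σ
of PD ON and non-freezers buffers it, which is how medication state enters
the behaviour.  Narrower doors cause more door-post collisions during
training, a deeper trough, and a stronger dip — the doorway effect.

## Free choices and calibration

The published description leaves several pieces open.  They are fixed here
as follows, once, and exposed as flags or config fields:

- **Critic learning rate η = 3e-4** (unspecified in the source).  The
  50-sector sums saturate tanh if η is large (≥1e-2); a saturated map has
  δ_V ≈ 0 everywhere, every condition degenerates to the same random walk
  and all group differences vanish.  3e-4 keeps the landscapes in their
  documented shapes within the 100-pass training budget.
- **Gaze** is door-facing at every step (`gaze_mode="door_facing"`), making
  position → φ a unique map, which is what hill-climbing over position
  space presumes.  A displacement-direction gaze is available.
- **Walls** are punished (r = −1) but non-terminal: the agent reflects
  elastically off the wall line and walks on (`wall_mode="bounce"`).  With
  terminal walls, random-walk exploration dies within ~12 steps, the
  passage reward is never discovered, and no condition can learn the task.
  Terminal walls remain available (`wall_mode="terminate"`).
- **GEN switching signal** is δ_V (`gen_signal="delta_v"`); the clamped δ
  drives learning only.  Feeding the clamped δ to the actor is available
  behind the flag, but then the EXPLORE weight becomes the constant
  exp(−(δ_lim/σ)²) and the dopamine-clamp null result (below) cannot hold.
- **Teach signals** are truncated Fourier series with a 1 Hz hip
  fundamental (amplitude 0.45 rad ≈ 26°, a physiological hip excursion,
  plus a 0.15-weight second harmonic giving the asymmetric extrema) and
  2 Hz knees with harmonics at 4 and 6 Hz, zero at the hip extrema.  The
  exact coefficients of the source profiles are not published; all
  downstream quantities depend only on the extrema structure.  The default
  yields control strides of ≈1.35 m and steps of ≈0.6 m.
- **Initial conditions**: W = 0; ΔX(0) = 0.1 m toward the door centre;
  start at y = 0.1, x uniform where the body fits; orientation toward the
  door centre.
- **Terminal value** is 0 (episodic TD convention), so δ = r − V(t−1) at
  the door.

## Protocols and statistics

Per condition and door: 100 training passes (weights updated sequentially),
then 50 test *trials* of 100 passes each with frozen weights.  Test passes
are simulated lock-step in batches; training is sequential.  All
randomness flows from one master seed through spawned substreams; results
are bit-reproducible per seed.

- **Velocity profiles**: per pass, v_y is linearly interpolated onto a
  0.1 m y-grid; passes are averaged pointwise per trial; profiles are
  normalized to the far-field mean (y ∈ [4, 5] m, i.e. 5–6 m before the
  door).  The dip depth is 100 minus the profile minimum within 2 m of the
  door.
- **Stride/step means**: the same interpolate-then-average protocol applied
  to the executed stride length, averaged over the 2 m pre-door window
  (and the |x| ≤ 2·d_pos consistency window, which the 4 m track already
  implies).  Position-weighting matters: a raw step-weighted mean
  over-represents whichever passes move fast enough to reach the window.
- **Step-length CV**: population SD/mean of the executed forward steps in
  the pre-door window, per trial, averaged over trials.  The 0.0001 m
  suppressed-backward placeholders are freeze markers, not steps, and are
  excluded; including them makes CV measure the explore-noise reversal
  rate (~50% of iterations in every condition) rather than step
  variability.
- **Group comparisons**: Welch two-sample t-tests on per-trial means
  (the source does not name its test).  Degenerate zero-variance pairs
  short-circuit to p = 1 when means agree.

## Numerical choices

- The oscillator equations are integrated with fixed-step RK4 at
  dt = 1/500 s (matching the 500-sample cycle); the teach sample is held
  constant within a step.
- The q-equation uses +ω·p (the rotation sign required for oscillation).
- The phase-coupling term uses the same sine argument as the phase-memory
  dynamics (τ·sin((ω_i/ω_0)·θ_0 − θ_i − ψ_i)); it vanishes at the recorded
  offset and only corrects drift, which is what lets the forcing converge.
- The reference oscillator of each pool keeps the ξ-relaxation and the
  forcing term; its coupling target is the previous pool's reference
  through ψ^G (the hip reference leads and is uncoupled).
- Convergence: training stops when every pool's RMS forcing over a cycle
  drops below 0.05 rad (default; the hip pool, which alone sets stride,
  settles below 0.002 — the knee pools plateau near 0.02–0.05 with their
  weaker forcing gain ε = 0.3).
- During gait runs the converged rhythm is evaluated analytically (the
  output is linear in the weights, so gain k scales a stored free-run cycle
  exactly); an ODE-reintegration mode exists and agrees to < 1e-6 rad.
- z = 0 in the phase/frequency laws is guarded by a 1e-9 floor; the
  explicit `instantaneous_phase` helper raises instead.

## What the synthetic world does and does not capture

All inputs are generated internally; there is no human data in the loop.
The corridor is a plane with a door line — no depth vision, no occlusion
by walls, no body dynamics (the leg model is purely kinematic), fixed
cadence, and collision handling by disc overlap at the door line.  Passing
the group-statistics tests therefore shows that the *mechanism* —
clamp-shaped value landscapes driving a GEN walker through an
amplitude-modulated CPG — reproduces the published orderings and
significance bounds under these idealized conditions; it says nothing
about fits to real gait recordings.

## Known limitations

- The PD ON door-width stride effect is right-signed but weak: wall-bump
  punishments are door-independent and, through the shared view features,
  dilute the door-specific collision signal.  Narrow-vs-medium stride
  differences within PD ON do not reliably reach p < 0.005 at N = 50.
- The dopamine-clamp (δ_lim) sweep is not a perfect null: the deepest
  clamp saturates the landscape, quiets δ_V, re-enables EXPLORE and
  lengthens strides by ~3% — far smaller than the σ effect (~35%), so the
  qualitative conclusion (dopamine clamping alone does not produce
  freezing; exploration width does) stands, but individual pairs can reach
  p < 0.05.
- Lowering γ alone to 0.1 does not shorten strides here: at the narrow
  door the expected terminal reward is near zero, so the γ = 0.8 control
  landscape is already nearly flat and extra myopia changes little.  The
  σ route to freezing reproduces strongly.
- Group mean levels (metres) are calibration-dependent through the teach
  amplitude; only orderings and significance bounds are treated as
  reproduction targets.
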