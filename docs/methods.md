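# Methods

## Model

`pcmotion` decomposes the motion of N tracked objects into one shared and N
individual latent motion sources with a two-level predictive-coding network.
The level-0 input is the observed per-frame velocity
`x_i(t) = (p_i(t) − p_i(t−1)) / dt`; feeding velocities (rather than raw
positions) makes the first-level error a velocity residual and matches the
interpretation of the first-level sources as velocities and the second level
as their slowly varying (acceleration-like) prediction. The network
minimises

    E = ½ ‖x − U¹r¹‖² + ½ ‖r¹ − U²r²‖²

with explicit-Euler gradient descent: activities relax at rate γ on a fast
timescale (`inner_iters` steps of length `dt_int = dt/inner_iters` per
stimulus frame), weights take one Hebbian step `ΔU¹ = η·dt_int·e⁰ r¹ᵀ` per
frame (the dot product contracting the two velocity components) and are
clipped to [0, 1] and to the connectivity mask afterwards (projected
gradient). U² is identity-sized and frozen by default; a `gamma2_frac`
setting can slow the second level relative to the first.

The connectivity is one shared source reaching every object plus one
private source per object. The network is therefore *overcomplete* (N+1
sources for N objects): which decomposition is learned is decided by the
dynamics, not by the objective alone. Two deliberate asymmetries implement
"shared-first" attribution:

* **Partial within-frame relaxation.** γ defaults to `relax_frac/dt`
  (relax_frac = 0.2), capped by the Euler stability bound
  `0.5/(dt_int·(N+1))` of the shared mode, whose stiffness grows with its
  fan-in. Full equilibration every frame would zero the error before the
  slow weights could attribute motion to anyone.
* **Warm shared / cold individual initialisation.** Shared weights start at
  U(0.1, 0.3), individual weights at U(0.002, 0.01). Private pathways
  bootstrap multiplicatively (their source is driven through their weight),
  so a cold start means they only acquire strength where a residual
  *persists* after the shared source has claimed the common component. The
  small positive floor prevents the degenerate case of a pathway that can
  never bootstrap at all.

## Surround suppression

Each object's estimate is compared with the equal-weight mean estimate of
its neighbours within a circular surround (centre excluded by default;
`include_self` switches to a consensus mean). The binary activation

    f = H( H(‖v̂ − v̄‖ − θ₁) − f̄_w − θ₂ )

uses a strict Heaviside (H(0) = 0) and a per-object history average `f̄_w`
over the last w milliseconds; a persistently active gate therefore switches
itself off once `f̄_w > 1 − θ₂`. The gate, its history, and the gated
residual `e⁰ = x − v_g` all live on the *fast* timescale: with the study's
frame interval of 50 ms, window durations of 10–90 ms are sub-frame and can
only be resolved if the history advances at the integration step (1 ms by
default). The per-frame weight update uses the gate's mean activation over
the frame (a fractional duty cycle): sampling a single step instead would
alias sub-frame gate cycles against the frame raster and artificially
favour window durations that divide the frame evenly.

Objects with an empty surround receive their own estimate as `v̄`, which
keeps the gate inactive: no contextual evidence, no suppression.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `gamma` | auto: min(0.2/dt, 0.5/(dt_int·(N+1))) | 1/s | activity (inference) rate |
| `eta` | auto: 100 / v_rms² | — | weight learning rate (normalised-LMS: per-frame weight increments are independent of the stimulus's velocity scale) |
| `inner_iters` | 50 | — | activity steps per frame; dt_int = dt/50 = 1 ms at dt = 50 ms |
| `theta1` | auto: 0.5·v_rms | units/s | surround deviation threshold (0.005 units/s for the standard RDK) |
| `theta2` | 0.5 | — | history threshold |
| `window_ms` | 30 | ms | suppression history window |
| `diameter` | auto: max(extent/4, 3 × median NN distance) | units | surround diameter; the nearest-neighbour floor lets sparse 2–3 dot displays see each other |
| `strength` | 1.0 | — | fraction of the deviation removed when active |

The auto-scaled defaults (γ, η, θ₁, d) adapt to the stimulus's velocity and
spatial scale so one configuration serves displays whose speeds differ by
three orders of magnitude. The free constants (relax_frac, eta_scale, the
initialisation ranges) were fixed once on the qualitative decomposition
behaviours of the three classical displays and then frozen.

## Stimuli

* **Johansson display**: three collinear dots; outer dots oscillate
  horizontally (0.5 Hz, amplitude 20.3 units), the middle dot diagonally
  (vertical amplitude cos 45°·20.3), dt = 1/60 s. Default duration 24 s
  (12 periods): the outer dots' transiently acquired individual strengths
  need several periods to decay.
* **Duncker wheel**: hub translating at 0.5 units/s plus a rim dot at
  radius 10. The default angular speed is the *rolling-wheel* constraint
  ω = h_speed/radius = 0.05 rad/s, the kinematic relation that makes the
  rim trace the cycloid of a rolling wheel; default duration 60 s (about
  half a revolution).
* **RDK**: 1000 dots (sweeps use a 200-dot scaled version), initial
  positions uniform over a square of side √(n/density) with density
  500 dots/unit², signal dots at 0.01 units/s horizontally, noise dots at
  0.01 units/s with direction re-drawn per dot per frame (uniform angle by
  default; a vertical sign-flip mode is available), dt = 0.05 s. Dots
  drift freely: total drift is a small fraction of the field side at these
  speeds, and a wrap-around rule would inject spurious ~28 units/s
  observed-velocity jumps.

"Signal-to-noise dots ratio" in the experiment grids is the ratio
N_signal/N_noise; a ratio r maps to the generator's coherence fraction
r/(1+r).

What the generators emulate — and what they do not: trajectories are
noiseless kinematics; there is no internal neural noise, no dot lifetime,
no aperture or luminance model. Passing tests therefore show that the
*decomposition and gating dynamics* behave as described under clean
kinematic input, not that the model is robust to sensor- or neural-level
variability.

## Convergence metric and experiments

A run is converged at the last frame of the first window of
`sustain_frames = 10` consecutive frames in which the mean shared strength
of the signal dots changes by less than 0.05 between successive frames,
provided the detected direction (the normalised shared-source velocity)
errs by less than 45° there. Non-converged runs are censored at the trace
duration, reported as such, and excluded from cell means (with the censored
count reported). Convergence times are multiples of the 50 ms frame
interval; differences smaller than one frame are not resolvable.

Sweeps (noise ratio, history window, suppression threshold, dot density)
run 30 trials per cell at 200 dots and 10 s per trial by default. Per-trial
seeds derive deterministically from the base seed, the cell's parameter
values and the trial index, so results are independent of sweep order and
reproducible bit for bit.

## Numerical choices

* Explicit Euler throughout; divergence (non-finite state) aborts the run
  with the frame index.
* Strict Heaviside H(0) = 0, so θ₂ = 0 with an empty history reduces to
  pure spatial thresholding.
* The engine exploits the shared + diagonal weight structure directly
  (O(N) per step instead of dense (N×N+1) products) and is cross-checked
  against the dense network operations in the gate-off limit.
* Neighbourhoods are recomputed per frame with a k-d tree and applied as a
  sparse row-stochastic averaging operator.
* The run is fully deterministic given (stimulus, config): the only random
  draw is the weight initialisation from `config.seed`.

## Known limitations

* **Two-dot displays are structurally ambiguous.** With N = 2 each dot's
  surround is exactly the other dot, so suppression is symmetric in the
  pair, and the only systematic asymmetry the dynamics see — constant
  translation versus varying rotation — favours attributing an individual
  source to the *constant* residual. The hub/rim decomposition of the
  Duncker wheel is therefore initialisation-sensitive under the default
  configuration, and the clean "hub individual → 0" outcome is not
  reliably reproduced; the Johansson (N = 3) and RDK decompositions are
  robust.
* The overcomplete weight dynamics exhibit slow attribution creep on long
  oscillatory runs (individual pathways picking up the shared source's
  tracking-lag residual); trial durations are chosen within the window
  where the decomposition is clean.
* Individual motion strengths of noise dots depend strongly on the (not
  independently constrained) learning-rate scale; their ordering relative
  to signal dots is robust, their absolute magnitudes are not.
* The interior optimum of the history-window sweep is resolved only to the
  frame quantum (50 ms); its exact location between 10 and 30 ms is below
  that resolution at the default noise level.
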