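# pcmotion

Hierarchical predictive-coding model of coherent motion detection with a
surround-suppression gate, plus the psychophysical dot-stimulus generators
and convergence-time experiments needed to study it.

## The problem

When many elements of a scene move together — a school of fish, a cloud of
dots on a screen — the visual system decomposes what it sees into a *shared*
(global, coherent) motion and *individual* (residual) motions of each
element. `pcmotion` implements a mechanistic model of that decomposition,
aimed at computational-neuroscience users who want to simulate how contextual
(centre–surround) gating and temporal history shape the detection of
coherent motion in noisy displays, e.g. random dot kinematograms (RDKs).

## The model

Each of N objects has an observed per-frame velocity `x_i`. A two-level
predictive-coding network explains it as a weighted sum of latent 2-D motion
sources,

    v̂_i = Σ_j u_ij r_j ,    u_ij ∈ [0, 1],

with one **shared** source connected to every object and one **individual**
source per object. The network minimises the sum-of-squares prediction error

    E = ½ ‖x − U¹r¹‖² + ½ ‖r¹ − U²r²‖²

by fast gradient descent on the source activities r (inference) and a slow
Hebbian step on the weights U (learning), with the weights — the model's
reported "motion strengths" — projected back to [0, 1] after every step.

A **surround-suppression gate** modelled on MT centre–surround interactions
compares each object's estimate `v̂_i` with the mean estimate `v̄_i` of its
spatial neighbours (a circular surround of diameter d):

    f_i = H( H(‖v̂_i − v̄_i‖ − θ₁) − f̄_w − θ₂ ),

where H is the Heaviside step and `f̄_w` is the object's own activation
history averaged over a window of w milliseconds. While active, the gate
replaces the deviant estimate by the surround consensus
(`v_g = v̂ − f·s·(v̂ − v̄)`), so outliers stop driving the inference of the
global motion. Convergence time — the number of frames until the tracked
shared motion strength stabilises (successive changes < 0.05) with the
coherent direction correctly identified — is the model's analogue of
detection latency, and is studied as a function of the noise level, the
history window w, and the threshold θ₁.

## Worked example

```python
from pcmotion import CoherentMotionModel, ModelConfig, generate_rdk

stim = generate_rdk(n_dots=200, signal_ratio=0.5, duration=10.0, seed=0)
res = CoherentMotionModel(stim, ModelConfig(seed=0)).fit()
print(res.summary())
print(res.convergence())
```

prints

```
Coherent motion decomposition
================================================================
frames processed: 200   dots: 200   dt: 0.05 s
detected direction: (+1.000, -0.007)  [-0.4 deg]
----------------------------------------------------------------
group          n    shared (final)    individual (final)
signal       100             0.849                 0.009
noise        100             0.147                 0.770
----------------------------------------------------------------
ConvergenceResult(converged=True, steps=11, time_ms=550.0, direction_error_deg=1.74)
```

The signal dots end with a high shared motion strength (0.85) and almost no
individual strength — the model attributes their motion to the global
source, whose direction (−0.4° from +x) is the detected coherent direction.
Noise dots keep a low shared strength and carry the residual individual
motion. The model converged 11 frames (550 ms of stimulus time) into the
run.

The same API fits the classical Johansson three-dot display
(`generate_johansson()`): the outer dots' individual strengths decay to
~0.04 while the middle dot — whose diagonal motion contains a vertical
component the shared source cannot explain — keeps the largest individual
strength.

Sweeps over stimulus and model parameters live in `pcmotion.experiments`
(`sweep_noise`, `sweep_window`, `sweep_threshold_noise`, `sweep_density`)
and return tidy per-trial tables with per-cell summaries.

## Command line

```bash
pcmotion init-config -o pcmotion.yaml
pcmotion generate-stimulus rdk --seed 1 --set n_dots=200 -o stim.csv
pcmotion run --stimulus stim.csv -o trace.csv
pcmotion sweep window --config pcmotion.yaml -o window.csv
pcmotion summarize window.csv
```

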