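# loomdyn

Psychophysics and pupillometry of looming threat: power-law modelling of
judged time-to-collision, functional principal component analysis of
event-locked pupil trajectories, and Markov-chain analysis of
behavioural–pupillary state dynamics.

## The problem

In a looming-threat paradigm, a stimulus (threatening or not) expands on
screen for one second and disappears; the participant imagines its
continued approach and presses a key at the judged moment of collision.
Each trial yields a behavioural response — the judged time-to-collision
(jTTC) against the actual one (aTTC) — and a continuous pupil trace.
Analyses of such experiments (for example pharmacological studies of
vasopressin and angiotensin-II blockade across treatment arms) need to
answer three linked questions:

1. **How is subjective time distorted?** The Stevens power law
   `jTTC = α · aTTC^β` separates a scaling bias α (α > 1 =
   overestimation) from a compression exponent β (β < 1 = temporal
   compression that worsens with longer intervals), and a linear model
   `jTTC = α + β·aTTC` serves as the baseline, compared by AIC/BIC.
2. **What temporal shapes organise the pupil response?** After cleaning,
   10-ms binning, baseline correction (0–300 ms fixation window) and a
   two-piece linear time warp (stimulus epoch 300–1,300 ms → [0, 0.5],
   variable imagination epoch → [0.5, 1]), FPCA decomposes the trial
   ensemble into a mean function plus orthonormal eigenfunctions with
   per-trial scores, retaining components until cumulative explained
   variance exceeds 85% (individual components > 5%).
3. **How do joint behavioural–pupillary states evolve across trials?**
   Trials are clustered first on log jTTC (early/late responders), then
   on FPCA scores within each subgroup (profiles E1…/L1…), and the
   per-subject profile sequences are treated as a first-order Markov
   chain: transition matrices, stationary distributions, adjusted
   standardized residuals `(O−E)/√(E(1−r)(1−c))` against independence,
   trigram block entropy (bits) as a flexibility index, and
   subject-level bootstrap confidence intervals for all of it.

Because raw eye-tracking data for such studies are rarely redistributable,
the package ships a first-class synthetic-data generator
(`loomdyn.synth`) that reproduces the statistical structure every stage
assumes — the 5×4×2 factorial, power-law responses with arm/sex/threat
effects, pupil traces built from three orthonormal eigenfunctions with
condition-dependent scores plus AR(1) noise and blinks, and per-arm
transition matrices — so the entire pipeline is testable end to end from
a single seed.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_time_perception_power_law.py` simulates 12 subjects
per arm and fits the models:

```
72 subject x condition fits (80 trials each)
power law preferred in 60% of conditions

mean fitted parameters by arm:
     alpha   beta     r2
arm
AVP  1.785  0.450  0.395
LT   1.490  0.254  0.188
PLC  1.479  0.440  0.378

LME treatment effect on beta, LT vs PLC: -0.161 (95% CI [-0.226, -0.096], p = 1.35e-06)
```

The arm means show the two injected pharmacological signatures — the
vasopressin arm's inflated scaling parameter α and the losartan arm's
reduced compression exponent β — and the random-intercept mixed model
recovers the configured β shift of −0.15 inside its confidence interval.
`examples/05_state_dynamics.py` prints the complementary dynamics
readout: stationary distributions per arm, attractor states
(self-transition > 0.45), a treatment occupancy contrast with
`χ²(14)`, and trigram entropies ordered LT > AVP > PLC.

The full pipeline is one call (or `loomdyn run-all` from a shell):

```python
from loomdyn import RunConfig, SimConfig
from loomdyn.pipeline import run_pipeline

manifest = run_pipeline(RunConfig(sim=SimConfig(n_subjects_per_arm=4),
                                  seed=5, out_dir="out"))
```

which writes trial tables, power-law fits, the trajectory matrix, the
FPCA model, profile assignments, transition matrices, the entropy
contrast and a manifest with the exclusion cascade.

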