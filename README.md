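# rodcascade

Kinetic modelling of the vertebrate rod phototransduction cascade, with
Levenberg–Marquardt estimation of effective reaction rates from the
photoreceptor-dominated initial segment (a-wave) of electroretinogram
(ERG) recordings.

## The problem

When a rod photoreceptor absorbs light, activated rhodopsin (R\*)
catalytically activates transducin (G\*), which activates
phosphodiesterase subunits (E\*) that hydrolyse cGMP; falling cGMP
closes cation channels and produces the early negative ERG deflection
(the a-wave). A battery of calcium-mediated feedbacks — R\* shutoff,
cGMP resynthesis, Ca²⁺ restoration — then drives the inactivation and
recovery phase. `rodcascade` implements a compact mass-action model of
*both* phases, in which the reaction rates appear as explicit
parameters, so that they can be estimated from a recorded ERG and
compared across experimental groups. It is aimed at vision
researchers and modellers who want rate-level summaries of rod function
from flash ERGs.

## The model

Eight normalized concentrations x₁..x₈ — R\*, G\*, the R\*:G complex C₁,
E\*, the E\*:cGMP complex C₂, free cGMP, Gα-GDP (G_r) and cytoplasmic
Ca²⁺ — evolve by mass-action kinetics with 17 effective rate constants
k₁ᵤ..k₁₇. Representative equations:

    dx1/dt = k1u (R0 − x1 − x3) − k2 x1 (G0 − x2 − x3 − x4 − x5 − x7)
             + (k3 + k4) x3 − k13 (Ca0 − x8) x1 − k16 x1
    dx6/dt = −k6 x4 x6 + k7 x5 + k14 (Ca0 − x8)(cG0 − x6) + k15 (cG0 − x6)
    dx8/dt = −k11 (cG0ⁿ − x6ⁿ) + k12 (Ca0 − x8)

with free pools (R₀−x₁−x₃, …) formed on the fly so conservation is
structural. The recorded signal is a Hill-type readout of cGMP
depletion,

    f(t) = k17 (cG0ⁿ − x6ⁿ),   n = 2,

sign-flipped by default so simulated traces are negative-going troughs
like recorded a-waves. Concentrations are ratios normalized against a
fixed rhodopsin pool (R₀ = 50, with G₀ = 5, E₀ = 0.5, cG₀ = 4,
Ca₀ = 0.22 as dark-adapted defaults), so fitted rates are *effective*
rates, comparable across groups fitted under the same normalization.

Three named parameter fixtures ship with the package — `NOB`
(b-wave-suppressed NOB1 mice), `NOB_drug` (photoreceptor-damaged,
drug-treated NOB1) and `wild` (wild type) — holding fitted effective
rates for each group.

Estimation is classic Levenberg–Marquardt on the initial trace segment
(stimulus onset to slightly past the trough, or a fixed 0.28 s
horizon), with forward-difference sensitivities, log-parameterization
for positivity, and co-optimizable pool totals (G₀, E₀, cG₀, Ca₀; R₀
stays fixed as the normalization reference). Forward simulation is
fixed-step 4th-order Runge–Kutta. Fit quality is reported as
‖data − model‖₂/‖data‖₂ × 100 (%).

## Worked example

```python
import numpy as np
import rodcascade as rc

# forward-simulate the NOB group's fitted rates: flash at t=0, off at 0.3 s
params, pools = rc.fixture_parameters("NOB")
sim = rc.simulate(params, pools, rc.Stimulus(0.0, 0.3),
                  rc.SimulationGrid(0.0, 0.5, 1e-3, 5e-5))
i = int(np.argmax(np.abs(sim.signal)))
print(f"a-wave trough: {sim.signal[i]:.2f} model units at t = {sim.times[i]*1e3:.0f} ms")

# generate a noisy synthetic recording and re-estimate k1u from a 1.5x start
stim = rc.Stimulus(0.0, 0.29)
grid = rc.SimulationGrid(0.0, 0.28, 1e-3, 5e-5)
trace, truth = rc.generate_trace("NOB", stimulus=stim, grid=grid,
                                 noise=rc.NoiseSpec(sigma_fraction=0.02, seed=1))
est = rc.PhototransductionFitter(
    free=("k1u",),
    params=truth.params.replace(k1u=1.5 * truth.params.k1u),
    pools=truth.pools, stimulus=stim, window="fixed", t_max=0.28)
est.fit(trace.times, trace.amplitudes)
print(f"recovered k1u = {est.params_.k1u:.4f}  (generating value 0.6717)")
print(f"relative fitting error = {est.result_.relative_error_pct:.2f}%  "
      f"in {est.n_iter_} LM iterations")
```

prints

```
a-wave trough: -187.35 model units at t = 379 ms
recovered k1u = 0.6851  (generating value 0.6717)
relative fitting error = 2.36%  in 4 LM iterations
```

The trough is the model's simulated a-wave minimum. With 2% additive
Gaussian noise the photoactivation rate is recovered to 2% of its
generating value; the residual 2.36% fitting error is the injected
noise floor. The same workflow is available from the shell:

```
rodcascade generate --group NOB --n 3 --noise 0.02 --seed 0 --out traces/
rodcascade fit traces/NOB_00.csv --init NOB --free k1u --window fixed --out fit.json
rodcascade recover --group NOB --free k1u --perturb 1.5 --out report.json
```

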