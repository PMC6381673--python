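# Methods

## Model structure and assumptions

The cascade is modelled as a well-mixed mass-action system on eight
normalized concentrations: activated rhodopsin x₁ (R\*), activated
transducin x₂ (G\*), the R\*:G Michaelis complex x₃ (C₁), activated PDE
subunits x₄ (E\*), the E\*:cGMP complex x₅ (C₂), free cGMP x₆, inactive
Gα-GDP x₇ (G_r) and cytoplasmic Ca²⁺ x₈. Activation follows
Michaelis–Menten-style lumping: R\* catalyses G activation through C₁
(rates k₂, k₃, k₄), G\* activates single PDE subunits (k₅), and E\*
hydrolyses cGMP through C₂ (k₆, k₇, k₈). Inactivation lumps the
GTPase/RGS step into E\* decay producing G_r (k₉) and its recycling to
G (k₁₀). The calcium branch models channel-closure-driven Ca²⁺ efflux
as a Hill function of cGMP depletion (k₁₁, exponent n = 2), Ca²⁺
restoration toward its dark level (k₁₂), and three feedbacks that are
all assumed *proportional to the calcium drop* Ca₀ − x₈: R\* shutoff
via recoverin/RK/arrestin (k₁₃), GCAP/GC-mediated cGMP resynthesis
(k₁₄, also proportional to the cGMP drop), plus calcium-independent R\*
decay (k₁₆) and first-order cGMP buffer release (k₁₅). GTP is treated
as constant, so no nucleotide bookkeeping appears. The readout is
f(t) = k₁₇ (cG₀ⁿ − x₆ⁿ): a Hill-type map of cGMP depletion to recorded
voltage, with k₁₇ absorbing photoreceptor count and instrument gain.

Key structural choices:

- **k₁ᵤ is one parameter.** Photoactivation enters as the product of a
  rate constant and light intensity; only the product is identifiable,
  so a stimulus simply gates it on/off over [t_on, t_off).
- **Normalized pools, R₀ fixed.** Concentrations are dimensionless
  ratios with R₀ = 50 the fixed reference (defaults G₀ = 5, E₀ = 0.5,
  cG₀ = 4, Ca₀ = 0.22); G₀, E₀, cG₀, Ca₀ may be co-fitted, R₀ never.
  Fitted rates are therefore *effective* rates.
- **Free pools are computed, not stored.** R = R₀−x₁−x₃ etc. appear
  only inside the rate expressions, so mass conservation cannot drift.
- **The dark state [0,0,0,0,0,cG₀,0,Ca₀] is a structural fixed point**
  of the light-off dynamics for every positive parameter set: each
  production and decay term vanishes there identically.
- **Sign convention.** f(t) as written is non-negative for cGMP
  depletion, but recorded a-waves are negative troughs. A sign flag
  reconciles the two: the raw readout `erg_output` defaults to the
  equation's positive form, while the trace-producing layers
  (`simulate`, the generator, the CLI) default to −1 so emitted traces
  look like conventional recordings. Fitting works in either polarity.

## Integration

Classic fixed-step RK4 with internal step 5×10⁻⁵ s (default). The
fastest lumped mode is C₁ turnover (k₄ ≈ 5800 s⁻¹ in the fitted sets),
giving k₄·dt ≈ 0.3 — well resolved and stable for an explicit method.
Output is a stride subsample of the internal grid (dt_output must be an
integer multiple of dt_internal), never interpolated, so traces are
bit-reproducible; model evaluation at arbitrary trace timestamps
linearly interpolates the *dense internal* grid, which is exact at
aligned timestamps (the usual case: 1 kHz sampling on a 5×10⁻⁵ s
step). Stimulus switches align with step boundaries under the default
steps, and the per-step light flag is evaluated at the step midpoint,
so the discontinuity never falls inside a stage evaluation.
Verification: step-halving shows 4th-order convergence, and the NOB
scenario over [0, 0.3] s agrees with scipy's LSODA at rtol 10⁻¹¹ to
~2×10⁻¹⁰ max state error.

States are **not clipped** to non-negativity; a dip beyond 10⁻⁶ emits a
`RuntimeWarning` and is recorded in the diagnostics, so model
pathologies stay visible. This matters in practice: the NOB_drug
parameter set (10× higher k₆, hence much deeper cGMP depletion) drives
the non-saturating Hill efflux −k₁₁(cG₀²−x₆²) past what k₁₂ can
restore, and Ca²⁺ runs to ≈ −1.15 within 0.3 s — confirmed with an
independent adaptive solver, so it is a property of the published
equations and rates, not of the integrator. The NOB and wild sets
respect all pool bounds (excess 0.0) on both fitting and long
horizons. A related caveat: after light-off the activated transducin
pool drains only through the E\* channel at rate ≈ k₉·E₀, producing a
plateau in f(t); the signal returns below 1% of the trough at ≈ 3 s
(NOB, wild) and ≈ 4 s (NOB_drug), not earlier.

## Estimation

Standard Levenberg–Marquardt on the windowed residual r = data − model:
solve (JᵀJ + λ·diag(JᵀJ)) δ = Jᵀr, accept only cost-decreasing steps
(λ ÷ 10 on accept, × 10 on reject; λ₀ = 10⁻³; ceiling 10¹²; at most 200
iterations; convergence when the relative cost decrease drops below
10⁻¹⁰ or the residual hits the numerical floor relative to the data
norm). Parameters are fitted as their logarithms — positivity without
constraints, and the natural scale for rate constants — with the
Jacobian obtained by forward differences at relative step 10⁻⁶
(absolute floor 10⁻⁸) and mapped to log-space by the chain rule.
Hitting the damping ceiling without an acceptable step terminates with
`converged=False` and a message rather than an exception, since that is
how LM stalls at an exact optimum or a genuinely singular system.

Window rules: `fixed` keeps samples with t ≤ t_max (default 0.28 s,
inclusive); `trough` finds the global extremum of |amplitude| (so both
polarities work) and keeps t ≤ t_trough·1.15, erroring if the extremum
sits on the last sample (trough not bracketed — note a trace simulated
with the light held on to the end of its grid has its extremum at the
last sample, so trough-rule traces must extend past light-off). The
error metric ‖data − model‖₂/‖data‖₂ × 100 is scale-invariant; samples
outside the window never enter the cost, Jacobian or metric.

Full 21-parameter fits (17 rates + 4 pools) are supported but
ill-conditioned from a single trace; the tested surface uses masked
subsets, which is also how the recovery experiments are defined.
Group-mean fitting is supported by pointwise averaging of traces
linearly resampled to a common grid.

## Synthetic data

The generator stands in for flash-ERG recordings from small rodent
cohorts. It simulates a named fixture (default 1 kHz over [0, 0.3] s,
light on from t = 0), applies the polarity, then adds:

- an optional delayed positive "b-wave-like" contaminant — an alpha
  function A·(t′/τ)·exp(1 − t′/τ) with onset 0.05 s after the stimulus,
  rise time τ = 0.06 s, and amplitude 30% of the trough for `wild`
  versus 15% for the NOB groups (bipolar-cell suppression leaves less
  b-wave). The form and constants are phenomenological, chosen to give
  a plausibly-timed positive deflection that accelerates the
  post-trough rise; no bipolar-cell physiology is modelled.
- white Gaussian noise with SD expressed as a fraction of the trough
  amplitude (default 2% in the panels), emulating broadband instrument
  noise. No coloured-noise model is attempted.

Every trace returns with a ground-truth record (generating parameters,
noiseless model signal, contaminant signal, seed) and regenerating from
that record is bit-exact. `make_group_panel` mirrors the 3-animals ×
3-groups design with independent seeds derived from one base seed.

What passing recovery tests on these traces shows: the
simulate–window–LM loop is self-consistent, identifiable for the tested
parameter subsets, and robust to the stated noise level. What it does
not show: performance against real ERGs, whose residual structure
(drift, oscillatory potentials, correlated noise, cone intrusion,
amplitude calibration in µV) the generator does not emulate, and
identifiability of the full 21-parameter set.

## Problem sizes and numerical defaults

Recovery experiments fit 281 samples (1 kHz, [0, 0.28] s); single- and
two-parameter noiseless recoveries from 1.5×-perturbed starts land
within ~10⁻⁷% of the generating values in 4–5 LM iterations, and the
noisy benchmark uses 20 seeds at 2% noise (median k₁ᵤ error well under
5%). Long-horizon simulations run to 2–4 s at the same internal step.
Monte-Carlo checks (noise SD, averaging gain) use 30–100 replicates —
enough for the 15% assertion bands without burning time.

## Known limitations

- Well-mixed, deterministic: no disc-membrane diffusion, no
  single-photon stochasticity, no graded light intensities within a run.
- The Ca²⁺ efflux term does not saturate at zero calcium, so parameter
  sets with deep cGMP depletion (the drug-treated fixture) push Ca²⁺
  negative; the package reports rather than masks this.
- Amplitudes are in model units; the instrument gain is folded into
  k₁₇ and cannot be separated without calibration data.
- No confidence intervals on fitted rates; point estimates only.
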