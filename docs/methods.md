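# Methods

## Pharmacokinetic model

The extracellular-space (ECS) drug concentration obeys a reaction-diffusion
equation: Fickian diffusion with effective diffusivity D/TS² (tortuosity TS
accounts for the porous brain parenchyma), exchange with plasma through the
blood-brain barrier at rates k_po (in) and k_pi (out), both divided by the
ECS volume fraction α. Bulk flow and intracellular uptake are neglected.
Internally everything is expressed in minutes, centimetres and picomoles;
diffusivities quoted in SI are converted at preset-construction time, and
tissue density is taken as 1 g/cm³ so k_po (ml·g⁻¹·min⁻¹) acts as min⁻¹.

Drug presets (all positive, validated at construction):

| parameter | psilocybin | chlorpromazine | units |
|---|---|---|---|
| D (ECS) | 3.052e-10 | 2.9e-10 | m²/s (stored as cm²/min) |
| k_pi | 16.38e-3 | 16.65e-3 | 1/min |
| k_po | 1.4e-3 | 1.43e-3 | 1/min |
| TS | 1.6 | 1.6 | – |
| α | 0.2 | 0.2 | – |

With a uniform initial field and spatially uniform plasma forcing the
diffusion term vanishes identically, so the compartment ODE is the default
solver. Because the plasma profile contract is piecewise linear (zero
outside the sampled window), the linear ODE has a closed form on every
segment; `solve_compartment_ode(method="exact")` integrates segment by
segment and is exact to round-off at the sample points — grid refinement
does not change it. The `method="euler"` variant reproduces the forward
Euler time-stepping of the 3-D solver, which is the right reference when
checking ODE↔PDE consistency: the two then agree to round-off on uniform
fields, isolating any error in the spatial coupling. The explicit PDE
scheme enforces Δt ≤ Δx²·TS²/(6D) and zero-flux (reflecting) walls, chosen
because no physical boundary condition is prescribed and reflection
conserves mass not removed by k_pi (verified to 1e-9 relative under pure
diffusion).

The transfer-coefficient interpolation over reference tracers is linear in
molecular weight. Literature values for the reference compounds are user
input, never baked in; queries outside the covered molecular-weight range
raise unless extrapolation is explicitly requested.

## Perceptual geometry

Perceived visual space is quantified by its metric tensor g. Because
visual space is taken as isotropic, only the diagonal changes: in
spherical coordinates at the fixation point (r = 1, θ = 0),

Δg = diag(μ M g_rr_max/P, r² μ M g_θθ_max/P, r² cos²θ μ M g_ΦΦ_max/P),

with M ∈ [0, 1] the Hill-law modulation index of concentration, μ = +1
(hyperactivation) or −1 (hypoactivation), and P > 0 the personalised Weber
constant. The baseline metric is the identity and Δg combines additively —
the convention that makes the no-drug diagonal equal 1, matching how the
prism experiments are normalised at t = 0. Defaults P = 1 and
g_max = (1, 1, 1) mean the behavioural fits absorb overall scale into
(n, k). A perceived metric with a negative diagonal entry is rejected as
degenerate rather than silently clipped.

The rod-placement surface is the ellipsoid x = a cosα cosβ,
y = b cosα sinβ, z = a sinα (the printed parametrisation re-uses a for x
and z; it is implemented as stated). Its first fundamental form is coded
in closed form and verified against a finite-difference JᵀJ oracle at
1e-8; Gaussian curvature comes from the first and second fundamental
forms, with the sphere limit 1/R² checked to 1e-10. The parametrisation
is singular at cosα = 0, where curvature evaluation raises. Rotated-ellipse
fitting of rod positions delegates to the direct least-squares conic fit
in scikit-image, normalised to a ≥ b with the major-axis angle in
(−π/2, π/2] so the fit is identifiable; collinear or non-elliptical input
raises a fit failure. The equal-area prism inference uses the Riemannian
area element √(det g) with an equal-diagonal 2-D metric, so
g_diag = area_ref/area_obs exactly.

Numerics note: M(C) is evaluated as expit(−n·(log k − log C)), which is
stable for Hill coefficients as large as the chlorpromazine fit (n ≈ 50)
where a naive (k/C)^n overflows.

## Hill fitting

Fitting is an exhaustive grid search: default grids n ∈ [0.1, 100] step
0.1 and k spanning [max(1e-3, 0.01·max C), 2·max C] in 500 uniform steps,
which bracket both behavioural fits; tests and pipelines may pass tighter
grids that contain the truth values exactly. The SSE surface is returned
whole (it is the natural diagnostic plot), the argmin is taken in
row-major order so ties deterministically resolve to the smallest n, then
smallest k. Goodness of fit is Pearson's χ² with the model prediction as
expectation and dof = N_obs − 2 (two fitted parameters). Degenerate inputs
are flagged in the result rather than raised: identical observations mark
`flat_surface`, and a best fit whose modulation index stays ≈ 0 everywhere
marks `uninformative`.

## Synthetic data

The generator stands in for the behavioural studies: a Bateman
one-compartment oral-absorption plasma curve
C_a(t) = dose·ka/(ka−ke)·(e^(−ke·t) − e^(−ka·t)), metric observations from
the forward model plus seeded Gaussian noise, rod positions on a rotated
ellipse, and prism series constructed so the equal-area inference inverts
them exactly. Truth records are returned separately from the observation
tables and are never consumed by fitting code.

Dose and rate constants are chosen by experimental-design reasoning: the
observations must straddle the half-effect concentration for (n, k) to be
identifiable from a handful of time points. Psilocybin-like: ka = 0.03,
ke = 0.006 min⁻¹, dose scale 30, observations at 0/90/180/270 min, giving
brain concentrations 1.68/1.15/0.68 pmol/cm³ and modulation indices
0.94/0.06/0.00 on the two shoulders of k = 1.39. Chlorpromazine-like:
ka = 0.02, ke = 4e-4 min⁻¹ (elimination half-life ≈ 29 h, consistent with
chlorpromazine's slow clearance), dose scale 65, observations at
0/210/450 min giving M = 0.87/0.14 around k = 4.96 — both points inside
the narrow transition band of the very steep (n ≈ 50) law, without which
that coefficient is unrecoverable. Because the brain concentration peaks
near 85 min, the psilocybin metric rises to its 90-min observation and
falls thereafter; the generator reflects that, and recovery does not
depend on monotone concentrations. Default observation noise is 0.01
metric units.

What passing recovery tests show — and do not show: they demonstrate the
estimator is consistent and well-conditioned *under the generator's
assumptions* (additive i.i.d. Gaussian noise, correct pharmacokinetics, a
single Weber constant, no inter-subject variability). Real behavioural
data add model mismatch that these tests do not probe.

## Grid-cell network

Ninety nodes occupy a 9 × 10 row-major lattice on a flat torus with
circumferences 0.5 and 0.61; distances wrap per axis into [−c/2, c/2]
after adding the eye-movement offset E(t), so node (minor m, major j) is
index 10m + j (node 47 = minor 4, major 7). Weights are
W = (I + ΔI)·exp(−d²/s²) − T with s = 0.24 and T = 0.05; activities update
by the normalised rule with stabilisation λ = 0.8 at dt = 0.01 s for 4 s
from a seeded uniform [0, 1/90] start.

Two design choices required resolving under-determined parts of the model,
and both are load-bearing:

* **Baseline interaction strength I.** The Gaussian kernel's row sum over
  this lattice is ≈ 42.5, so the update's per-step gain at I = 1 would be
  (1−λ)(I·42.5 − T·90) ≈ 7.6 and activities overflow within the 4-s run; I
  must be far smaller than 1. Linear analysis of the update places the
  patterned (bump) attractor in I + ΔI < T·N/(Ĝ₀−Ĝ₁) ≈ 0.149, and
  simulation shows the bump fails to form from the random start below
  I ≈ 0.10. The default I = 0.11 is the smallest value robust across
  seeds. It is configurable, and the fitted half-effect of the sweep is
  essentially 0.149 − I, so this choice directly sets the fitted k.
* **Rectification.** The literal update drives the summed activity
  negative during inhibition-dominant transients (T·N = 4.5 exceeds the
  excitatory row sum at small I + ΔI), after which the 1/ΣP normalisation
  is undefined. `step_network` keeps the literal algebra for unit-level
  verification; `simulate` clips negative activities to zero after each
  step by default (`NetworkConfig.rectify=False` restores the literal
  rule). Because the update is positively homogeneous, clipping commutes
  with overall rescaling, which also justifies renormalising the raster
  when values pass 1e100 (flagged, pattern unchanged).

Eye movement enters as a displacement inside the weight norm: fixation
E = 0 (weights constant, a static bump — the attractor property), constant
mode adds the velocity (default (0.01, 0.01) torus units/step, giving ≈ 3
activation periods in 4 s as the bump circles the torus in ~63 steps), and
random mode draws seeded Gaussian per-step velocities (sd 0.005). The drug
increment ΔI is spatially uniform — with only 90 nodes the local
concentration is effectively common — and may follow a (time, ΔI) schedule
derived from the pharmacokinetic solver for coupled runs.

**Period measurement.** L is defined in time steps (the reproducible
analogue of measuring stripe spacing on a raster image). The raster after
a 1-s transient is split into a per-step-normalised *pattern* and a common
*envelope*; node periods are the first positive-lag maximum of a per-lag
Pearson autocorrelation (unbiased by window length) above 0.2, with L the
median over nodes. A static pattern with a flat or monotonically growing
envelope means continuous activation: zero distance between activations,
L = 0 and AI = 1. A static pattern with an oscillating envelope takes L
from the envelope; no detectable peak anywhere returns an aperiodic
marker, not an exception. L_max is the per-seed baseline L(ΔI = 0).

**Known limitation — the shape of AI(ΔI).** Within this update rule the
activity direction evolves by power iteration on a circulant matrix (the
normalisation term only contributes a scalar), so the travelling pattern's
temporal period is locked to the phase of the dominant Fourier mode and
cannot vary continuously with ΔI. What ΔI does control is which mode
dominates: past I + ΔI ≈ 0.149 the uniform mode wins and the nodes become
continuously active. The measured AI(ΔI) is therefore a sharp saturating
step at ΔI ≈ 0.149 − I rather than a shallow sigmoid: at the defaults the
five-seed sweep fits n ≈ 69, k ≈ 0.042 with R² ≈ 0.9998 (recomputed by
`scripts/acceptance.py`, not stored). Alternative readings — cumulative
eye offsets, no rectification, rescaled or 3-D-embedded torus geometries —
were explored and either diverge, lock the period identically, or destroy
the attractor; a smooth, shallow Hill dependence of the period on ΔI is
not attainable in this model family, and any published value of that shape
must depend on implementation details beyond the stated equations.

## Pipelines

`run_behavioral_pipeline` chains generation → pharmacokinetics → grid fit
→ χ² (optionally predicting the metric at held-out times); outputs are CSV
plus a JSON report containing the config snapshot, file paths, fitted
parameters and seeds, and the synthetic truth is written to its own
clearly-named file. `run_grid_pipeline` runs the ΔI sweep with per-seed
fits and a median-AI aggregate fit; requesting a fixation sweep is a
pipeline error because periodicity requires movement, and an aperiodic
baseline aborts with advice to adjust the eye velocity. Identical configs
and seeds reproduce byte-identical CSVs.
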