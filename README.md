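# percspace

Quantitative modelling of how neuromodulating drugs alter visual-spatial
perception, for computational neuroscientists and pharmacologists who want a
testable, end-to-end pipeline from an oral dose to a perceptual read-out.

Sympathetic ("fight-or-flight") hyperactivation and parasympathetic
("rest-and-digest") hypoactivation — induced here pharmacologically by
psilocybin and chlorpromazine — change the geometry of perceived visual
space. The package models the chain quantitatively:

1. **Brain pharmacokinetics.** The brain is a porous medium; the drug
   concentration C(x, t) in the extracellular space (ECS) obeys

   ```
   ∂C/∂t = (D/TS²) ∇²C − (k_pi C − k_po C_a(t)) / α
   ```

   with plasma concentration C_a(t), tortuosity TS, ECS volume fraction α
   and blood↔brain transfer coefficients k_po, k_pi. A spatially uniform
   state reduces this to a one-compartment ODE (the default solver, exact
   per piecewise-linear plasma segment); an explicit 3-D finite-difference
   solver with zero-flux walls is provided as a verification mode.

2. **Perceptual modulation.** A modulation index
   `M(C) = 1 / (1 + (k/C)^n)` (a Hill law with coefficient n and
   half-effect concentration k) scales a diagonal change Δg of the
   perceived-space metric tensor, signed by the arousal coefficient
   μ = ±1 and scaled by a personalised Weber constant P. Behavioural
   observables — rotated-ellipse rod placements, the induced ellipsoid
   surface metric and Gaussian curvature, and equal-area prism-power
   thresholds — connect Δg to experiment.

3. **Hill fitting.** (n, k) are recovered from metric observations by
   exhaustive grid-search least squares, with the SSE surface exposed and a
   Pearson χ² goodness-of-fit test.

4. **Grid-cell network.** A 90-node continuous-attractor network on a
   torus (circumferences 0.5/0.61, Gaussian weight width s = 0.24,
   inhibition T = 0.05, stabilisation λ = 0.8) path-integrates eye
   movements. A uniform interaction increment ΔI models the drug; the
   distance L between periodic node activations yields an activity index
   AI = 1 − L/L_max whose dependence on ΔI is again fitted with a Hill law.

All inputs are synthesised by the `percspace.synthetic` module from known
ground truth, so every stage is testable offline and parameter recovery can
be audited.

## Worked example

```python
import numpy as np
from percspace import grid_search_fit
from percspace.synthetic import psilocybin_like, synth_metric_observations

spec, pk = psilocybin_like(noise_sd=0.01, seed=1)
table, truth = synth_metric_observations(spec, pk)
result = grid_search_fit(
    (table["time_min"].to_numpy(), table["g_rr"].to_numpy()),
    truth["concentration_series"], spec.mod_truth,
    n_grid=np.round(np.arange(1.0, 50.01, 0.1), 10),
    k_grid=np.round(np.arange(0.1, 5.001, 0.01), 10))
print(result.best, result.chi2_p)
```

prints (see `examples/02_behavioral_hill_fit.py` for the full script)

```
fit   : n = 14.6, k = 1.41 pmol/cm^3
chi2 = 3.35e-05, p = 1.0000 (dof 2)
```

The fitted Hill coefficient and half-effect concentration recover the
generating truth (n = 14.8, k = 1.39) to within the noise, and the χ²
p-value near 1 confirms that the Hill model reproduces the observed metric
time course. The other scripts in `examples/` walk through the
pharmacokinetics, the perceived-space geometry, the grid-cell sweep and the
end-to-end pipelines, each printing the numbers it computes and one line on
what they mean.

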