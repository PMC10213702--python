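"""Drug modulation of the toroidal grid-cell attractor network.

Simulates the 90-node continuous-attractor network under constant eye
movement for a sweep of the interaction increment dI, measures the
periodic-activation distance L, forms the activity index AI = 1 - L/L_max,
and fits AI(dI) with a Hill law.
"""

import numpy as np

from percspace.gridcells import fit_activity_hill, sweep_activity_index

delta_is = np.round(np.arange(0.0, 0.301, 0.02), 10)
frame = sweep_activity_index(delta_is, seeds=[1, 2, 3])

print("median over seeds:")
med = frame.groupby("delta_I")[["L_steps", "AI"]].median()
for di, row in med.iterrows():
    print(f"  dI = {di:4.2f}   L = {row.L_steps:5.1f} steps   AI = {row.AI:.3f}")

sub = frame[frame.delta_I > 0].dropna()
fit = fit_activity_hill(sub.delta_I.to_numpy(), sub.AI.to_numpy())
print(f"\nHill fit of AI(dI): n = {fit.best.n:.2f}, k = {fit.best.k:.3f}, "
      f"R^2 = {fit.r_squared:.4f}")
print()
print("At dI = 0 the activity bump circles the torus once per ~63 steps;")
print("above the patterned-to-uniform transition (dI ~ 0.045 at the default")
print("baseline interaction) the nodes become continuously active (L = 0,")
print("AI = 1).  The Hill fit summarises how sharply that changeover occurs.")
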