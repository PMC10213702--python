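"""Run both end-to-end pipelines and print their reports.

The behavioural pipeline: synthetic observations -> pharmacokinetics ->
Hill fit -> chi-square.  The grid pipeline: dI sweep -> activity index ->
Hill fit, per seed and aggregated.
"""

import json
import tempfile
from pathlib import Path

from percspace.pipeline import run_behavioral_pipeline, run_grid_pipeline

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp)
    behav = run_behavioral_pipeline(
        {"synthetic": {"preset": "psilocybin", "seed": 1, "noise_sd": 0.01},
         "fit": {"n_grid": {"start": 1.0, "stop": 50.0, "step": 0.1},
                 "k_grid": {"start": 0.1, "stop": 5.0, "step": 0.01}}},
        out / "behavioral")
    print("behavioural pipeline:")
    print(json.dumps(behav.results, indent=2, default=float))

    grid = run_grid_pipeline(
        {"network": {"delta_i_max": 0.30, "delta_i_step": 0.02, "seeds": [1, 2, 3]}},
        out / "grid")
    print("\ngrid pipeline:")
    print(json.dumps(grid.results, indent=2, default=float))
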