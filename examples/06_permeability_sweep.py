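"""A miniature permeability sweep: DEI vs membrane permeability.

Runs the full simulate -> synthesize -> invert -> segment -> DEI chain at
three membrane transit probabilities and reports the Spearman rank
correlation of DEI against the implied permeability.  Walker counts are cut
hard for speed (~1 min); the larger sweeps in scripts/acceptance.py use the
study's probability range with six points.
"""

import numpy as np

from dexsy.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    substrate={"kind": "spheres"},
    probabilities=[1e-4, 2.8e-4, 5.5e-4],
    n_walkers=3000, duration=0.17, n_steps=6800,
    seed=11, run_fexsy=False,
)
res = run_pipeline(cfg)
print(res.summary.to_string(index=False))
print(f"Spearman rho of DEI vs permeability: {res.dei_rho}")
print("(each row: transit probability, the permeability it implies, and "
      "the DEI measured from the inverted spectrum)")
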