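"""Write a full synthetic dataset to disk: SWC skeletons, clone records,
ground truth and brain model.

The on-disk layout is what the command-line interface consumes
(``hemimorph prune/nblast/topology/heatmap/stats``), so this doubles as the
entry point for exercising the shell workflow.
"""

import tempfile
from pathlib import Path

from hemimorph import demo_scenario, write_scenario

out = Path(tempfile.mkdtemp(prefix="hemimorph_sim_"))
scenario = demo_scenario(seed=7)
write_scenario(scenario, out, n_brains=500)

swcs = sorted((out / "swc").glob("*.swc"))
print(f"wrote {len(swcs)} SWC skeletons, clones.csv, ground_truth.json, brain.json")
print(f"under {out}")
print("first few skeleton files:", [p.name for p in swcs[:4]])
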