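"""Simulate one 96-well plate and run the whole pipeline in one call.

Generates WormToolbox-style per-object CSVs (soft-matched model rows,
clusters, edge animals, debris), then runs read -> model selection ->
edge/outlier flagging -> prune -> summarize via the `xpress` wrapper.
"""

import tempfile
from pathlib import Path

from wormwell import SimulationConfig, generate_plate_set, xpress

workdir = Path(tempfile.mkdtemp(prefix="wormwell_"))
config = SimulationConfig(plates=1, wells_per_plate=96)  # 30 animals/well default
generate_plate_set(config, seed=42, outdir=workdir)

bundle = xpress(workdir / "objects.csv", design_path=workdir / "design.csv")

print(f"raw objects:       {len(bundle.raw_data)}")
print(f"processed objects: {len(bundle.processed_data)}")
print(f"wells summarized:  {len(bundle.summarized_processed)}")
print()
print(bundle.summarized_processed[["Metadata_Well", "n", "mean_length", "q50"]].head())
# Each summarized row is one well: n animals kept after pruning, with the
# mean and median body length in micrometres. Raw minus processed counts
# are the cluster/edge/outlier objects the QC flags removed.
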