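"""Render the plate heatmap and an annotated single-well view.

The plate view is written both as a static PNG and as a self-contained
interactive HTML file (hover a well for its id, object count and mean
length). The well view draws every object at its centroid, colored by
class, with the 825 px even-illumination radius in red.
"""

import tempfile
from pathlib import Path

from wormwell import SimulationConfig, generate_plate_set, xpress, view_plate, view_well

workdir = Path(tempfile.mkdtemp(prefix="wormwell_"))
generate_plate_set(SimulationConfig(plates=1), seed=7, outdir=workdir)
bundle = xpress(workdir / "objects.csv")

plate_fig = view_plate(bundle.summarized_processed, "p01")
plate_fig.to_html(workdir / "plate.html")
plate_fig.to_png(workdir / "plate.png")

well = bundle.raw_data["Metadata_Well"].iloc[0]
fig = view_well(bundle.raw_data, "p01", well)  # raw: flagged objects still visible
fig.savefig(workdir / f"well_{well}.png", dpi=150)

print("wrote:", *sorted(p.name for p in workdir.glob("*.png")), "plate.html")
print(f"well {well}: {int((bundle.raw_data['Metadata_Well'] == well).sum())} objects plotted")
# Cool (short) wells on the heatmap are L1-synchronized, warm ones Adult;
# flagged markers in the well view show what pruning will remove.
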