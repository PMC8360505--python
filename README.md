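# wormwell

Post-processing, quality control and visualization of per-object data from
high-throughput *C. elegans* imaging in 96-well plates.

CellProfiler's WormToolbox detects animals in brightfield well images and
measures them with several user-calibrated worm shape models (e.g. `L1`,
`L2L3`, `L4`, `Adult`, matching the sizes of the larval stages and adults).
Running multiple models is deliberate — "soft matching" keeps differently
sized animals detectable across strains and conditions — but it leaves a
one-to-many relationship between real animals and measurement rows, plus
the usual plate pathologies: overlapping animals, degraded segmentation
near the well rim, and debris. `wormwell` turns that raw export into
per-well phenotype summaries you can trust:

1. **Read** per-object CSV exports (and an optional plate-design table
   mapping wells to strain/drug/dose) into one validated table.
2. **Model selection** — models are ranked by dataset frequency (the
   smallest model is fitted most often, the largest least often); per
   animal, the largest-ranked model present is selected, and a repeated
   best fit raises a **cluster flag**. One row per animal comes out.
3. **Flagging** — a **well-edge flag** for centroids beyond the radius of
   even illumination (default 825 px from the image center), and an
   **outlier flag** from Tukey's fences `[Q1 − k·IQR, Q3 + k·IQR]`
   (default k = 1.5) computed per well over the not-already-flagged
   lengths.
4. **Prune and summarize** — flagged rows are dropped (configurably) and
   body length is summarized per well (or any design grouping): n, mean,
   sample variance, min/max, 10/25/50/75/90% quantiles. Results travel as
   a four-element bundle: raw table, processed table, and summaries of
   both.
5. **Visualize** — interactive plate heatmap (self-contained HTML), an
   annotated single-well view with the edge radius drawn in red and an
   optional length boxplot, and per-dose representative-well panels.

A synthetic plate generator emulates the WormToolbox output schema — soft
matching, clusters, edge animals, debris — with ground truth, so the whole
pipeline is testable and benchmarkable without any images.

## Worked example

```python
from wormwell import SimulationConfig, generate_plate_set, xpress

config = SimulationConfig(plates=1, wells_per_plate=96)   # 30 animals/well
generate_plate_set(config, seed=42, outdir="demo")
bundle = xpress("demo/objects.csv", design_path="demo/design.csv")
print(len(bundle.raw_data), len(bundle.processed_data))
print(bundle.summarized_processed[["Metadata_Well", "n", "mean_length", "q50"]].head())
```

prints

```
3184 2430
  Metadata_Well   n  mean_length         q50
0           A01  26   997.329503  989.335906
1           A02  26   708.640919  710.106783
2           A03  24   702.419494  698.727553
3           A04  22   995.167772  986.749525
4           A05  25   246.913486  249.331333
```

3184 model-selected objects enter QC; 2430 survive pruning of cluster,
edge and outlier flags. Each summary row is one well: `n` animals kept,
with mean and median body length in micrometres (wells are synchronized to
one stage, so A01/A04 are adult wells, A05 an L1 well). The same workflow
is available from the shell:

```sh
wormwell simulate --plates 1 --seed 42 --out demo/
wormwell process --data demo/objects.csv --design demo/design.csv --out run/
wormwell view-plate --summary run/summary_processed.csv --plate p01 --out plate.html
```

The `examples/` directory holds one short script per capability
(simulation, model selection, plate/well views, dose response, truth
scoring).

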