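# Methods

## The problem and the model of the data

WormToolbox per-object exports have one row per *model object*: one fit of
a calibrated worm shape model to a *primary object* (a detected animal).
Because several models of different sizes are run over the same image, a
single animal typically yields several rows — its own stage's model plus
partial fits of smaller models along its body — and two animals lying
across each other can make the same model fit twice. `wormwell` treats the
export as a relation `(plate, well, primary_object_id, model_name) → 
(centroid, length)` and reduces it to one measurement per animal with
explicit quality flags, rather than trying to re-segment anything.

## Model selection

Models are ranked by frequency over the **whole dataset** (all files read
together), descending; rank 1 is the most frequent model. The empirical
justification: a small model is repeatedly assigned along every larger
animal, so dataset frequency decreases with model size. Exact frequency
ties are broken by ascending mean `worm_length` per model — length is the
direct size measure for which frequency is only a proxy. Per animal, the
largest-ranked model present is selected; if it occurs more than once in
the group, the animal gets `cluster_flag = True`.

The row kept for a cluster is the selected model's instance with maximal
length (first occurrence on a tie). The choice only affects raw-data
views: cluster measurements are unreliable and pruned by default. 

## Flags

**Well edge.** `well_edge_flag = dist(centroid, center) > radius`, radius
default **825 px**, the radius of even illumination for a 2× objective on
a 2048 px camera. The center comes from an explicit `center` or from
`image_shape / 2`; with neither, the config raises rather than guessing —
except in the `xpress` wrapper and the CLI, which default to a
2048 × 2048 px geometry (the synthetic generator's and a common camera's)
so that an all-defaults run is possible. The comparison is strict:
boundary points are unflagged, on the principle that a flag marks
deviation *beyond* a threshold. The same strictness applies to the fences
below.

**Outliers.** Per well, Tukey's fences `[Q1 − k·IQR, Q3 + k·IQR]` with
k = 1.5 by default (the classical inner-fence multiplier). Quartiles are
linearly interpolated order statistics at position `(n − 1)·p` — numpy's
default and the convention this package standardizes on everywhere
(fences and summary quantiles alike), documented because fence positions
depend on it. Fences are computed over the well's rows not already
carrying an excluded flag (default: clusters and edge objects are
excluded, so corrupted lengths cannot drag the fences), and only those
eligible rows can be outlier-flagged. Wells with fewer than `min_n = 3`
eligible rows are left unflagged: quartiles of one or two points over-flag
wildly. Both the exclusion set and `min_n` are configurable.

## Pruning and summaries

`prune` drops rows carrying any of the requested flag families (default:
all three); retained-by-choice flags simply stay in the processed data.
Summaries report n, mean, **sample variance** (ddof = 1, missing for
n = 1), min/max and the {10, 25, 50, 75, 90}% quantiles of `worm_length`
per group — per `(plate, well)` by default, or any design columns. The
quantile set is this package's choice; additional measurement columns can
be summarized identically via `extra_measurements`. Wells whose objects
are all pruned vanish from the processed summary; the plate view renders
them as empty cells.

## Synthetic wells

The generator writes the same CSV dialect the reader consumes, with
filenames on the `{date}-{experiment}-{plate}-{magnification}_{well}.TIF`
grammar. Default conditions: 96 wells/plate, **30 animals per well**
(typical titer for this assay), 10% edge animals, 5% clusters, debris rate
0.1 per animal, measurement noise 2% CV. Wells are **bleach-synchronized**:
each well holds one nominal developmental stage, drawn from
`stage_mixture` (default uniform over L1/L2L3/L4/Adult). This mirrors the
real protocol and is what makes per-well fences meaningful — a
deliberately mixed-stage well would span 250–1000 µm and hide debris
inside its IQR. Per-stage true lengths are normal draws with defaults
L1 ~ N(250, 25), L2L3 ~ N(450, 50), L4 ~ N(700, 60), Adult ~ N(1000, 80) µm
— plausible body lengths chosen as this package's own fixtures, fully
configurable.

Construction of each animal: 1–3 partial fits per smaller model with
lengths drawn as fractions of the true length (scaled by relative model
size), then the stage's own model once — or 2–3 times with 0.5–0.9×
distorted lengths for cluster animals. Edge animals are placed strictly
beyond the illumination radius and get an extra 0.5–1.5× multiplicative
length error (degraded rim segmentation). Debris is a single short fit of
the smallest model (N(80, 20) µm), placed inside the radius, and carries
the constructed `is_outlier` truth label. With a dose design
(`doses_um`), true lengths shrink by a simple Emax curve
(EC50 250 µM, max 50% inhibition).

One RNG stream per plate is spawned from the master seed
(`SeedSequence.spawn`), so a fixed seed gives byte-identical CSVs and
plate-parallel generation would stay reproducible.

**What the simulator does not emulate:** optical realism (the optional
TIFFs are schematic strokes with radial vignetting), segmentation failure
modes other than the three constructed artifact classes, plate-position or
batch effects, and stage mixtures *within* a well. Passing the recovery
benchmark therefore shows the post-processing logic is correct under its
own assumptions, not that any particular real dataset is clean.

## Evaluation

`evaluate_against_truth` joins pipeline output to the truth table
(bijective on plate/well/primary-object keys, enforced) and reports
precision/recall per flag family (defined as 1.0 when there are no
positives to score), per-well absolute/relative error of the processed and
raw mean length against the true animal mean, and model-selection accuracy
on truth-unflagged animals. Under default conditions the cluster and edge
flags are exact by construction; the outlier flag trades a few false
positives (≈0.7% of normally distributed lengths fall outside k = 1.5
fences) for near-complete debris recall.

## Visualization choices

The plate view exports PNG via matplotlib and a self-contained SVG/HTML
file with browser-native hover tooltips; all numbers are embedded, no
external scripts. 16-bit well images are contrast-stretched to their
1st–99th intensity percentiles for display (raw 16-bit brightfield renders
near-black). Without an image, the well view draws markers on a blank
circle of the configured radius so the function works data-only. Markers
sit exactly at centroid coordinates, no jitter. The representative well of
a dose is the well whose mean length is the (lower) median of that dose's
well means — deterministic and always an existing well.

## Problem sizes

The test suite exercises single plates of 8–24 wells for unit/property
tests and the full 4 × 96-well benchmark (≈12,600 primary objects,
≈45,000 model rows) for recovery checks; the whole suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

- Frequency ranking assumes the smallest model really is fitted most
  often; a dataset dominated by one stage with no soft matching could
  invert a pair of ranks. The tie-break on mean length mitigates but does
  not eliminate this.
- Tukey fences assume within-well homogeneity; a genuinely bimodal well
  (e.g. failed synchronization) will have its minority mode flagged.
- The reader accepts long-format model columns or wide
  `Worm_Length_<Model>` columns; other vendor dialects need an explicit
  `column_map`.
- R-serialized archives from cluster runs are not read; export to CSV
  upstream.
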