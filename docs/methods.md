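# Methods

## Problem setting

A digitized herbarium sheet shows a pressed plant specimen; its
reproductive structures (buds, flowers, fruits) indicate its phenophase.
Annotation platforms collect one dot marker per visible structure, placed
roughly at its centre, from experts and/or crowd-sourcers. The package
turns such dot-marker tables into (a) surrogate instance-segmentation
training data for a detector and (b) per-specimen count vectors
c_{i,k}, k ∈ {bud, flower, fruit}, against which detector counts
ĉ_{i,k} are evaluated.

## Dodecagon surrogate masks

Region-proposal instance-segmentation models need a full mask per object,
which dot markers do not provide. Since the organs of the target taxa
(spring herbs in *Anemone* and *Trillium*, and similar approximately
circular structures) press into near-circular shapes, each dot is expanded
into a regular dodecagon inscribed in the organ's typical enclosing
circle:

* **Radius calibration.** For each (genus, organ), the radius is the
  arithmetic mean of the enclosing-circle radii of a few manually
  segmented structures; five samples per pair is the recommended effort,
  and entries backed by fewer are flagged. Radii are stored in
  resized-image pixels; measurements taken on original images must be
  multiplied by the specimen's resize scale first. A missing (genus,
  organ) entry is an error by default; an organ-level mean fallback can be
  enabled explicitly.
* **Geometry.** Vertex k of the dodecagon sits at angle 30k° from east,
  counter-clockwise — a pure convention, since all downstream metrics are
  rotation-invariant. The polygon's area is exactly 3r²
  ((n/2)·r²·sin(2π/n) at n = 12), which anchors the rasterization checks.
  An inscribed dodecagon covers 3/π ≈ 95.5% of its circle, so a
  calibrated mask covers ≥ 90% of a circular organ.
* **Rasterization.** A pixel belongs to a mask iff its centre lies inside
  the polygon, on the half-open grid [0, W) × [0, H); masks are clipped to
  image bounds by polygon–rectangle intersection, never wrapped. Masks are
  also encoded as polygons and as uncompressed column-major run-length
  encodings, both lossless against the raster.
* **Resizing.** Detector inputs use an aspect-preserving fit:
  s = min(1024/long edge, 600/short edge), target = round(s × source).
  The "long edge toward 1024, short edge toward 600" rule is applied as a
  fit-within (including upscaling of smaller sheets) rather than a fixed
  non-square resize, because a non-uniform resize would distort the
  circular organs that radius calibration assumes. Dot coordinates are
  0-based pixels in the original image and are transformed (scaled, then
  clamped) to resized space with the same plan.
* **Anchors.** Region-proposal anchor sizes form a geometric ladder (ratio
  2) from 2·r_min·cos 15° (the smallest dodecagon's bounding-box side) to
  at least 2·r_max, guaranteeing every mask fits inside some anchor;
  aspect ratios default to {0.5, 1, 2}.
* **Export.** One COCO-dialect annotation per dot (categories bud=1,
  flower=2, fruit=3; polygon segmentation, tight bbox, rasterized area,
  iscrowd=0); exported annotation counts equal input dot counts.

## Counting by detection

The predicted count is the number of detector instances per organ, with
no non-maximum suppression or spatial deduplication beyond what the
backend provides — double detections over-count and merged components
under-count by design, since those error modes are precisely what the
evaluation framework characterizes. Detections carry a confidence score
in [0, 1]; the default operating threshold is τ = 0.5, chosen as the
conventional midpoint (no published value dictates it).

Any backend implementing `detect(image, specimen_id) -> [Detection]` with
a configuration digest can be evaluated. The bundled baseline is a
deterministic colour/size detector for palette-separable images (such as
the synthetic sheets): pixels are assigned to the nearest reference
colour within a Euclidean RGB tolerance (default 40), 8-connected
components become candidate instances, each classified to its majority
colour class with score = the majority fraction, and components below 12
px (or outside optional per-organ equivalent-radius bounds) are
discarded. "Training" the baseline means fitting one reference colour per
(species, organ) present in the training split — several reference
colours per organ when training spans species with different appearance —
which gives the train/test discipline of a learned detector at CPU speed.
Full-scale CNN training is out of scope here; the backend contract is the
integration point.

## Evaluation framework

* Counting error e_{i,k} = ĉ_{i,k} − c_{i,k} (positive = over-count).
* MAE: per organ, mean |e| over specimens. The overall ("All") MAE
  reported in comparison tables is the **unweighted mean of the three
  per-organ MAEs** — this is the aggregation that published comparison
  tables use (e.g. (0.201 + 0.507 + 0.266)/3 = 0.325). A literal
  per-specimen normalisation (summing the three organ errors of each
  specimen before averaging, exactly 3× the table value on complete data)
  is available as `variant="literal"`.
* R² = 1 − SS_res/SS_tot with c̄ the mean of observed counts on the
  evaluated subset; may be negative; pooled "all" uses (specimen, organ)
  observations. Constant truth (SS_tot = 0) yields an explicit undefined
  marker (`None`), never ±∞.
* Letter values: depth d₁ = (1+n)/2 gives the median, d_{i+1} =
  (1+⌊d_i⌋)/2 the fourths, eighths, …, each level reporting the lower and
  upper order statistics at its depth (half-integer depths average
  adjacent order statistics). The stop rule is configurable: a fixed
  number of levels, descent to depth 1, or the ⌊log₂ n⌋ − 3 heuristic
  (default). The median always equals the classical median.
* Predicted-count distributions: per observed true-count value, the
  median, quartiles, 1.5·IQR whiskers and outliers of the predictions;
  empty bins are omitted.
* Presence/dominance: presence is count ≥ 1; dominance columns are
  flowers ≥ buds and fruits ≥ flowers, ties (including 0 = 0) satisfying
  "≥" per the column definition. TP/FN rates are percentages of observed
  positives, TN/FP of observed negatives; overall accuracy is the
  prevalence-weighted mean of the TP and TN rates. Columns with an empty
  denominator report NaN rates and fall back to the defined rate for
  accuracy. `reconstruct_presence_column` additionally recovers the
  integer confusion counts behind rounded published rates (counts of
  specimens are integers), which removes the ~0.01 drift that rounded
  percentages introduce into the weighted identity. One published
  dominance column (fruits ≥ flowers) is internally inconsistent
  (its FP and TN rates do not complement to 100, and the weighted
  identity misses the printed accuracy by a wide margin); it is flagged
  here and not used as a reference value.

## Crowd aggregation and source comparison

Each crowd-scored specimen has counts from one or more annotators.
*Isolated* aggregation keeps a single annotator per specimen, chosen by a
seeded hash of (seed, specimen id) so the choice is reproducible and
independent of row order. *Average* aggregation takes the per-organ
arithmetic mean and keeps it fractional — rounding would discard the
variance reduction that makes averaging competitive. Sources are compared
on paired per-specimen absolute errors (summed over organs) with a
two-sided Wilcoxon signed-rank test (exact null for n ≤ 25 without ties,
normal approximation otherwise); counting errors are integer-valued and
heavy-tailed, so a rank test is preferred over a paired t-test. Identical
error vectors are reported as a degenerate comparison with p = 1.

## Scenario harness

`per_species` (train = test = one species), `global` (all species), and
`transfer` (test species disjoint from training, asserted on specimen
ids). For the first two, a seeded 20% specimen-level holdout is
evaluated; for transfer, every specimen of the test species is evaluated
and none enters training. Reports (MAE, R², error letter values,
presence/dominance) are JSON-serialized with a content digest of the
configuration; identical (config, data) produce byte-identical reports.

## Synthetic sheets

The generator renders a beige sheet with green stem/leaf clutter and
organ blobs: flowers are light five-lobed blobs (largest), fruits
mid-sized dark-brown disks, buds small dark ellipses — sizes and colour
distinctiveness ordered so that detectability tracks organ size, as it
does on real sheets. Counts per organ are zero-inflated: present with
probability p, and zero-truncated Poisson given presence. Defaults
emulate real crowd-scored *Anemone*/*Trillium* collections: presence
probabilities 9.75% (buds), 82.92% (flowers), 20.00% (fruits), with
conditional means solved numerically so the marginal expectations are
0.160 / 1.991 / 0.422 structures per sheet — organ composition
6.2 / 77.4 / 16.4% and ~2.57 structures per sheet in total. Sheets are
400 × 600 px (organ radii ~6/16/11 px mean), small enough to keep the
end-to-end suites fast while leaving organs well above the detector's
minimum area. Placement keeps enclosing circles disjoint unless overlap
is explicitly allowed; a sheet too small for its draw raises a placement
error. Dot markers are the centroids of the rendered masks. Everything is
deterministic given the seed.

What the generator does **not** emulate: pressing artifacts, lighting and
scanner variation, colour charts, labels and handwriting, touching or
occluded organs, within-species appearance variation. Perfect pipeline
scores on these images therefore validate the machinery (mask generation,
detection plumbing, counting, statistics) — they say nothing about
detector accuracy on real specimens, which is limited by exactly the
factors the generator omits.

## Problem sizes and numerical conventions

The end-to-end oracle uses 60 noiseless sheets; the transfer experiment
uses 40 sheets of two same-genus species whose palettes differ by a +70
RGB shift — far enough that a detector fitted on one species misses most
organs of the other, reproducing the direction of the cross-species
degradation (in-species R² near 1, transfer R² clearly lower). These
sizes make every statistic stable across seeds while keeping a full run
under a couple of minutes on one CPU. Dataset splits are seeded uniform
shuffles with a round-half-up test-set size at specimen level; at the
published corpus scale (3073 specimens, test fraction 615/3073) this
reproduces the published 615-specimen test set. (The published train +
test sizes, 2457 + 615 = 3072, disagree with the stated 3073 total by
one specimen; the discrepancy is documented, not resolvable from the
published numbers.) Percentages in composition tables are rounded to one
decimal and sum to 100 ± 0.1; undefined quantities (empty groups,
constant truth) are explicit markers, never silent NaNs or infinities.
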