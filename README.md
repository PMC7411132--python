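# phenocount

Locate and count reproductive structures — buds, flowers, and fruits — on
digitized herbarium sheets, and evaluate how well a detector counts them.

Herbaria hold hundreds of millions of pressed plant specimens whose
phenological state (budding, flowering, fruiting) is a key trait for
studying plant responses to climate. Scoring that state by hand does not
scale, so a practical pipeline works in two phases: annotators (experts or
crowd-sourcers) place one **dot marker** at the centre of each visible
reproductive structure, and a detection model trained from those markers
counts structures automatically on the remaining sheets. `phenocount`
implements everything around the detector that makes this pipeline work:

* **Weak-label mask generation.** A dot marker gives position but no
  extent. Because the organs of interest are approximately circular when
  pressed, each dot is expanded into a regular 12-gon (dodecagon) inscribed
  in the organ's typical enclosing circle, calibrated per (genus, organ)
  from a handful of manually segmented examples. Masks are produced in a
  resized image space (long edge ≤ 1024 px, short edge ≤ 600 px, aspect
  preserved) and exported as a COCO-dialect instance-segmentation dataset
  (categories bud=1, flower=2, fruit=3), ready for any region-proposal
  detector; anchor scales are derived so every dodecagon is fully covered.
* **Counting by detection.** The predicted count ĉ_{i,k} of organ k on
  specimen i is the number of detected instances of k. No spatial
  deduplication is applied, so a structure detected twice is counted twice
  — the characteristic failure modes of this approach are part of what the
  evaluation measures.
* **Evaluation framework.** Counting error e_{i,k} = ĉ_{i,k} − c_{i,k};
  per-organ and overall MAE = mean |e|; coefficient of determination
  R² = 1 − Σ(c−ĉ)²/Σ(c−c̄)² (can be negative); letter-value summaries
  (median, fourths, eighths, … — successive half-sample quantiles) for
  heavy-tailed error distributions; composition tables; presence accuracy
  (is each organ present?) and dominance accuracy (flowers ≥ buds,
  fruits ≥ flowers), scored as prevalence-weighted TP/TN rates.
* **Crowd aggregation.** Per-specimen counts from several crowd-sourcers,
  aggregated as an isolated (single seeded) annotator or as a fractional
  per-organ average, compared across sources (experts, crowd, model) with
  a paired Wilcoxon signed-rank test.
* **Scenario harness.** Per-species models, one global model, and
  cross-species transfer (train species ∩ test species = ∅), runnable
  against any backend satisfying the detector contract.
* **Synthetic data.** A generator that renders herbarium-sheet-like images
  (beige paper, green clutter, colour-coded organ blobs) with exact dot,
  mask, and count ground truth, with organ imbalance and sparsity matching
  real crowd-scored collections. A deterministic colour/size baseline
  detector makes the whole pipeline exercisable end-to-end on a CPU.

## Worked example

Simulate ten sheets, detect, count, and evaluate:

```sh
phenocount simulate --n 10 --seed 42 --out demo
phenocount detect   --data demo --out demo/dets.csv
phenocount count    --detections demo/dets.csv --manifest demo/manifest.csv --out demo/pred.csv
# demo/truth.json carries the generator's true counts; exported here as demo/true.csv
phenocount evaluate --true demo/true.csv --pred demo/pred.csv --out demo/report.json
```

The run above prints, in `demo/report.json`:

```json
"mae": {"all": 0.0, "bud": 0.0, "flower": 0.0, "fruit": 0.0},
"r2":  {"all": 1.0, "bud": null, "flower": 1.0, "fruit": 1.0}
```

MAE 0 and R² 1 say the baseline detector recovered every true count
exactly on these noiseless sheets — the expected outcome, and the oracle
the test suite pins. The bud R² is `null` because no sheet in this small
draw carried a bud (buds are rare by design: ~90% of sheets have none), so
the truth is constant and R² is undefined rather than fabricated.

The library mirrors the CLI one-to-one, e.g.:

```python
from phenocount import (default_params, generate_specimen,
                        fit_palette, BaselineDetector, count_detections)

img, truth = generate_specimen(default_params(), seed=7)
palette = fit_palette([img], [[(i.organ, i.mask) for i in truth.instances]])
pred = count_detections(BaselineDetector(palette).detect(img, truth.specimen_id),
                        specimen_id=truth.specimen_id)
assert pred.counts == truth.count_vector.counts
```

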