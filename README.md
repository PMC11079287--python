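# slidegrid

Aggregation-free, grid-level evaluation of cancer detection on whole-slide
images (WSI).

Most deep-learning pathology pipelines are validated only on their
slide-level output, after a learned aggregation step has pooled thousands
of tile predictions into one binary call. That hides where the model
actually saw cancer. `slidegrid` implements the alternative evaluation
style used for computer-aided detection (CADe) of colorectal cancer: the
slide is meshed into disjoint physical grids, every grid gets a label,
and the slide-level call is *derived* from the grid calls with no pooling
model at all — one true-positive grid makes a positive slide.

It is aimed at people validating segmentation-based detectors on WSI
cohorts: it handles the geometry, the ground-truth protocol, the
statistics, and the paired reader study, and ships a synthetic cohort
generator so the whole pipeline is testable without any image data.

## What it computes

**Geometry.** A slide of `W x H` pixels at `mpp` microns per pixel is
meshed into square grids of edge `e` mm: `ceil(W * mpp / 1000e)` columns
(same for rows), disjoint and jointly covering every pixel; edge grids may
be physically partial. Predictions live on fine 0.25 x 0.25 mm2 grids; a
fine grid is positive iff the cumulative positive-mask area inside it
exceeds 625 um2 (strict inequality). Display grids of 0.5 x 0.5 mm2 are
derived from the fine grids (any-positive rollup) and exported as viewer
bounding boxes, red or yellow by whether the supporting connected region
reaches 6400 um2 (the color never enters any metric).

**Ground truth.** Per grid: two independent annotators plus the AI; a
unanimous label stands, any disagreement is escalated to a blinded chief
whose label is final. Per slide: positive iff any grid is positive; cancer
area = positive fine grids x 0.0625 mm2.

**Statistics.** Sensitivity `TP/(TP+FN)` and specificity `TN/(TN+FP)`
at grid and slide granularity, with Wald intervals
`p ± 1.96 sqrt(p(1-p)/n)` deliberately *not* clipped to [0, 1];
likelihood ratios `LR+ = sens/(1-spec)`, `LR- = (1-sens)/spec`; ROC by
threshold sweep with trapezoidal AUC (equal to the rank statistic with
0.5 tie credit); strata by procedure type and lesion area.

**Reader study.** Each reader annotates every slide with and without AI
exposure; grids whose correctness status changes fall into the four
revision directions FN→TP, TP→FN, FP→TN, TN→FP; the beneficial/harmful
discordant counts are tested with McNemar's test (exact below 25
discordant pairs, continuity-corrected chi-square above). Miss sets
(truth-positive slides where an observer marked no positive grid) are
compared by exact Venn subset counts.

## Worked example

Generate a 200-slide synthetic cohort at the default study conditions
(11.6% positive slides, log-uniform lesion areas on 0.5–349.25 mm2), run
the grid-level detection oracle at its default operating point
(sensitivity 0.9025, specificity 0.9660), and evaluate:

```python
from slidegrid import (CohortConfig, OracleConfig, generate_cohort,
                       simulate_oracle, grid_confusion, slide_confusion,
                       sens_spec, likelihood_ratios, round_half_up)
from slidegrid.metrics import ConfusionCounts

cohort = generate_cohort(CohortConfig(n_slides=200, seed=11))
grid = ConfusionCounts(granularity="grid")
slide = ConfusionCounts(granularity="slide")
for i, rec in enumerate(cohort):
    rec.prediction = simulate_oracle(rec.truth, OracleConfig(), seed=i,
                                     with_scores=False)
    grid = grid + grid_confusion(rec.prediction, rec.truth)
    slide = slide + slide_confusion(rec.prediction, rec.truth)

sens, spec = sens_spec(grid)
lrs = likelihood_ratios(sens.estimate, spec.estimate)
print(f"grid sensitivity  {sens.as_percent()}  (n={sens.n})")
print(f"grid specificity  {spec.as_percent()}  (n={spec.n})")
print(f"LR+ {round_half_up(lrs.lr_positive, 2)}   "
      f"LR- {round_half_up(lrs.lr_negative, 3)}")
s_sens, s_spec = sens_spec(slide)
print(f"slide sensitivity {s_sens.as_percent()}  (n={s_sens.n})")
print(f"slide specificity {s_spec.as_percent()}  (n={s_spec.n})")
```

prints

```
grid sensitivity  (90.41, 89.96, 90.85)  (n=16938)
grid specificity  (96.6, 96.58, 96.63)  (n=1992203)
LR+ 26.63   LR- 0.099
slide sensitivity (100.0, 100.0, 100.0)  (n=29)
slide specificity (0.0, 0.0, 0.0)  (n=171)
```

The grid-level operating point is recovered within its Wald intervals,
and slide sensitivity exceeds grid sensitivity because a lesion spanning
many grids needs only one hit. Slide specificity collapses to zero under
this oracle: with *independent* per-grid false positives at rate 3.4%, a
10,000-grid negative slide almost surely contains one. Real detectors
concentrate their false alarms on few slides — see
`docs/methods.md` for what the simulation does and does not emulate.

The full pipeline (adjudication, readers, Venn, report bundle) runs from
the CLI:

```sh
slidegrid simulate --out run/            # synthetic end-to-end study
slidegrid grid --mask mask.png --mpp 0.25 --out gridded/
slidegrid reproduce-paper                # metrics from the shipped counts
```

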