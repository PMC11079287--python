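# Methods

This note documents the models, conventions and design choices behind
`slidegrid`, in the order the pipeline applies them.

## Grid geometry

A whole-slide image is reduced to a pixel raster with one scalar physical
calibration, the microns-per-pixel (MPP). The mesh uses 0-based row/column
indices, a top-left origin, and half-open pixel rectangles
`[x0, x1) x [y0, y1)` — the standard raster convention. The grid count
along an axis is `ceil(extent_px * mpp / edge_um)`, so the mesh always
covers the slide and the last row/column of grids may be physically
partial. Partial grids are kept in the mesh: the 625 um2 positivity
threshold is an absolute area, so a partial grid can still turn positive,
and dropping edge grids would silently discard tissue. Grid boundaries
are computed once per axis (`ceil(k * edge_um / mpp)`, clipped to the
slide) and pixels are assigned by interval membership, which makes the
partition exact by construction regardless of floating-point noise in the
division.

Two lattice levels exist. The *fine* 0.25 x 0.25 mm2 lattice is where
mask-derived labels and detector predictions live. The *display*
0.5 x 0.5 mm2 lattice is what human readers see and annotate; each
display grid aggregates its (up to) 2 x 2 fine grids. The identity
`ceil(ceil(x)/2) = ceil(x/2)` guarantees the two meshes nest exactly.

## Labeling and rollup rules

A fine grid is positive iff its cumulative positive-pixel area *strictly
exceeds* 625 um2 ("exceeds" read as `>`); an `inclusive=True` option
switches to `>=` but is off by default. Rollup to the display level is
any-positive (logical OR) by default: the display grid must flag every
localized detection, and OR is the only rule with that property. The
source protocol does not state the rollup rule explicitly; an alternative
`rule="area"` re-applies the area threshold to the summed per-block
positive area, for sensitivity analyses.

Annotation boxes are emitted one per positive display grid. The box color
rule (red at >= 6400 um2, yellow below) needs a "supporting region"; we
measure the union of 4-connected positive fine-grid components that
intersect the display grid, using positive-pixel areas when the map came
from a mask and whole-grid areas otherwise. Whether the region should be
confined to one grid or span the connected component was genuinely open;
spanning the component matches how a viewer would perceive one lesion.
Color is computed for export only and never enters a metric.

## Ground-truth adjudication

Each grid's truth comes from two independent annotators plus the AI
output. Unanimity (all three agree) fixes the label; *any* disagreement —
annotator vs annotator, or either annotator vs AI — escalates to a chief
resolver whose label is final. The chief is a label map or callback
consulted only on disputed grids, so blinding is enforced by
construction: the chief input receives grid coordinates, never the
sources' labels. Adjudication is symmetric in the two annotators, and a
unanimous cohort provably never invokes the chief (tested with a
resolver that raises).

Slide truth is aggregation-free: positive iff any grid is positive. The
lesion area used for stratification is the positive fine-grid count times
0.0625 mm2. The source protocol reports lesion areas without defining the
measurement (grid-derived vs contour-derived); grid-derived is the only
definition available to this pipeline and is consistent with the 50 mm2
stratification boundary (exactly 800 fine grids).

The comparison scale of the original adjudication (did pathologists
annotate 0.5 mm display grids while the AI predicted 0.25 mm fine grids?)
is not stated. The synthetic pipeline sidesteps the question by
adjudicating on the lattice the maps are generated on, with the generated
truth as the chief; headline grid metrics are additionally reported after
display rollup, which is the scale the original grid counts imply
(~633 mm2 of tissue per slide at 0.25 mm2 per grid).

## Metrics

Confusion counting is exhaustive per grid. Slide-level counts are a pure
function of per-slide grid outcomes: a truth-positive slide is TP iff it
has at least one TP grid, otherwise FN — false-positive grids do not
rescue it; a truth-negative slide is TN iff it has no positively
predicted grid. `slide_outcome_from_counts` re-derives the slide call
from stored per-slide grid counts, and the test suite checks the two
routes agree slide by slide.

Intervals are Wald, `p ± z sqrt(p(1-p)/n)` with `z = 1.96` fixed (no
exact or t-based variant), and are **not clipped** to [0, 1]: the
slide-level sensitivity 163/164 prints an upper bound of 100.58%, and
reproducing printed tables requires keeping it. A `clip=True` option
exists, off by default. Display rounding is decimal half-up at two
percent decimals (three for LR-), matching how the reference tables are
typeset; internal values are never rounded.

Likelihood ratios use the unrounded estimates; `LR+` is reported as
`+inf` at specificity 1 rather than an error, since degenerate rates do
occur (an endoscopic stratum with zero false negatives yields `LR- = 0`).
Two printed values in the reference tables are *not* reproducible from
unrounded arithmetic but are from the rounded percentages (an endoscopic
grid LR+ of 25.66 = 90.07/3.51, and one CI bound off by 0.01); the
package reports the unrounded-arithmetic values.

ROC curves sweep all distinct score thresholds; the AUC is the
trapezoidal integral, algebraically equal to the pair-counting rank
statistic with 0.5 credit for ties, which the tests verify to 1e-12
against a brute-force pair count. For a detector that only emits hard
labels the module refuses to extrapolate an AUC (single operating point
only): how the original study computed an AUC from an apparently binary
grid output is unexplained, and inventing an interpolation would
manufacture a number. The synthetic oracle therefore dresses its labels
with Beta-distributed scores purely to exercise the ROC machinery.

McNemar's test on the discordant-direction pairs defaults to the exact
binomial sign test for `b + c < 25` and the continuity-corrected
chi-square otherwise (the variant used is recorded in the result); the
test itself is delegated to statsmodels. `b = c = 0` returns p = 1 with
a degenerate flag. The "average" reader is the micro-average (pooled
counts); an unweighted per-reader macro mean is also emitted, because the
original definition of "average" is unstated.

## Synthetic data: what it emulates, and what it does not

Defaults are the reference study conditions: 1,418 slides, positive-slide
prevalence 164/1418, surgical fraction 238/1418, lesion areas log-uniform
on [0.5, 349.25] mm2 (the reported extremes; the true area distribution is
unpublished, and log-uniform spreads mass across the two decades), slides
of 80–120 fine grids per side (matching the ~633 mm2 mean tissue area
implied by the grid totals), detector operating point 0.9025/0.9660,
reader baselines 81.80%/99.93%. Lesions are grown as 4-connected blobs by
uniform random frontier accretion — the simplest contiguity-preserving
generator; shape realism is out of scope, as is any pixel-texture
synthesis. A lesion draw that cannot fit its slide raises a configuration
error rather than silently truncating the area distribution.

The oracle flips truth labels independently per grid with
class-conditional error rates. This recovers the configured grid-level
operating point (the acceptance suite demands both rates inside their
empirical Wald intervals in >= 93 of 100 replicates over 10^6 grids) and
reproduces the qualitative slide-vs-grid sensitivity gap (one hit per
lesion suffices). It does **not** reproduce slide-level specificity:
independent 3.4% false positives make a 10,000-grid negative slide
FP-free with probability ~0.966^10000 ~ 0, where the real detector left
68% of benign slides untouched. Real CNN errors are strongly clustered on
few slides; the optional `spatial_correlation` parameter (a Markov copy
of the error state along row-major order, default off) clumps errors
within a slide but preserves the per-grid marginal, not the per-slide
FP-free probability, and no correlation estimate was published to
calibrate against. Passing tests therefore demonstrate the evaluation
machinery, not a claim that iid errors model a real detector's
slide-level behavior.

Simulated readers draw an unaided annotation from their baseline rates,
then flip labels with direction-specific probabilities only on grids
where the AI label supports the flip (e.g. FN→TP requires an AI-positive
grid the reader had missed). The four default profiles derive their flip
probabilities from the published per-reader revision counts divided by
the expected opportunity mass of each direction under the default
baselines and oracle rates; readers are simulated on the same lattice the
oracle predicts on, because those opportunity masses hold at that scale.
This is a marginal model: it matches revision-count structure (e.g. the
senior reader's 99.3% FN→TP share of positive-grid revisions), not any
within-reader spatial correlation. Note the published revision counts
overlap between readers (column sums 3,386/160/1,968/623 vs distinct-grid
totals 3,169/158/1,596/574), and the published "4.21% of all positive
grids" for the 3,169 FN→TP revisions does not match 3,169/75,914 = 4.17%;
the package reports the ratio against the stated positive-grid total.

## Problem sizes and determinism

Every stochastic component takes a `numpy` seed; a pipeline run is
reproducible byte-for-byte from its config and seed (tested). The test
suite and the acceptance script use scaled cohorts — 10–60 slides of
12–28 grids per side for exact-accounting checks, 300 slides of 80–120
grids per side (~3 million grids) for rate recovery, and 100 replicates
of 10^6 grids for interval coverage — sizes chosen so each check's
Monte-Carlo error is far below its assertion tolerance. Empirical claims
in this note (coverage, recovered rates, revision shares) are exactly the
quantities the tests and `scripts/acceptance.py` compute; none are
asserted beyond what those runs measure.

## Known limitations

- No pyramidal WSI decoding (SVS/NDPI): inputs are plain rasters or
  precomputed grid tables.
- No CNN inference; the detector is an injected oracle or an external
  mask. The original detector's real-data AUCs (0.962/0.966/0.971) need
  its trained weights and are out of reach by design.
- No inter-annotator agreement coefficients, reading-time analysis, or
  slide-level aggregation models — all deliberately out of scope.
- Wald intervals are known to undercover for proportions near 0 or 1 at
  small n; they are used because they are what the reference analysis
  used, not because they are optimal.
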