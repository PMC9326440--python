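# Methods

This note documents the models and procedures `soyphen` implements, the
conventions chosen where the field leaves them open, and what the
synthetic generators do and do not emulate.

## Coordinates and annotation handling

Boxes are stored 0-based and half-open, so width, height and area are
plain differences and products. PASCAL VOC XML on disk is 1-based and
inclusive; the conversion (`x_min = xmin_voc − 1`, `x_max = xmax_voc`)
happens only at the I/O boundary. Because the parser rejects
`xmin ≥ xmax`, a one-pixel extent is not representable in the on-disk
dialect and `write_voc` refuses boxes thinner than 2 px rather than emit
XML it could not re-read. Labels are restricted to the closed set
{flower, pod}; anything else is a parse error naming the element.

Rescaling to the 640×640 working resolution scales each axis
independently by `target/source`, which preserves every box's relative
image area exactly (to float rounding); this is the invariant the tests
assert rather than any absolute pixel value.

### Dataset splitting

The split is train+val : test at 8:2, then train : val at 9:1, with floor
rounding toward train+val and train and remainders to test and val —
the unique simple convention that reproduces both published campaign
rows, (1364, 152, 379) of 1,895 and (1938, 216, 539) of 2,693. Two
numerical details matter:

* fractions are converted to exact rationals (`Fraction(str(f))`) before
  the floor, because `floor(1895 * (1 − 0.2))` in binary floating point
  can land on 1515;
* ids are lexicographically sorted before a seeded Fisher–Yates shuffle,
  so the member lists — not just the sizes — are identical across
  platforms and input orders. No stratification (by cultivar or
  otherwise) is applied.

## Anchor clustering

Anchor shapes are found by k-means over image-normalized (w, h) pairs
under `d(box, centroid) = 1 − IOU(box, centroid)`, with the two shapes
co-anchored at a common corner so only shape matters (centering them
would give identical numbers). Design choices, all switchable or seeded:

* **Assignment** maximizes IOU; **update** is the per-dimension median,
  which is robust under the non-Euclidean distance (mean available via
  `update="mean"`).
* **Initialization** is k-means++-style seeding under the same distance;
  the best of 5 restarts by mean best-IOU is returned.
* **Termination**: the assignment being unchanged between two consecutive
  iterations, or `max_iter`. Because the median update does not exactly
  minimize the 1−IOU objective, an update that would increase the
  objective is rejected and iteration stops there — this makes the
  monotone-objective invariant true by construction rather than only
  empirically.
* **Empty clusters** are re-seeded from the box farthest from all
  centroids.

`mean_iou_curve` evaluates the clustering over a k range for elbow
selection; with best-of-restarts it is non-decreasing in k up to restart
noise.

Centroid aspect ratios are defined as h/w (hanging pods are taller than
wide, so representative values run from ~0.75 to ~3.2).
`derive_aspect_ratios` sorts the k ratios and partitions them into
contiguous groups by an exact dynamic program minimizing within-group sum
of squares, returning group means. The DP is deterministic and optimal;
a converged seeded 1-D k-means yields the same contiguous grouping, so
nothing is lost by avoiding restarts here.

Size stratification follows the COCO pixel-area criteria: small
≤ 32² = 1024 px², large ≥ 96² = 9216 px², medium between. The published
criteria overlap at equality; equality is assigned to the outer strata
(small at 1024, large at 9216) so classification is a total function.

## Detection evaluation

Matching is the PASCAL-style protocol: detections of one class are sorted
by descending confidence (ties keep input order) and greedily matched
one-to-one to the unmatched same-image ground-truth box with the highest
IOU ≥ 0.5; IOU ties break toward the earlier ground-truth index, and a
detection overlapping only already-matched ground truth is a false
positive. Conservation (TP+FN = |GT|, TP+FP = |detections|) holds by
construction.

AP is the rank walk `Σₖ Precision(k)·ΔRecall(k)` with k indexing ranked
detections. The raw (uninterpolated) sum is the default; an
all-point-interpolated mode (monotone precision envelope) is provided
because most benchmark toolkits report that variant. With distinct
confidences the raw walk equals a brute-force oracle that enumerates
every confidence threshold — the equivalence test and the acceptance
script both check this; with tied confidences the two definitions
legitimately differ, so the oracle comparisons use distinct confidences.
mAP is the unweighted mean of class APs. Precision/recall with empty
denominators are defined as 0 with a warning rather than an error, so
bulk evaluation does not abort on a class absent from one side.

Segmentation MIoU averages per-class pixel IoU over the K+1 classes
including background, with K inferred from the masks. A class with zero
union (absent from both masks) counts as IoU 1 — the masks agree — and
is flagged with a warning.

## Fusion counting and agreement

The counting pipeline applies a flower detector and then a pod detector
serially to each per-node image and counts emitted detections of the
matching class with confidence ≥ 0.5 (the threshold is a parameter; the
synthetic oracle detector emits confidence 1). Output is one CSV row per
(plant, node, date) plus a TOTAL pseudo-node row per plant, ordered
bit-exactly. The detector seam is a plain callable, so a trained CNN
could be slotted in without touching the pipeline.

Agreement with manual counts is summarized two ways: the fractions of
samples at absolute error 0 / ≤1 / ≤2 (nested by construction), and an
OLS fit of manual on predicted counts with R² the squared Pearson
correlation — identical in either regression direction, which is why
that statistic is reported. Under a pure miss model with probability p,
the expected predicted count is (1−p)·truth, and the fitted slope
recovers 1−p within its standard error; this parameter-recovery property
replaces any claim about real detector accuracy.

## Phenology

Every opened flower resolves to exactly one fate — dropped as a flower
(TNOFD), formed a pod that dropped (TNOPD), or formed a surviving pod
(TNOPF) — so FDR, PDR and PFR share the denominator TNOFD+TNOPD+TNOPF
and sum to 100 identically. `fate_counts_from_events` enforces the
conservation identity (fates = flowers opened) and derives TNOPF as pods
formed minus pods dropped.

Stage intervals are half-open [Rk, Rk+1), with the final interval closed
at R8 (the end of the window); the published interval notation carries no
boundary rule, so this is a package convention. Percentages are reported
at 2 dp. Node layers split the main stem into contiguous thirds from
node 1 upward, the remainder going to the lower layers first (plants
fill from the bottom); sizes differ by at most one.

Daily series bookkeeping: standing flowers(t) = opens≤t − flower
drops≤t − pod formations≤t, live pods(t) = formations≤t − drops≤t. Both
must remain non-negative; a violation raises an error naming the first
offending date, which catches double-spent flowers in hand-built logs.

### The published observation tables

`soyphen.field_tables` carries the two published six-plant drop tables
(cultivars DN252 and HN51, three plants each) as package data, because
they are inputs the reproduction script needs offline. Two findings from
reproducing them, preserved in code and tests:

* The flower table's drop-rate column and all its row/column averages
  recompute exactly (2 dp) from the printed counts. Its per-stage share
  cells do not: no integer count set reproduces the DN252 rows' printed
  shares at 2 dp (an exhaustive denominator search up to 3000 fails),
  while the HN51 rows are consistent only with a denominator equal to the
  row's *total* flower count. The reconstruction tests therefore assert
  exact 2-dp reproduction where arithmetic consistency exists and
  one-count-granularity agreement elsewhere.
* The pod table's printed rates satisfy `rate = total/(dropped+total)`
  for all six rows — not the shared-denominator PDR — and several cells
  are truncated rather than rounded. Both the shared-denominator rate
  and this "organ-conditional" two-count rate are implemented; the
  reproduction uses the arithmetic the table is actually consistent
  with, without asserting which was intended.

## Synthetic generators

All generators are seeded and byte-deterministic. They emulate the
*statistics* the pipeline consumes, not images: no occlusion, lighting,
plant architecture or weather.

* **Annotations**: Poisson(3.3) boxes per 640×640 image (the observed
  density, ~6,334 boxes over 1,938 images), stratum mixture
  (0.5, 0.35, 0.15) over small/medium/large (the observed populations are
  small-heavy), log-uniform pixel area within the stratum capped at 0.25
  of the image area, and aspect ratios scattered lognormally (σ = 0.1)
  around (0.75, 1.8, 3.2). Integer rounding that would cross a stratum
  boundary or the area cap triggers a redraw, so the generator/classifier
  contract is exact.
* **Detections**: independent per-box misses, Poisson spurious boxes per
  image drawn from the same size mixture (so false positives are not
  separable by shape), Normal coordinate jitter clipped to the image,
  and Beta confidences — Beta(5,1) for true boxes, Beta(1,3) for
  spurious — so ranking-based AP is informative. Hidden TP/FP provenance
  is returned for evaluator validation. The per-image adapter keys its
  randomness on (seed, image id), making results independent of
  presentation order.
* **Phenology**: daily per-node Poisson flower openings with
  stage-dependent intensity (defaults {R1: 0.4, R2: 0.6, R3: 0.4,
  R4: 0.2, R5: 0.05} flowers/node/day over a 2019-06-27 → 2019-09-30
  calendar, giving ~5 new flowers per plant per day in full bloom and
  season totals of one to a few hundred flowers per plant, matching
  field-scale observations); fate probabilities defaulting to
  (0.62, 0.14, 0.24), near the observed season FDR; fate resolution
  after 1 + Poisson(lag−1) days with mean lags of 8 d (flower drop),
  7 d (pod set — about a week after flowering) and 14 d (pod drop),
  clamped to the window end so logs are conservation-complete by
  construction. The configuration is rejected if the calendar span does
  not exceed the combined mean lags.

Passing tests on these generators show the *arithmetic and bookkeeping*
of the pipeline are correct and that known parameters are recovered at
the configured rates; they say nothing about the accuracy of any real
detector on real field images, which is out of scope along with all CNN
training.

## Problem sizes and tolerances

The test suite and the reproduction script run at desk scale: hundreds
of images (~1,000 boxes) for detector-noise checks, one simulated season
(~900 flowers) for fate recovery, 50 random instances of ≤ 20 detections
for the AP oracle. Stochastic recovery checks use 99% binomial intervals
(or 3 standard errors for the regression slope) at the realized sample
size; exact identities are asserted to 1e−9 or tighter; published
percentages are asserted at 0.01 (their printed precision), except the
single column average printed at 0 dp (0.5) and the stage-share
reconstructions discussed above.
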