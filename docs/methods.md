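# Methods

This note documents the models, numerical choices and design
decisions behind each module, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Exact trial statistics

The single-stage design search iterates n upward from 1; at each n it
scans thresholds r upward and accepts the first r whose binomial
upper tail under p0 is at most alpha while the tail under p1 reaches
the required power.  Because the type-I tail is decreasing and the
power tail increasing in r, the first feasible r is the smallest, and
the first feasible n is minimal by construction.  Tails are computed
with scipy's exact binomial survival function; no normal
approximation enters anywhere.  The search ceiling defaults to
n = 1000 and raises an error beyond it.

Clopper–Pearson intervals use the beta-quantile form with the usual
boundary conventions (k = 0 forces a zero lower bound, k = n a unit
upper bound).  Percent output rounds half away from zero to one
decimal and drops a trailing ".0", matching the convention of
clinical reports that print "81" rather than "81.0".

The two-stage rule evaluator only *evaluates* a pre-specified rule
(n1, s1_min, n_total, r_final); it does not search for optimal
two-stage designs, whose optimality criterion is a design choice we
do not reproduce.  The stage-1 endpoint may differ from the final
endpoint (e.g. 3-month non-progression vs confirmed response), so the
final success count is not constrained to be at least the stage-1
count.  When stage 1 passes and no final count is supplied the
decision is `continue`; a `require_final` flag turns that situation
into an error for callers that expect a completed trial.

Non-evaluable patients stay in response-rate denominators,
matching full-analysis-set logic.

## Tissue detection

Pipeline: ×8 block-mean downsample (edge padding so the mask has
ceil-divided dimensions) → Rec.601 grayscale → subtraction of the
30×30 local mean (reflect padding) → Law's spot texture energy, i.e.
separable convolution with S5 = (−1, 0, 2, 0, −1) along both axes
followed by a 15×15 moving average of absolute responses → threshold
at energy > 20 → 4-connected hole filling → removal of connected
components of at most 1,500 downsampled pixels.

Two consequences of this construction are worth knowing.  First, the
minimum-area rule means rasters much smaller than ~1,000 px can never
yield tissue; the detector is built for whole-slide images.  Second,
the 15×15 absolute-value averaging bleeds energy past the true tissue
boundary by up to about half the window, so masks are slightly
dilated wherever interior texture energy is far above threshold.  On
slides with pathologist region-of-interest annotations the patch
stage clips this dilation; the synthetic slides therefore carry an
ROI polygon, as the annotated cohort did.

## Patch extraction

Patches are 64×64, grid-aligned from pixel (0, 0), non-overlapping.
A patch is kept when at least 50% of its footprint maps into the
(downsampled) tissue mask and, when ROIs are present, at least 50% of
its area lies inside them (shapely polygon intersection).  The
black/white filter counts raw values over all three channels jointly
(12,288 values): strictly more than 70% below 2 discards a black
patch, strictly more than 80% above 250 a white one.

## Stain model and nuclei morphometrics

Optical density is OD = −log10((I + 1)/I0) per channel (the +1
avoids log 0 on 8-bit data); pixels are unmixed onto unit-norm
hematoxylin/DAB vectors (Ruifrok–Johnston defaults) by least squares
with negative loadings clipped at zero.  Bases within 10° of
collinear are rejected.

The nuclei segmenter is deliberately classical — Otsu threshold on
the hematoxylin OD, hole filling, watershed on the distance transform
seeded at local maxima — because the deep unsupervised segmenter used
upstream in the original analysis is not reproducible without its
weights.  The *post-filters* are the part specified by the protocol
and are preserved exactly: perimeter bounds and a circularity floor
(defaults 8–300 px and 0.25, configurable and logged, since no
canonical values exist), greedy centroid deduplication discarding any
nucleus strictly within 20 px of an already kept one (processing
order: descending area, then raster order), DAB intensity averaged
over a 30 µm-diameter disc (diameter rounded to the nearest odd pixel
count, clipped at borders), and per-patch aggregation by the
half-open patch interval containing the centroid.

## Descriptors, clustering and model selection

The default handcrafted descriptor has 14 dimensions: DAB OD mean,
s.d. and the 0.1/0.25/0.5/0.75/0.9 quantiles; hematoxylin OD mean and
s.d.; S5S5 and E5E5 Law energies of the mean-centred grayscale tile;
the square root of the nucleus count; the square root of the mean
nucleus area; and the mean within-nucleus DAB tile OD (falling back
to the patch DAB mean when no nucleus is found, so the feature stays
continuous).  The square roots variance-stabilise count-driven
features — raw counts give the sparse classes a long within-class
tail that the Davies–Bouldin index likes to split — and features that
carry no between-class information on IHC tiles (e.g. circularity of
uniformly round nuclei) are left out because pure-noise dimensions
dilute the cluster geometry.  A CNN embedding (the original analysis
used 1,024-d truncated-ResNet50 features) can be plugged in through
the same deterministic fixed-dimension interface.

Features are z-scored over all patches of all slides; features with
s.d. below 1e-12 are dropped (and logged) rather than divided.
Descriptor rows are canonically sorted by (slide id, patch origin),
which makes the entire pipeline invariant to the order slides are
supplied in.

Clustering is mini-batch k-means (batch 1,024, 100 iterations,
k-means++ with 10 initialisations, fixed seed).  Model selection fits
every k in 7..12 and keeps the fit minimising the Davies–Bouldin
index, ties broken toward smaller k.  Fits that collapse below k
distinct labels are flagged degenerate and excluded by an infinite
score.

Association: per cluster, a two-sided Mann–Whitney U on the cluster's
slide proportions between responders and non-responders — exact null
when both groups have at most 8 slides and the data are tie-free,
otherwise the normal approximation with tie and continuity
corrections — followed by Benjamini–Hochberg across the k clusters
(statsmodels step-up).  A cluster with identical proportions on every
slide is reported at p = 1.

## Paired-genomics rules

Rescue thresholds are 1 alt read below 100× coverage, 2 from 100× to
below 500×, and 3 above 500×.  Coverage exactly 500 is not covered by
the quoted bands; we require 3 reads there (the conservative choice)
and expose it as a parameter.  Rescued calls carry a provenance tag
naming the source timepoint, and a pileup row is required for every
retained call of the source sample (a missing row is an error listing
the uncovered positions).  One rescue round in each direction is a
fixed point: the test suite checks that a second round adds nothing
in either order.

The CNA filter works gene-by-gene from the primary segmentation run;
for driver genes the higher-sensitivity run's segment substitutes
when it is shorter than 3 Mb or more than three times shorter than
the primary segment, the focality rule then drops segments of 10 Mb
or more (strictly: 9,999,999 bp passes), and the category filter
keeps high-level amplifications and homozygous deletions, plus
medium-level amplifications on oncogenes.  Hemizygous deletions are
excluded by default and can be toggled in (`keep_hemizygous_del`),
since their status in the original oncoplot is ambiguous.
Coordinates are 1-based inclusive; multi-allelic records are split
into biallelic events before any rule.

"Altered" for acquired-alteration calling means any driver mutation
or surviving CNA event.  The driver/oncogene list is a packaged toy
table with the production schema (two-column TSV); analyses meant for
real cohorts should substitute a curated list.

## Microenvironment statistics

Densities divide marker-query-positive cell counts (conjunctive
queries over phenotype flags) by the analysed tissue area in mm²;
area is supplied explicitly or estimated from a buffered convex hull
of the cell cloud.  Nearest-CK+ distances use a k-d tree, with CK+
cells measured to the nearest *other* CK+ cell; bins are half-open
with a 10 µm default width, so a distance of exactly 10 falls in the
second bin.  The paired test is the two-sided Wilcoxon signed-rank
with zero differences dropped (Wilcoxon's original rule), exact null
up to 25 non-zero tie-free differences and the tie/continuity-
corrected normal approximation otherwise; all-zero differences give
p = 1 with a warning.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed); a master seed
spawns independent substreams per artifact family, so regenerating
one artifact never shifts another.

*Slides.*  A jittered disc of tissue (annotated as the ROI) is tiled
into 64 px cells; each cell draws a planted class from a per-slide
Dirichlet mixture (concentration 60 around the group mixture).  The
eight default classes sit on a DAB-level × cell-density ×
nucleus-size grid — DAB OD 0.06/0.45/1.00/1.60, about 6 or 22 nuclei
per patch, nucleus radius 1.5 or 2.6 µm — so that each class is a
well-separated mode in appearance space, which is the generator's
contract: planted structure the pipeline should recover.  Class 0 is
the stroma-like class (essentially unstained, sparse small nuclei);
non-responders receive a +0.15 excess of it.  Per-patch nuclei counts
are under-dispersed (truncated normal, s.d. 20% of the mean) rather
than Poisson — real nuclei exhibit hard-core repulsion, and
over-dispersed counts would smear the planted modes.  Rendering is
forward Beer–Lambert: hematoxylin from nucleus discs plus a faint
wash, DAB at the class level with 8% multiplicative jitter, additive
Gaussian sensor noise (s.d. 2 grey levels) on the transmitted
intensity, clipped to 8 bits.  Not emulated: realistic chromatin
texture, stain gradients, scanner artifacts, folded tissue and
out-of-focus regions — so a passing pipeline demonstrates the
*machinery* (patching, descriptors, model selection, statistics), not
robustness to real-slide variability.

*Variants.*  Eleven patients receive shared clonal mutations at both
timepoints (coverage drawn from 60/250/800× regimes), the
deterministic 5×3 coverage-by-alt-reads rescue grid
({99, 100, 499, 500, 501} × {1, 2, 3}) as baseline-only calls with
fixed resistance pileups, acquired mutations in two resistance
samples per truth gene, a CNA-only acquired gene in three samples
plus a two-sample decoy that must stay below the CNA-only threshold,
germline contaminants at rate 0.1 (three patients lack a matched
normal), and the segment constructions that exercise the focality and
substitution boundaries (12 Mb primary with 2.5 Mb sensitive, 9.9 vs
10.0 Mb deletions, medium amplifications on an oncogene and a
non-oncogene).  Sequencing-read-level noise is not simulated; truth
labels accompany every planted record.

*Trial outcomes.*  Per-cohort Bernoulli confirmed responses with the
observed cohort sizes (68/72/37) and response rates
(0.706/0.375/0.297) as defaults; target-lesion changes are drawn
consistently with the response category.

*Cell maps.*  Homogeneous marked Poisson processes on a 1.4 × 1.5 mm
field: CK+ tumor cells at 400/mm² with PD-L1 positivity 0.25, CD3+ at
150/mm² (CD4/CD8 split 60/40, FoxP3 10%, PD-1 20%), CD68+ at 80/mm²
(PD-L1 10%), all scaled by a per-patient lognormal abundance
multiplier (s.d. 0.3) shared across timepoints.  The planted
treatment effect multiplies the CK+/PD-L1+ positivity on treatment by
a configurable ratio (1.0 = null).  Spatial clustering of immune
cells and tissue-boundary effects are not modelled.

## Problem sizes used in the checks

The slide-pipeline recovery check runs ten seeded 24-slide cohorts of
512×512 px slides (roughly a thousand patches each) — small enough to
run in about a minute per few cohorts on one core, large enough that
model selection and the rank-1 recovery of the planted class are
non-trivial.  The microenvironment calibration uses 200 null
replicate cohorts and 100 effect replicates of 18 pairs each.  The
exact-statistics oracles enumerate group sizes up to 8, all (k, n)
with n ≤ 25 on a 1e-4 probability grid, and 2,000 coverage draws.

## Known limitations

- The classical nuclei segmenter under-performs a trained network on
  crowded or low-contrast real tissue; only the downstream filters
  and features are protocol-faithful.
- The Davies–Bouldin selection is sensitive to noisy descriptor
  dimensions; with a CNN embedding, a dimensionality-reduction step
  before clustering may be warranted.
- The two-stage design search (as opposed to rule evaluation) is out
  of scope.
- Clinical-benefit-rate and time-to-event endpoints are not
  implemented; they are routine off-the-shelf analyses.
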