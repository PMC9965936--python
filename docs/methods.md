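# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions that matter for reproducing its
behavior.

## Synthetic phantoms

A phantom is a piecewise-constant template — dark background (gray level
20), an elliptical "brain" (level 120), optionally a bright circular
"tumor" (level 220) fully contained in the brain — corrupted first by
additive Gaussian noise (default σ = 4 gray levels) and then by
salt-and-pepper impulses (default 2 % of pixels, half set to 0 and half to
255). Images are 64×64, 8-bit. Per-image geometry (brain axes, tumor
center and radius) is jittered deterministically from the dataset seed;
every image carries its own child seed, so a dataset is reproducible bit
for bit. The default dataset size for end-to-end runs is 100 images with a
50/50 class balance and an 80/20 stratified train/test split; the two-folder
export (`yes/`, `no/`, `masks/`, `manifest.csv`) mirrors the layout of
public brain-MRI collections of a few hundred images.

The phantoms deliberately reproduce only the properties the pipeline's
stages act on: impulse noise for the median filter, a small number of
intensity clusters for fuzzy c-means, a compact bright blob for region
growing and candidate ranking. They do not model MR physics — no bias
fields, Rician noise, partial-volume effects, anatomical texture, or 3-D
structure. Passing the end-to-end tests therefore demonstrates that the
pipeline's stages interlock correctly and recover known ground truth under
its stated assumptions, not that the system reaches any particular
accuracy on clinical images.

Color inputs are collapsed with fixed BT.601 luminance weights
(0.299, 0.587, 0.114); 16-bit inputs are rescaled by the fixed linear map
`v·255/65535`.

## Preprocessing

**Median filter.** Window side defaults to 3 (configurable, odd ≥ 3);
borders are handled by edge replication, chosen for simplicity and
shift-invariance at interior pixels. The filter replaces every pixel
unconditionally by default; an optional threshold mode replaces a pixel
only when it deviates from its window median by more than a given amount,
for callers who want detection-style filtering. The output pixel is always
a member of its input window multiset.

**Sub-histogram equalization.** The split point of an interval is the
CDF-weighted mean gray level over the interval's occupied levels; splitting
recurses binarily until `t` segments exist (default `t = 2`,
bi-histogram style). Each segment is equalized onto its own input interval
with the min-CDF-normalized mapping
`l ↦ a + round((CDF(l) − CDF_min)/(1 − CDF_min) · (b − a))`, so a segment
containing a single occupied level maps to itself, segment ordering is
preserved, and output never leaves [0, 255]. A split point is clamped so
both sides keep at least one occupied level; requesting more segments than
occupied levels is an error.

## Segmentation

Fuzzy c-means runs on pixel intensities only (default `c = 3` for
background/brain/tumor, fuzziness `m = 2`, tolerance 1e-4 on the maximum
center displacement, random membership initialization from the seed). The
alternating center/membership updates make the objective
`Σ μ^m d²` nonincreasing; a point coinciding with a center receives full
membership there. An optional intensity+coordinate feature space exists
but is not the default.

The cluster "center" is an intensity, not a place, so each cluster's
spatial seed is its maximal-membership pixel (ties broken row-major).
Region growing enqueues all seeds together (breadth-first, 4-connectivity
by default); a neighbor is admitted when its intensity is within τ of the
region's **running mean** — stabler than comparing to the seed value alone,
which remains available as an option. Growth terminates when no front can
advance, i.e. zero pixels change between sweeps. τ defaults to twice the
pooled within-cluster intensity standard deviation of the clustered image.

**Which image is segmented.** The pipeline computes both the denoised and
the equalized image but, by default, clusters and grows on the *denoised*
one. Equalization stretches the heavily populated background band across a
wide intensity range — that is its purpose — and in doing so destroys the
tight three-cluster structure FCM needs: on the default phantoms, mean
tumor Dice collapses from ≈ 0.95 (denoised) to ≈ 0.01 (equalized). The
equalized image is still written as an artifact and can be selected with
`segment_on="equalized"`.

**Candidate selection.** Each grown region is scored by circularity
`4π·area/perimeter²` (perimeter = count of region pixels with a 4-neighbor
outside) times edge support (fraction of boundary pixels whose gradient
magnitude exceeds the image's median gradient); the highest score wins,
ties break toward larger area. This operationalizes "a compact, strongly
edged, circle-like region" as a concrete, testable score.

Segmentation quality is reported as pixel accuracy and Dice
`2|A∩B|/(|A|+|B|)` against the ground-truth mask; the Dice of two empty
masks is defined as 1.

## Features

The feature schema is frozen to twelve columns so the table is stable:
mean, standard deviation, skewness `m₃/m₂^{3/2}`, kurtosis `m₄/m₂²`
(population moments; excess-kurtosis available as an option), the central
moments m₂–m₄, region area, and four co-occurrence statistics. Constant
regions take skewness = kurtosis = 0 by convention so degenerate candidates
do not inject NaNs.

The co-occurrence matrix uses 16 quantization bins over [0, 255], the four
distance-1 offsets E/S/SE/NE, symmetrization and normalization to sum 1,
restricted to pixel pairs lying inside the region mask. Texture statistics
are contrast `Σ P_ij (i−j)²`, correlation (defined as 1 when a marginal
variance vanishes), energy `Σ P_ij²`, and homogeneity `Σ P_ij/(1+(i−j)²)`.
A region admitting no valid pair falls back to whole-image features with a
logged warning.

## The optimizer

The metaheuristic maintains `f` candidate positions. Each member proposes,
once per iteration, either the exploration update
`A' = A_rand − v1·|A_rand − 2 v2 ∘ A|` or the exploitation update
`A' = (1−v1)·A_rand + 2 v1 v2 ∘ A`, where `A_rand` is a uniformly chosen
member, the branch is selected by a fair draw against 0.5, and proposals
are clamped to the feasible box. Three design choices matter:

- **`v2` is a random vector** (uniform per dimension), not a scalar. With
  a scalar, both updates move a point along a single line determined by
  `A_rand` and `A`; in as few as two dimensions this cripples the search
  (the fixed-target benchmark then succeeds in only ~2/10 runs versus
  10/10 with vector draws). Random vectors are the norm in this algorithm
  family.
- **Greedy per-member acceptance.** Neither update references the best
  solution found, so the update rules alone contain no pull toward good
  regions; selection supplies it. A member adopts its proposal only when
  the proposal's cost does not exceed its own; the best position ever
  evaluated is additionally retained (elitism), making the best-fitness
  trace monotone nonincreasing and capping evaluations at `f + f·iters`.
- **`v1` decays linearly**, reaching 0 exactly at the final iteration
  (`v1 = 1 − (b+1)/iters`), so the search hands over from large exploratory
  steps to pure recombination of surviving members.

An optional coefficient-vector term `+ B·|best − A|` (B uniform in [0, 2])
can be enabled; it is off by default. The canonical Harris-Hawks machinery
(escape energy, soft/hard besiege, Lévy flights) is intentionally out of
scope: the implemented updates are the two self-consistent rules above.

On the 10-D sphere in [−5, 5]^10 (population 30, 500 iterations) the
optimizer reaches best fitness < 1e-3 in 20/20 seeded runs (the test suite
asserts ≥ 18/20).

## The classifier

The network is the smallest architecture matching the layer list
input → convolution → ReLU → max-pool → fully connected: 64×64 input, one
convolution layer of eight 3×3 kernels (valid cross-correlation, stride 1),
2×2 non-overlapping max pooling, and a single sigmoid output unit. The
loss is the mean squared error between the sigmoid output and the 0/1
label — deliberately MSE, not cross-entropy, to match the printed training
objective. Training is mini-batch gradient descent (default learning rate
0.1, 40 epochs, batch 16, seeded shuffling; whole-image inputs share a
large background component that conditions the final-layer gradient badly,
so the whole-image mode typically needs a smaller rate, around 0.02); the backward pass is exact and
is checked against central finite differences (< 1e-4 relative error) in
the tests. Labels threshold the probability at 0.5, with 0.5 itself mapping
to the tumor class.

**Classifier input.** By default the classifier sees the candidate region
masked out of the processed image, translation-normalized by rolling the
region centroid to the frame center. Without that normalization the single
fully connected layer memorizes tumor *positions* seen during training and
an unusually placed test tumor can score near zero; with it, the
end-to-end phantom benchmark classifies essentially perfectly. A
whole-image mode is available.

**Metaheuristic refinement.** After gradient descent, the final-layer
weight vector (default scope; an all-weights mode exists but puts the
population search in a very high-dimensional box) is refined by the
optimizer inside a ±0.5 box around the trained values, with the incumbent
seeded into the initial population. Refined weights are adopted only when
the training loss does not increase, so refinement can never hurt the fit.
Defaults (population 8, 10 iterations) keep this stage cheap.

Models serialize to a single JSON file (architecture header + flat weight
list); JSON round-trips float64 exactly.

## Evaluation and orchestration

Classification metrics are the confusion-matrix rates with the convention
that a zero-denominator rate is reported as 0 and flagged (portable JSON
instead of NaN); the ROC is the standard sweep over unique predicted
probabilities with trapezoidal AUC (equal to the all-pairs concordance
count, which the tests verify). The train/test protocol is an 80/20
stratified split — a documented choice, since no split is canonical for
collections of this size.

All stage seeds derive from the single global seed via seed sequences, and
metrics JSON is written with sorted keys, so two identically configured
runs are byte-identical. The default end-to-end problem size (100 phantoms
at 64×64) keeps a full run around ten to fifteen seconds on one CPU while
leaving every stage non-trivial.

## Known limitations

- The phantom generator's realism limits are listed above; no claim is
  made about clinical MR data.
- Candidate selection assumes roughly one compact tumor; multifocal or
  ring-shaped lesions would need a different score.
- The equalization stage improves display contrast but does not help the
  default segmentation path (see above); it is retained as a documented,
  switchable stage.
- The optimizer is a faithful implementation of the two printed update
  rules plus standard selection machinery, not the canonical Harris-Hawks
  algorithm; comparisons to published HHO results are out of scope.
- Training uses MSE on a sigmoid output, which is slower to escape
  plateaus than cross-entropy; it is retained as the specified objective
  and is adequate at this problem size.
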