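# Methods

## Representation and input

A concept is a vector of 11 mean sensorimotor strength ratings, each on a
0–5 scale, in the fixed order: auditory, gustatory, haptic,
interoceptive, olfactory, visual, foot/leg, hand/arm, head, mouth/throat,
torso (six perceptual modalities, then five action effectors).  This is
also the clockwise-from-top order used for polar-profile export.  The
item-level means are the unit of analysis; the package never
re-aggregates participant-level ratings, and ancillary norm variables
(dominant modality etc.) do not enter any distance.

Word keys are case-folded with whitespace runs collapsed, because norms
tables are conventionally distributed upper-case while similarity
benchmarks are lower-case, and the evaluation pipeline must join the two.
Multi-word items are kept verbatim (single internal spaces); duplicate
keys are a hard load error rather than last-wins, since a silent
overwrite would corrupt pair statistics.  Loaded tables are stored sorted
by key, so row order in the input file is irrelevant to every downstream
result.

Ratings outside [0, 5], non-numeric cells and missing mapped columns are
load errors naming the row and column.  The column map defaults to the
published Lancaster norms header and is user-overridable, since the file
schema is a distribution convention, not part of the measure.

## Metrics

Five pairwise distances are implemented on the raw mean ratings, in
double precision, with no standardisation step:

* **cosine** (principal): 1 − u·v/(‖u‖‖v‖); in [0, 1] for non-negative
  vectors; scale-invariant, so it compares profile *shape*.  An all-zero
  vector has no direction and raises an error rather than returning a
  sentinel, which would silently contaminate extreme-pair scans.
* **correlation**: 1 − Pearson r across the 11 dimensions of the two
  vectors; constant vectors are an error for the same reason.
* **euclidean**: ‖u − v‖₂.
* **minkowski3**: (Σ|uᵢ−vᵢ|³)^{1/3}.
* **mahalanobis**: √((u−v)ᵀ Σ⁺ (u−v)).  Σ is estimated once from the
  whole loaded table (dimensions as variables, concepts as observations,
  n−1 denominator) — one global geometry, matching the idea that the
  metric removes the norms' correlated structure.  The pseudo-inverse Σ⁺
  is used instead of a plain inverse: identical when Σ is
  well-conditioned, and still defined when a dimension is (nearly)
  linearly dependent.

Scalar implementations are written directly from these definitions.
Block computations (pair scans, neighbour queries, layouts) use a
vectorised path (`scipy.spatial.distance.cdist`, plus an expanded
quadratic form for Mahalanobis whose clamping keeps pseudo-inverse
round-off finite); the test suite holds the two routes to ≤1e−8 pairwise
agreement and holds the scalar route to ≤1e−10 agreement with naive
long-form re-implementations.

## Pair-space scans

All n(n−1)/2 unordered pairs (self-pairs excluded) are covered exactly
once by streaming row blocks against the remaining rows.  Moments use a
mergeable mean/M2 accumulator (Chan-style pairwise combine), so results
are independent of the block size to ~1e−10 even at hundreds of millions
of accumulations; SD is the sample SD (n−1), defined as 0 when only one
pair exists.  Extreme pairs are kept in bounded pools (default 100 per
end); ties break lexicographically on the normalised key pair, making
reported extremes deterministic.  The histogram has 100 bins: fixed
width 0.01 on [0, 1] for cosine (single pass), and for the other metrics
100 equal bins from 0 to the observed maximum, which requires a second
streaming pass after the maximum is known — a deliberate trade of one
extra scan for exact bin placement; no pair set is ever materialised.

Nearest-neighbour queries are exact scans over all other concepts
(approximate indexing is unnecessary at n ≈ 40k), sorted by (distance,
word) so ties are alphabetical and the query itself is excluded; k is
capped at n−1.

## 2-D layouts

Selected concepts are laid out in the plane by minimising Sammon stress

E(Y) = (1/c) Σ_{i<j} (d*_{ij} − d_{ij})² / d*_{ij},  c = Σ_{i<j} d*_{ij},

where d* are the input sensorimotor distances and d the layout Euclidean
distances.  Exact-zero input distances (duplicate vectors) are floored at
1e−9 to keep the weights finite.  Initialisation is classical scaling
(eigendecomposition of the doubly centred squared-distance matrix) with a
sign convention fixed per axis, falling back to a seeded random
configuration only when the leading eigenvalue is non-positive; descent
is plain gradient steps with backtracking (halve until the stress drops,
then grow the step 1.5×), so the accepted stress sequence is
non-increasing by construction.  Defaults: max_iter 500, relative
improvement tolerance 1e−9.  Layouts are deterministic given the seed.
Stress is invariant under rotation, translation and reflection of the
layout, so coordinates are reported up to rigid motion.

## Benchmark evaluation

Benchmarks join to the norms on normalised unordered pairs.  Pairs with a
missing word are flagged uncovered and kept, so coverage counts are
always available.  External similarity measures (taxonomic distance,
feature overlap, distributional distance, …) are consumed as pre-computed
columns merged on the unordered pair; the package does not reimplement
them.

Statistics are frequentist point estimates: Pearson r for zero-order
correlations (human scores are similarities, so distances correlate
negatively), OLS R² for regressions.  Hierarchical ΔR² fits the human
score on an alternative predictor alone, then adds sensorimotor distance;
because the models are nested and fitted on identical rows, ΔR² ≥ 0
(clamped against round-off at ~1e−16).  Best-subset search enumerates all
2^p − 1 non-empty predictor subsets (p ≤ 12) on the rows jointly covered
by all candidates, so every subset competes on the same data, and ranks
by BIC with ties broken towards fewer predictors.  Rows with any missing
value for the predictors of a given fit are dropped listwise for that fit
only.

The abstract/concrete split uses a 1–5 concreteness rating: a word is
abstract if rated < 3 (the scale midpoint) and concrete if ≥ 3; a pair is
abstract–abstract, mixed, or concrete–concrete accordingly, and pairs
with a missing rating go to an explicit `unsplit` bucket.

## Synthetic data

The norms generator draws latent vectors from a multivariate normal with
a block covariance template — correlation 0.5 within the six perceptual
dimensions, 0.4 within the five action dimensions, 0.2 across blocks,
unit diagonal — qualitatively mirroring the real norms' structure (what
can be touched can usually be seen).  Latents are mapped as
2.0 + 1.0·z and clipped to [0, 5]: the location/scale pair keeps most
mass in-bounds so clipping distortion stays mild, which matters because
the covariance-recovery tests compare the estimated covariance against
the template.  The generator emulates correlated, bounded, item-level
mean ratings; it does not emulate the real norms' skewed marginals,
part-of-speech mix, or word frequencies, so tests passing on fixtures
demonstrate algorithmic correctness, not distributional claims about
real norms.

The benchmark generator samples unordered pairs without replacement
(flat pair indices decoded to (i, j)), and scores each pair as
link(1 − cosine distance) + Gaussian noise, recording the realised
signal SD.  With an affine link, the observed |r| between score and
distance has the closed form σ_s/√(σ_s² + σ_n²), which the recovery
tests check within ±0.05 at n = 2,000.  Note that |r| at finite n is
itself a random draw with sd ≈ 1/√n; the huge-noise check therefore
bounds the median of several draws rather than one sample.

## Problem sizes and numerical defaults

The default test suite and the acceptance script run entirely on
synthetic data: tables of 100–1,500 words (up to ~1.1 million pairs in
the streamed summary), benchmarks of up to 2,000 pairs, layouts of up to
15 points — sizes chosen so the full pipeline, including brute-force
oracles, runs in seconds while still exercising the chunked streaming
paths.  Full published-scale checks (39,707 concepts, 788,303,071 pairs)
run through the identical code when the published files are supplied, and
stream in row blocks of 512 with O(n·block) memory.

Known limitations: distances are only as meaningful as the input means
(items rated by few participants are noisy, and the package does not
propagate rating SEs); Sammon layouts are local minima — different seeds
can give different (equally valid) configurations for hard inputs; the
correlation metric discards profile magnitude entirely; Mahalanobis
results depend on which table the covariance was estimated from, so
covariance contexts record their source size.
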