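# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Input model and preprocessing

The unit of observation is a tissue sample: one (case, cortical region)
pair, measured for p proteins across one or more western-blot runs.
Values are assumed densitometry-normalized (loading-control division done
upstream) and therefore nonnegative; the package treats empty cells,
"NA" and "NaN" (case-insensitive) as missing because CSV dialects vary.

Replicate runs are collapsed to the per-cell arithmetic mean over the runs
where the cell was observed; a cell stays missing only when missing in
every run. Averaging precedes imputation, matching the order in which the
workflow was originally applied.

k-NN imputation (opt-in) fills a missing cell with the mean of that
protein over the k nearest rows. Distances are Euclidean over mutually
observed proteins on column-standardized values; standardization affects
the distance only — imputed values are on the original scale. Neighbors
must observe the target protein and ties break by row order, making the
procedure deterministic. Default k = 10, capped at one less than the
number of complete rows. This contract (distance-only standardization,
deterministic tie-break) is why the imputer is implemented in the package
rather than delegated to a generic distance-weighted imputer.

Centering subtracts column means and never divides by the standard
deviation: abundant proteins are allowed to dominate the PCA, which is the
intended behavior for panels whose absolute expression differences are
biologically meaningful.

## PCA and the dimension rule

PCA is computed by SVD of the centered matrix; eigenvalue_k = s_k²/(n−1).
The denominator is a convention only — percent variance, cos² and every
downstream quantity are invariant to it. SVD signs are arbitrary, so each
loading column is flipped to make its largest-magnitude entry positive;
without a fixed convention the sign-based feature heuristics would not be
reproducible. Rank-deficient input is allowed (trailing zero eigenvalues);
a zero-variance protein gets an all-zero cos² row with a warning rather
than NaN.

The retained dimension count is the smallest d whose cumulative explained
variance reaches the threshold, compared inclusively; the default
threshold is 80 %. That single value is the source of truth for every
later stage.

## Feature engineering

A sum feature is Σ over a protein set; an index feature is
(A − B)/(A + B) on the sums of two disjoint sets. The bounded,
antisymmetric, scale-free contrast form is fixed because the phenotype
color map anchors zero at yellow on a symmetric red–green scale — only a
bounded, sign-symmetric index is consistent with that encoding.
Multi-protein indices contrast the sums (not means) of each side, for
consistency with the sum features; this makes the index sensitive to the
set sizes, which is documented here deliberately.

Proposal heuristics, deduplicated by unordered protein-set identity:
the all-protein sum always; a sum for each declared protein class with at
least one member whose |variable coordinate| reaches the per-dimension
amplitude threshold (default: the 0.75 quantile of that dimension's
amplitudes — "largest amplitudes" is qualitative in practice, so the
quantile is exposed in config); an index for every a-priori pair present
in the panel; and a novel-pair index for any two proteins that on some
retained dimension both clear the threshold with opposite signs (the
positively loading protein becomes the numerator). Proposal is assistive:
the library returns the list with provenance and the caller decides.

Validation computes Pearson r and two-sided p for every (retained
dimension × feature) pair and adjusts over all d·m tests, Bonferroni by
default with Benjamini–Hochberg selectable. A feature is validated when
significant on at least one retained dimension. Constant features are
reported as not significant with a warning rather than as an error.

## Phenotype encoding

Group profiles are feature medians (missing excluded). Indices map
linearly in RGB from red (−L) through yellow (0) to green (+L) with
L = max |index median| over the scale span; sums map on a white→near-black
gray ramp over [0, max sum median]. In `absolute` mode the span pools all
profiles passed in one call — this is what makes two datasets' phenotypes
comparable — while `local` mode scales each profile alone. Pure-green and
pure-red anchors keep both color channels monotone in the median. Sum
features can be re-expressed relative to a reference group (each sum
divided by that group's median) before boxplotting; indices are never
renormalized. Boxplots use 1.5·IQR whiskers and seeded jitter.

## Clustering

tSNE (2-D, perplexity 25, 5 000 iterations, PCA initialization, fixed
seed) embeds the feature columns only; metadata provably never reaches
the embedding. The original tSNE workflow drew a fresh random seed each
run, so the embedding here is seeded and the backend recorded; precomputed
coordinates can be substituted where figure-faithful reruns matter.

The WSS curve holds k = 1 (total centered sum of squares, in closed form)
plus k-means totals for k = 2..15, each the best of 25 k-means++ restarts
— a single random start makes the curve unreproducible. The cluster count
is read from an exponential-decay fit a·e^{−k/τ} + c (nonlinear least
squares; c₀ = min WSS, a₀ = WSS(1) − c₀, τ₀ = range/4, τ bounded by the
searched range): k* = round(4τ), half-away-from-zero, clamped to the
range. Four time constants is where the fitted decay has flattened to
under 2 % of its initial value. A non-decaying curve raises an error
recommending a manual k. On well-separated blob data the 4τ rule tends to
sit within one of the true cluster count; the k-means partition is what
carries the recovery, and it is run at k* with seeded restarts (empty
clusters trigger a reseeded retry).

Subclusters are (condition, cluster) pairs with at least `min_size = 2`
members.

## Similarity

Entities (subcluster medians or individual animals) are compared by
Pearson correlation across features. The dendrogram is built on Euclidean
distances **between rows of the correlation matrix** — mirroring the
original workflow's convention — with 1 − r available behind an option;
linkage is complete by default with Ward.D2 selectable (implemented on
Euclidean distances per the Ward.D2 convention). The cut count is
user-supplied: branch-height judgment is left to the analyst rather than
automated.

## Inference

Reference bounds are the pooled 5th/95th percentiles of the reference
group's features under nonparametric bootstrap resampling (default
10 000 resamples, seeded); "simulating the reference distribution" is
interpreted nonparametrically because no distributional family is
implied by the data. Quantiles use linear interpolation (type 7)
throughout — at reference sizes of 5–10 samples the percentile rules are
sensitive to the convention, so it is fixed and documented.

ORA calls a feature over when the group's lower percentile (25th, or 10th
under the conservative rule) exceeds the reference 95th, under when the
upper percentile (75th/90th) falls below the reference 5th. The
conservative rule's calls are a subset of the loose rule's by
construction.

The bootstrap comparison resamples group and reference independently,
forms the difference of medians (medians summarize features everywhere in
this workflow; the mean is selectable), and reports
p = 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0)) with a +1/(n_boot + 1) continuity
correction. No multiplicity correction is applied across features by
default (raw p < 0.05 calls are the workflow's convention; Bonferroni/FDR
are available). At group sizes around 6–8 the median-difference bootstrap
runs somewhat conservative (observed type-I ≈ 0.03–0.05 at nominal 0.05),
which is the safe direction for a screening tool.

## Synthetic panels

A generated value is baseline · group effect · region effect ·
exp(N(0, σ_bio)) · exp(N(0, σ_global)) + run noise, with the biological
and global (per-sample loading) lognormal factors drawn once per tissue
sample and additive Gaussian run noise per replicate. Multiplicative
lognormal variation keeps values positive and right-skewed like
densitometry data, and the global factor cancels exactly in contrast
indices while inflating sums — reproducing the familiar pattern that
balances are more stable than absolute levels. Because the lognormal
median is 1, group medians sit exactly at baseline × effects, so ground
truth propagates to the feature level in closed form: a sum is recorded
as planted when its expected ratio to the reference leaves ±8 %, an index
when its expected shift exceeds 0.05.

Presets: `cat_dev` (9 age groups, 24 cases, 16 regions, 2 runs = 768 rows,
with receptor-subunit swaps peaking at the 4–6 week critical period);
`human_dev` (30 cases in 6 age bins × 3 runs = 90 rows, 210 cells after
averaging, a compressed version of the same trajectory); `rat_flx`
(normal/1wk MD/flx+1wk MD/flx of 6/6/8/8 animals × 3 runs, with condition
multipliers arranged so that exactly 5, 1 and 3 of the nine features
shift beyond the truth margins while the others stay flat by
construction); and `cat_recovery` (six rearing conditions × 12 cases ×
3 regions × 2 runs, each condition pairing an overall expression scale
with a distinct receptor-balance signature). The recovery preset uses 12
cases per condition so that each condition's 36 samples exceed the tSNE
perplexity of 25 — a smaller design would violate the embedding's own
precondition — and its noise (σ_bio 0.10, σ_global 0.05) reflects the
within-condition coherence needed for rearing conditions to be
distinguishable at all, which is the regime the clustering stage is for.
An `effect_strength` knob (strong/moderate/weak) scales the planted
log-multipliers.

What the generator does **not** emulate: correlated noise between
proteins on one blot, run-order drift, age as a continuous covariate
within groups, censored/saturated bands, and the real panels' actual
values. Passing tests therefore demonstrate that the algorithms recover
structure of the assumed form at realistic noise; they do not certify
performance on any particular real dataset.

## Numerical choices and limitations

- Cumulative variance is pinned to exactly 100 at the last component to
  absorb accumulated floating-point error.
- Index colors clip to the scale limits; an all-zero index span renders
  all-yellow with a warning rather than dividing by zero.
- SVG output is deterministic (fixed hash salt, no embedded date), so
  pipeline manifests can checksum figures as well as tables.
- The elbow rule inherits the exponential-decay assumption; WSS curves
  from nested or chain-like cluster structure can bias k* low, which is
  why the fitted τ, the residual and the full curve are always reported
  alongside k*.
- The rat feature panel is a reconstruction (five sums, four indices)
  shipped as an editable preset; analyses of real rat data should review
  its membership before use.
- Hierarchical group counts and the ORA rules are descriptive screening
  devices, not inference with controlled error rates across features.
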