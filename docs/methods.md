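# Methods

## Data model and coordinate conventions

All computation is per chromosome. A `BinTable` holds contiguous,
non-overlapping bins of uniform width (`resolution`, bp; the last bin may
be short), 0-based half-open in bp; bin ordinals are 0-based internally
and 1-based only in human-readable output. Contact matrices are symmetric
and non-negative; zero-coverage rows are **masked, not dropped**, so
ordinals stay aligned with genome coordinates. Masked bins are never
regression candidates and pairs touching them are excluded before any fit.
Supported formats: dense whitespace matrix, sparse 0-based `i j count`
triplets (one triangle suffices; symmetry is enforced by mirroring), and a
minimal single-resolution cooler-style HDF5 container (`bins/`, `pixels/`
groups). Balancing is ICE (iterative correction to equal row sums over
unmasked bins, total mass preserved, relative tolerance 1e-6, capped at
500 iterations with a warning and `balanced=False` on non-convergence).
KR and vanilla-coverage variants are out of scope.

## Pair universe and design matrix

Pairs are the unmasked upper triangle with 1 ≤ j − i ≤ `max_gap`
(default 10 bins). The diagonal is excluded; gap-1 pairs carry no
insulation information but are retained because they anchor the distance
trend at short range. The distance variable is d = log((j − i) ×
resolution) — log bp, not log bins; under uniform bins the two differ
only by an intercept shift. The insulation design X is binary with
X[(i,j), k] = 1 iff i < k < j, *strictly* between — endpoints are not
counted — stored sparse; row sums equal gap − 1 when all bins are
candidates.

## Distance (polymer) trend

`log E[y|d] = β₀ + f(d)` is fit as a negative-binomial GLM on a cubic
B-spline basis of d (default df 8, knots at quantiles of the distinct
distances; with max_gap = 10 the distances take only 10 values, so the
fit is nearly saturated, which is intended — the trend must absorb the
decay exactly, not smooth it). The NB dispersion α is estimated by
method-of-moments iteration from Pearson residuals followed by a bounded
profile-likelihood refinement; α ≤ 1e−8 or a failed NB fit falls back to
Poisson (with a warning in the failure case). At least 50 pairs and one
positive count are required.

## Residuals

Residuals are taken on the log scale with a pseudocount c (1 for raw
counts; half the smallest positive value for normalized input):

    z = log(y + c) − Ê[log(y + c) | d],

where the second term is the *model-implied expected log count* under the
fitted NB/Poisson, computed by the second-order delta approximation
log(μ̂ + c) − Var̂(y)/(2(μ̂ + c)²) with Var̂ = μ̂(1 + α̂μ̂). Subtracting the
raw fitted log-mean instead would leave a Jensen offset E[log(y+c)] −
log μ that grows as counts shrink with distance (≈ +0.05 at gap 10 for
mean 10); because the in-betweenness columns are correlated with gap,
that offset is *predictive* and inflates spurious selections under the
null. The delta correction removes it to O(μ⁻²). A bin's β then remains
interpretable as an additive effect on log contacts, matching its reuse
inside the Poisson prediction model.

## L0 best-subset selection

The working objective is (1/N) Σ (z − β₀ − Xβ)² + λ‖β‖₀ with an
unpenalized intercept (handled by centering). The solver is
coordinate-wise hard thresholding: coordinate j enters with its OLS
update iff its squared partial correlation exceeds λ·N·G_jj, cycled to
convergence, followed by an exact OLS polish on the final support and a
*swap local search* (try replacing each selected coordinate by the best
excluded one; accept improvements; re-descend). The swap step matters:
adjacent in-betweenness columns are nearly collinear and plain cyclic CD
systematically parks on the lower-indexed neighbor of a true border.
For ≤ 12 candidates the default (`algorithm="auto"`) switches to exact
exhaustive enumeration (subset OLS solutions are cached across the λ
grid, so the path costs one enumeration).

The λ grid has 50 log-spaced values from just above the data-driven entry
threshold max_j c_j²/(N G_jj) down to 1e−4 of it. Model size along the
path is capped (default 100) — grid points past the cap are never
selected. 10-fold CV assigns pairs to folds by a seeded shuffle
(default seed 1789) and evaluates validation MSE along the path with warm
starts (path fits use plain CD; the final fit at the chosen λ uses the
full local search). **λ selection uses the one-standard-error rule**: the
largest λ whose mean CV MSE is within one SE (across folds, at the
minimizer) of the minimum. The plain minimizer is available
(`selection_rule="min"`) but is a near coin-flip between the empty model
and 1–6 spurious bins on null data, because those models differ by less
than the CV noise floor; the 1-SE rule returns the empty model on null
matrices essentially always while leaving planted-effect recovery
unchanged (measured: 20/20 empty nulls; 8/8 borders, 2/2 facilitators, 0
false positives over 10 fixture seeds).

When more than `prefilter_trigger` (default 5000) candidates exist, a
10-fold cross-validated lasso prefilter keeps bins with |coefficient| >
0.2 before the L0 stage; below the trigger the candidate set passes
through unchanged. On fixture-scale problems the prefiltered and
unprefiltered pipelines select identical supports.

Borders are tiered: strong β̂ < −2, moderate −2 ≤ β̂ < −1.2, weak
−1.2 ≤ β̂ < 0; positive β̂ are facilitators. For human-readable output,
selected border bins ≤ 1 bin apart are additionally merged into "border
regions" (per-bin βs untouched).

## Differential model (DIM)

Each experiment is fit by SIM independently; the retained set S is the
union of nonzero-β bins, deduplicated so that within any run of
consecutive bins only the bin with the larger max |β̂| across the two fits
survives (ties to the lower index) — this prevents the same border being
counted at adjacent positions in the two experiments. Residuals come from
each experiment's **own** distance trend, so depth and decay differences
cannot masquerade as differential insulation; the experiment main effect
β_e absorbs any remaining global offset. The stacked model
E[z|S,e] = β₀ + Sβ_S + β_e e + Σ β_{s_j e} s_j e is ordinary least
squares with classical standard errors; interaction p-values are BH
adjusted over the |S| tests. Interaction columns that are all-zero or
collinear with their main effect (bin spans pairs in only one experiment)
are dropped with a warning and reported as zero. Applying DIM to a matrix
against itself yields interaction coefficients that are zero to machine
precision, and swapping the experiment labels negates them exactly.

Calibration caveat: the interaction t-tests assume homoscedastic
residuals, but log-scale residual variance grows as counts shrink — with
distance, and on border-crossing pairs. At deep coverage (the regime of
real differential Hi-C studies; the synthetic differential study uses
≈500 expected counts at gap 1) the null raw-p < 0.05 rate measures
≈0.05–0.08; at shallow coverage (≈100 at gap 1) it inflates to ≈0.14.
Differential calls from shallow data should be treated with caution.

## Prediction model (PIM)

Counts are modeled directly: log E[y|d,X] = β₀ + β_d d + Xβ_X, Poisson
GLM with *all* bins as dense insulation variables (no L0 — sharp
selection is unnecessary for prediction; a config option restricts to
SIM-selected bins for speed). Columns spanning no pair are dropped as
unidentifiable. Normalized counts are rounded with a warning and a
quasi-Poisson scale is reported as an overdispersion diagnostic;
non-convergence triggers a ridge-stabilized refit (L2 = 1e−6).

Rearrangements are ordered deletion/inversion operations on bin
intervals, composed left-to-right with coordinates on the
already-rearranged genome; bp inputs are snapped to bin boundaries with a
warning. The engine derives the surviving bin order, rebuilds the pair
universe within max_gap on the new bin table, recomputes d′ from the new
genomic distances (a deletion between a pair shrinks their distance by
the deleted length) and the in-betweenness indicators X′ on the new
order, with columns still keyed to original bins so trained coefficients
carry over; deleted bins' columns vanish. Applying an inversion twice is
an exact involution on (d′, X′). Prediction is entry-wise
exp(β̂₀ + β̂_d d′ + X′β̂_X), assembled symmetrically; an empty
rearrangement reproduces the training fitted means.

Metrics: Pearson correlation of log(counts + 1), Spearman of counts, and
the stratum-adjusted correlation — per-gap Pearson coefficients combined
with weights proportional to stratum size × the product of rank standard
deviations (HiCRep-style; no 2D smoothing by default, enableable).
Strata that are constant (to relative tolerance 1e−10) are skipped;
with < 3 usable strata the SCC is flagged undefined.

## Insulation score baseline

IS_i = log2(M_i / mean M), M_i the total count over pairs strictly
spanning bin i within max_gap. Because the two terminal bins are never
strictly spanned, the mean is taken over bins where M is defined
(unmasked, M > 0); bins with M = 0 get NaN and a mask flag. Scaling all
counts leaves IS unchanged, and Σ 2^{IS}·mean reconstructs Σ M exactly.

## Synthetic generator

The truth model mirrors the regression: log μ_ij = β₀ − α·log(dist_ij) +
Σ_{i<k<j} β_k with a pure power-law decay (so the spline trend has a
closed-form target), planted per-bin effects, and Poisson,
negative-binomial (gamma-mixture) or no noise. Defaults: p = 200 bins at
25 kb, α = 1, β₀ chosen for ≈100 expected counts at gap 1, 8 borders with
β ∈ [−2.5, −1.0] and 2 facilitators (+1.5, +1.0) — the scale of a deep
25 kb human map over ~5 Mb. Mutant matrices are drawn from the truth
evaluated on rearranged coordinates (deleted bins leave the effect map;
inverted bins carry their effects along). The generator reproduces
exactly under a seed.

What the generator does *not* emulate: A/B compartments, loop dots,
nested TAD hierarchies, coverage biases, and between-replicate
variability. Passing tests therefore demonstrate correctness of the
estimators under the stated model class, not robustness to every artifact
of real Hi-C.

## Problem sizes and numerical choices

The synthetic studies use: exact-L0 verification on 30 problems with
3–12 candidates and ≤ 500 pairs against brute-force enumeration
(objective tolerance 1e−8); recovery and prefilter fidelity on the
default 200-bin fixture over 10 and 20 seeds; null specificity over 20
seeds; differential power and calibration on 100-bin, depth-500 pairs
over 50 seeds each; Poisson-model recovery on 20 stacked replicate
matrices (p = 100, max_gap = 10, ≈18.9k pairs); prediction scoring on
single wild-type/mutant pairs (10-bin deletion, 40-bin inversion).
Degenerate inputs are handled explicitly: all-zero counts error; a
single positive count exercises the Poisson fallback; constant counts
give a flat trend and zero effects; empty candidate sets return all-zero
fits.

## Known limitations

- Per-chromosome, cis-only, within max_gap; no trans contacts.
- Covariate-adjusted fitting of unnormalized data (GC, mappability,
  fragment length) is not implemented; input should be balanced, or raw
  with the understanding that coverage biases fold into the βs.
- DIM supports exactly two conditions without replicates; variance is
  pooled classically (see the calibration caveat above).
- PIM handles deletions and inversions only — no duplications or
  translocations — and reuses wild-type coefficients unchanged, so
  rearrangements that create genuinely new regulatory contacts beyond
  the additive-insulation model are out of reach.
- Best-subset selection is conservative by construction: fewer, confident
  borders rather than exhaustive catalogs.
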