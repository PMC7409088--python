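# Methods

## Data model

Responses are subjects × items matrices of ordinal categories 1..C
(C = 4 for the PAI-CY 7–12), one matrix per respondent role (child
self-report, parent proxy-report) and occasion (test, retest), sharing
an item catalog of 55 items in 9 domains. "Not applicable" is treated
as missing; on disk, blank cells and the token `NA` are missing. The
published per-item summary (missing %, category distribution, test-
retest agreement and weighted kappa per role, child–parent concordance
per item) is packaged as a CSV fixture, transcribed column-for-column;
two cells printed without decimals (17, 13) are stored as 17.0/13.0,
and the braille item's dashes as missing values.

## Screening rules

All thresholds are strict inequalities on fractions of the relevant
denominator:

| rule | default | denominator | consequence |
|---|---|---|---|
| missing in both roles | > 0.40 | all subjects | automatic deletion |
| missing in both roles | > 0.20 | all subjects | flag only |
| floor/ceiling (first/last category) | > 0.70 | non-missing subjects | flag only |
| inter-item Spearman | > 0.7 | pairwise complete | flag only |
| corrected item-total Spearman | < 0.3 | see below | flag only |

Only the 40%-in-both rule deletes automatically; all other flags feed a
human consensus decision passed in as an explicit roster. This
reproduces a development workflow in which statistical criteria
nominate items but content experts decide. The corrected item-total
score is the per-subject mean of the *other* items' observed responses
(person-mean rest score), avoiding the part–whole inflation of the
uncorrected version; Spearman is used throughout because the scale is
ordinal. Cronbach's α uses complete cases only and is flagged
unreliable below 30 complete cases (undefined below 3). α is computed
on the raw 4-category scale by default; reliability statistics likewise
use the original scale, and the top category is collapsed into the
third only before network extraction, matching the order of the
development workflow.

## Reliability statistics

Percentage agreement and weighted kappa compare test with retest per
role; pairs with any missing member are dropped. Kappa uses linear
disagreement weights |i−j|/(C−1) by default — the conservative common
choice for a 4-category scale — with quadratic available; when both
raters are constant on the same category the chance expectation is
degenerate and kappa is undefined (agreement is still reported).
Interpretation bands: kappa > 0.4 moderate, > 0.6 good, > 0.8 very
good; agreement ≥ 60% moderate, ≥ 75% good, ≥ 90% excellent.

Child–parent concordance is the two-rater Kendall W with the tie
correction (midranks; T_j = Σ(t³−t) over tie groups of rater j). W > 0.7
counts as adequate; for checks against printed two-decimal values the
rule is applied at printed precision (≥ 0.70), since a printed 0.70 can
hide an unrounded value above the threshold. Confidence intervals are
percentile bootstrap (default B = 2000) over dyads, keeping the
child–parent pairing; BCa was deliberately left out as the percentile
interval is the simplest method consistent with how such intervals are
usually reported for W.

## Network extraction

The Spearman matrix over pairwise-complete observations can be
indefinite, so the precision matrix is estimated by a ridge-penalized
Gaussian likelihood with a positive-definite guarantee. With target T
(default: identity scaled by p/trace(R), i.e. the identity for
correlation input — a rotation-equivariant choice) and A = R − λT, the
stationarity condition Ω⁻¹ − R − λ(Ω − T) = 0 is solved in the
eigenbasis of A: each eigenvalue d of A maps to precision eigenvalue
1/(d/2 + √(d²/4 + λ)), which is positive for any real d and λ > 0. The
estimating-equation residual is the implementation's correctness
oracle (‖Ω̂⁻¹ − R − λ(Ω̂ − T)‖_F < 10⁻⁸ across random instances).

λ is selected on a log-spaced grid (default 200 points on
[10⁻⁴, 10²]) as the smallest value whose estimate loses at most
`max_digits` = 2 digits of accuracy, measured as log₁₀ of the spectral
condition number of Ω̂(λ). Smallest-compliant-λ means least shrinkage
subject to numerical stability; the full (λ, κ) path is returned for
inspection.

Edge support uses a local false discovery rate on the off-diagonal
partial correlations r: f(r) = η₀ f₀(r; k) + (1 − η₀)·½ on (−1, 1),
where f₀(r; k) = (1 − r²)^{(k−3)/2} / B(½, (k−1)/2) is the density of a
sample correlation under independence at k effective degrees of
freedom. k is *estimated* jointly with η₀ by maximum likelihood (coarse
grid over η₀ ∈ [0,1] × log k ∈ [log 4, 5·log 10], then L-BFGS-B
refinement, tolerance 10⁻⁶) rather than fixed at n − p − 1, because
ridge shrinkage changes the null spread of the partial correlations.
The posterior probability an edge is present is (1 − η₀)·½ / f(r),
monotone in |r|; edges are retained when it is ≥ 0.75 (inclusive).
Degenerate inputs (all partials identical) yield η₀ = 1 and an empty
network. Undefined pairwise correlations (fewer than `min_pairs` = 3
complete pairs) are imputed as 0 with a logged warning instead of
aborting, so heavily missing items can still be carried.

## Comparison and layout

Edge identity for the shared/unique partition is the unordered item
pair; weights and signs are ignored for identity but preserved on the
edges (positive drawn solid, negative dashed; nodes colored by
domain; isolated nodes hidden by default). Degree centrality is the
incident-edge count, with ties reported as an item-id-ordered set.
Layout is Fruchterman–Reingold (networkx spring layout, seeded, fixed
iteration count); when reference coordinates are given they are reused
verbatim rather than warm-started, so the self- and proxy-report
panels have identical node placement.

## Synthetic generator

The generator is a latent-Gaussian threshold model — the simplest
generative process whose true conditional-independence graph is known
and whose monotone latent structure matches the Spearman-based
pipeline. A sparse precision matrix with unit diagonal is drawn from an
Erdős–Rényi support at the requested density; edge entries are set so
edge partial correlations equal ±magnitude exactly, and the graph and
signs are re-drawn (up to 100 attempts) until the matrix is positive
definite. Child latents are multivariate normal with the implied
correlation; the parent latent for each item is
ρ_c·(child) + √(1−ρ_c²)·(independent draw from the parent's own
structure), and retest latents blend the test occasion at ρ_t
analogously. Latents are cut at per-item thresholds into categories;
cells are then deleted MCAR, with optional per-item "not applicable"
blocks that remove a whole item for a random subject subset.

Defaults describe a desk-scale study in seconds: p = 20 items,
n = 200 dyads, density 0.1, |ρ| = 0.4, category probabilities
(0.65, 0.25, 0.08, 0.02) — a strong floor with a rare top category,
the dominant shape of the real response distributions — concordance
ρ_c = 0.5 (most real items fall below the 0.7 adequacy bar), retest
ρ_t = 0.75, 5% MCAR missingness. No published effect-size scale exists
for the real item partial correlations, so the magnitude is a
convention, not an estimate.

What the generator does *not* emulate: informative (non-MCAR)
missingness, acquiescence/extreme response styles, mode effects
(interview vs web), or non-Gaussian copulas. Passing recovery tests
therefore show the pipeline works under a well-specified monotone
latent model, not that the real study's edges are certain.

## Problem sizes in checks

The packaged performance checks use: 100 random instances for the
estimating-equation residual; 2000 draws for local-FDR recovery;
p = 20, n = 1000, 20 replicate structures for edge recovery (observed
mean sensitivity and precision ≈ 0.87–0.92, threshold 0.8); 200
replications × 300 bootstrap resamples at n = 100 dyads for W interval
coverage (observed ≈ 0.94–0.96), with the "true" W taken from a one-off
n = 200 000 draw of the same process because no closed form exists
under ties; and n = 10⁵ for marginal calibration of the generator
(tolerance 0.01).

## Known limitations

- The exact shrinkage target and penalty grid of any particular
  published analysis are not identifiable from summary tables; results
  on real data reproduce in distributional/property terms, not
  edge-for-edge.
- The local-FDR alternative is uniform on (−1, 1); heavy concentrations
  of true effects near the null will bias η₀ downward slightly (the
  mixture simulations recover η₀ = 0.9 to within ±0.05).
- Recounting "floor in either role" or ">20% missing in either role"
  from printed, rounded percentages does not always match prose counts
  in published tables; only both-role counts are treated as exact.
- Cronbach's α on complete cases can rest on very few subjects under
  heavy missingness; the reliability flag (n < 30) must be checked.
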