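# Methods

This note documents the models implemented in `palaeosom`, the choices
made where the methods literature leaves details open, and what the
synthetic-data generator does and does not emulate.

## Self-organising map

Input is the ln(x+1)-transformed assemblage matrix of the non-empty
samples (all-zero slices carry no assemblage information and are removed
first; they reappear as explicit "barren" zones in the zonation output).
The natural log is the default; log10 is available (`log_transform(...,
base="log10")`) and changes the codebook only by a uniform scale factor.

The output layer is a rectangular lattice with neuron index = row-major
`(row, col)`. Its size targets `round(5·√n)` neurons; among factor pairs
`rows ≥ cols` with aspect ratio ≤ 1.5 the pair minimising
`|rows·cols − target|` is chosen, ties going to the smaller product and
then the smaller row count. For n = 79 this yields 7 × 6 = 42. The
aspect-cap minimisation is this package's documented convention for
factoring the target into a grid; nothing deeper is implied by it.

Training is the batch algorithm (no learning-rate parameter): per epoch
every sample is assigned to its best-matching unit (BMU, Euclidean, ties
to the lowest index) and every codebook vector is replaced by the
Gaussian-neighbourhood-weighted mean of all samples, the kernel acting on
Euclidean distance between integer grid coordinates. The radius shrinks
linearly from `max(rows, cols)/4` to 1 over 10 rough epochs, then from 1
to 0.5 over 40 fine epochs (all config-exposed). Initialisation is linear
— codebooks span the first two principal axes of the data, scaled by the
corresponding standard deviations — with a seeded uniform-random fallback
for degenerate inputs. Two limiting behaviours pin the implementation
down and are asserted in tests: with an effectively infinite radius every
codebook collapses to the global mean, and with radius → 0 one batch step
equals one k-means Lloyd iteration on neuron cells (cells left empty keep
their previous vector). Quality diagnostics are the mean sample-to-BMU
distance (quantization error) and the fraction of samples whose two
nearest neurons are not lattice neighbours (topographic error; defined as
0 on a single-neuron map).

## Neuron clustering, labels, zonation

Codebook vectors are clustered with Ward's minimum-variance method on
Euclidean distances (scipy linkage). One dendrogram is cut at k = 2
(clusters) and k = 4 (subclusters); cutting a single tree guarantees
nesting, which is asserted anyway. k-cuts rather than height cuts are the
reproducible convention. Neurons without assigned samples are clustered
like any other — their codebooks are valid virtual samples — but
contribute nothing downstream. Subclusters are ordered by the number of
significantly associated indicator taxa (ascending; ties by total IndVal
sum, then subcluster id), and renamed with cluster letters in gradient
order and numbers within clusters (X1 ≤ X2 ≤ Y1 ≤ Y2 in the canonical
2 + 4 case; an uneven cut such as 3 + 1 yields X1..X3, Y1). Zonation
merges consecutive same-label depths per core, reporting depth and age
spans; barren samples form their own zones so that mostly-empty cores
remain interpretable.

## Indicator value analysis

Computed on untransformed counts. Specificity uses within-subcluster
*mean* abundances, making it insensitive to unequal subcluster sizes;
taxa with zero total abundance get an all-zero specificity row. IndVal is
in [0, 100] and attains 100 exactly when a taxon occurs in every sample
of one subcluster and nowhere else. Significance attaches to each taxon's
maximum IndVal: subcluster labels are shuffled across samples (sizes
preserved) and the maximum recomputed; the estimator
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)` includes the observed table so p
is never 0. Default `n_perm = 4999`. Tier summaries count taxa in the
disjoint bands p ≤ 0.001, (0.001, 0.01], (0.01, 0.05], attributing each
significant taxon to its argmax subcluster. Only subclusters are tested;
testing the two top-level clusters as groups is not done by default.
Measured calibration: under label-independent data the test rejects at
rate 0.052 at α = 0.05 (1000 null datasets, n_perm = 199), within the
99% binomial interval.

## Canonical correspondence analysis

Species preparation follows the classic CANOCO options: square-root
transform, then optional downweighting in which a taxon occurring in
fewer than `f_max/5` samples is multiplied by `f/(f_max/5)`. The CCA
itself: chi-square standardisation `Qbar = (P − r c')/√(r c')`, row-
weighted regression of `Qbar` on the weighted-standardised environment
matrix, SVD of the fitted part. Total inertia is `‖Qbar‖²` (the species
table's chi-square statistic over its grand total); constrained inertia
is the fitted sum of squares. Axis percentages are reported against both
(species-data variance and species–environment relation). Scaling 1
(inter-sample distances) is the default: site scores are scaled by the
singular values, species scores unit-scaled; biplot arrows are weighted
correlations of the (standardised) variables with the unit site scores.
Eigenvalues agree with scikit-bio's CCA and with a direct generalised-
eigenproblem solution to 1e-8, and a saturated constraint set reproduces
plain CA axis-for-axis.

Per-variable "marginal" percentages come from single-constraint CCAs
(constrained inertia over total inertia); sequential (conditional)
effects are not the default because marginal effects are the
interpretable per-variable summary when the selection order is unknown.
The permutation test of a variable uses the pseudo-F
`(constrained/q) / (residual/(n−q−1))`; under the default
`method="full"` the response is rebuilt from row-permuted residuals of
the fitted model (ter Braak's permutation-under-the-full-model), with
free row permutation as the alternative. The collinearity screen is
greedy: while any |r| exceeds 0.9 the member of the worst pair with the
larger mean absolute correlation is dropped; constant columns are
excluded up front. Samples with missing geochemistry are dropped from the
ordination only, never from the SOM or IndVal, keeping each analysis
maximally powered. Detrended correspondence analysis is deliberately not
implemented; when a gradient-length diagnostic is wanted, the CA axis
lengths of the unconstrained solution serve as a proxy.

Geochemical ratio indices (Na/K, Fe/Mn, Cu/Zn, Ca/Mg, TOC/N) are exact
quotients of the input columns; zero denominators yield flagged NaNs.
Reference means for the flags default to Na/K = 0.12, Fe/Mn = 60,
Cu/Zn = 0.27, and TOC/N < 20 flags a predominantly algal organic-matter
source.

## Among-core count model

The long table zero-fills the full core × age-category × taxon grid.
Samples are restricted to cores with overlapping modelled ages and to the
common age window; ages are quantile-binned (default 6 levels), and an
age category empty in any core raises an error advising fewer levels. By
default one row per sample × taxon is kept with offset ln(sample volume);
aggregation to (core, age, taxon) cells with ln(summed volume) offsets is
optional. The model is a fixed-effects Poisson GLM with log link
(statsmodels IRLS behind the module surface, converged to 1e-10 relative
deviance change): age enters as a fixed main effect rather than the
random effect a full mixed model would use — the post-hoc contrasts
require the fixed-effects path in any case, and random-effect variance
estimation is out of scope. Candidate structures are ranked by
`AICc = −2LL + 2k + 2k(k+1)/(n−k−1)` with n the number of rows, and
Akaike weights from ΔAICc. Post-hoc contrasts take, per taxon and core
pair, the core difference in linear predictor minus its across-taxa mean
(the interaction content only, reference-free); Wald chi-square p-values
are Holm-adjusted and taxa ranked by absolute contrast. Core × taxon
cells with zero total counts make the corresponding interaction effects
weakly identified; they are warned about at fit time, and their contrasts
are flagged `identified=False` and ranked last.

## Synthetic-data generator

The generator emulates a multi-core moat-fill study design: 4 cores of
20–30 contiguous 2–4 cm slices (100 samples), 97 taxa, per-slice totals
of 50–100 head capsules, sample volumes 5–70 cm³, 21% barren slices
(79 non-empty), 4 ecological states ordered unfavourable → favourable,
and 57% of taxa planted as indicators — none for the harshest state,
proportionally more for the favourable ones (9/18/28 by default),
mirroring a rising richness gradient.

Counts are multinomial conditional on a uniform total (fixed counting
effort), with optional Dirichlet-multinomial overdispersion. Fidelity f
is the per-sample presence probability of an indicator inside its own
state (its mass is zeroed with probability 1−f before the draw);
specificity a is the fraction of the taxon's expected abundance mass
inside its state, with (1−a)/(n_states−1) leaking to each other state, so
a = f = 1 gives exact absence outside the state and IndVal 100 under true
labels. Non-indicator taxa have state-constant expected shares, and each
state's indicator group carries the same total mass, so diffuse taxa sit
near the permutation null; the residual state dependence of row
normalisation (the no-indicator state has less indicator mass to absorb)
leaves them with a small induced association, and the realised indicative
fraction at study scale is roughly 0.45–0.65 across seeds rather than
exactly 0.57. Geochemistry is state-conditional normal (truncated at
physical bounds: pH in [3, 10], percentages in [0, 100]) with pH, OM, Ca,
Pb, Fe, Cu, K tracking the state gradient, built-in collinear pairs
Na ≈ 0.12·K and Mg ≈ 0.35·Ca for the screening step, Mn and Zn loosely
tracking Fe/60 and Cu/0.27 so the ratio indices sit near their reference
means, and TOC/N low in the limnetic states. Ages are linear in depth per
core with Gaussian noise; no radiocarbon machinery is emulated.

What passing tests on these data do **not** show: robustness to
taphonomic loss or transport, to counting error correlated across taxa,
to non-normal geochemical noise, or to age–depth model misspecification —
none of which the generator produces. The multinomial totals also induce
mild within-sample count correlation that a Poisson GLM ignores; the
AICc experiments show this does not spuriously favour the interaction
model at the sizes used.

## Problem sizes and numerical conventions

Validation experiments are scaled to desk size: oracle equivalences use
≤ 10 × 5 matrices (200 instances), Ward comparisons ≤ 8 items,
permutation calibration 1000 datasets at n_perm = 199, and the recovery
experiments 20 seeds at 100 samples × 97 taxa (SOM/CCA) or 3 cores × 12
slices × 15 taxa with 3 age levels and 1-yr age noise (AICc selection —
small enough that quantile age bins stay occupied in every core).
Tie-breaks are everywhere "lowest index" for determinism; all randomness
flows through explicit seeds; permutation p-values use the (b+1)/(n+1)
estimator; IRLS runs to 1e-10 relative deviance change (max 100
iterations); CCA eigenvalues below 1e-12 of the leading one are treated
as null space.

## Known limitations

- Hexagonal lattices, growing grids and supervised SOM variants are not
  offered; the lattice is rectangular by design.
- No stratigraphically constrained zonation (CONISS/optimal partitioning);
  zones follow the SOM subcluster labels only.
- No partial CCA with covariables and no variance partitioning beyond
  marginal single-variable effects.
- The count model offers no negative-binomial or zero-inflated families
  and no random effects; strong overdispersion would have to be judged
  from deviance diagnostics by the user.
- IndVal is computed per subcluster only, not over unions of subclusters.
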