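# Methods

This package implements, as reusable library code, the three analysis
stages of an integrative-taxonomy workflow for shelled pteropods
(*Cuvierina*-type planktonic gastropods): shell-outline geometric
morphometrics, population-genetic statistics on aligned COI/28S
sequences, and presence-only ecological niche modelling with
niche-overlap statistics. A synthetic-data module generates inputs with
the statistical structure these analyses assume, so the full pipeline is
testable without any external download.

## Geometric morphometrics

**Semi-landmarking.** *Cuvierina* shells carry no true landmarks, so
shape is captured by semi-landmarks placed at equal arc-length intervals
along the digitized outline. Ventral outlines are open curves running
from one aperture-edge transition around the septum to the other; they
are resampled to 75 semi-landmarks (`resample_outline`), with one extra
fixed landmark at the top of the aperture appended afterwards, giving 76
points per ventral configuration. Apertural outlines are closed curves
resampled to 35 points starting at the mid-aperture anchor. Open curves
use arc positions `i*L/(k-1)` so both anchors are retained exactly;
closed curves use `i*L/k`.

**Superimposition.** Generalized least-squares Procrustes analysis
(`gpa`) centers each configuration, scales it to unit centroid size
(CS = sqrt of summed squared distances to the centroid), and iteratively
rotates all configurations to the running consensus using proper
rotations only (reflections are excluded by sign-fixing the SVD
determinant). Iteration stops when the consensus moves by less than
1e-10; the cap is 1000 iterations, which covers even mutually very
dissimilar configurations, for which convergence is slow and linear.
Original centroid sizes are retained as the size variable.

**Relative warps.** `relative_warps` is a principal-component
decomposition of the flattened aligned coordinates with uniform
weighting (no bending-energy exponent), because the workflow uses
non-sliding semi-landmarks and PCA-like variance fractions. All
`min(n-1, 2k)` axes are returned by default; the four similarity
dimensions removed by superimposition simply carry numerically zero
variance, and an explicit axis count can be requested where a fixed
dimensionality (e.g. 2k-4) is wanted. Axis signs follow the convention
that the largest-magnitude loading is positive.

**Repeatability.** Duplicate digitizations of the same specimens are
compared per feature with the two-way absolute-agreement single-measure
intraclass correlation,

    ICC = (MS_R - MS_E) / (MS_R + MS_E + 2 (MS_C - MS_E) / n),

the conservative choice when the precise estimator of the original
software is unknown. Features pass the screen when ICC strictly exceeds
0.80; an empty selection is an error because downstream stages need at
least one feature.

**Classification.** `lda_fit_assign` is classic linear discriminant
analysis with pooled within-class covariance and equal priors
(scikit-learn backend); a near-singular pooled covariance raises an
error advising feature reduction. `jackknife_confusion` runs
leave-one-out cross-validation and tabulates true-by-assigned counts;
singleton classes cannot be left out and refit, and are flagged.

**PerMANOVA.** Group differentiation is tested on Euclidean distances:
`SS_total = (1/N) Σ_{i<j} d²`, `SS_within` pools per-group terms, and
the pseudo-F statistic `(SS_among/(a-1)) / (SS_within/(N-a))` is
referred to its permutation distribution (label reshuffles, +1
convention so p is never 0). For univariate input the statistic equals
the classical one-way ANOVA F exactly. The feature table is used raw by
default, matching common practice of analysing CS plus RW scores
directly; a `standardize` flag z-scores columns first for cases where a
size variable in millimetres would otherwise dominate the distances (the
pipeline uses this mode because synthetic CS ranges dwarf unit-size RW
scores). Multiple simultaneous tests are corrected with the sequential
Bonferroni (Holm step-down) procedure at initial alpha 0.05.

## Sequence statistics

Distances are uncorrected p-distances with pairwise deletion: positions
carrying a gap, N, or any non-ACGT symbol in either sequence of a pair
are excluded for that pair. Haplotypes are distinct full-length strings
(sequences with ambiguity codes collapse only when identical as
strings); S counts columns with at least two distinct unambiguous bases;
haplotype diversity uses the n/(n-1) small-sample correction; nucleotide
diversity is the mean pairwise per-site distance, so it equals the mean
off-diagonal of the distance matrix by construction.

The fixation index phi_ST comes from an AMOVA on raw pairwise
difference counts used as squared distances ("pairwise differences"
option, no gamma correction): within- and among-group sums of squared
deviations give variance components with the standard unequal-sample-
size coefficient, and significance comes from permuting individuals
among groups with group sizes fixed (10 000 permutations by default, +1
convention). For eight or fewer sequences the permutation distribution
is verified against exhaustive enumeration in the test suite.

The pseudogene screen translates the protein-coding locus in a stated
reading frame under a named NCBI code table (default invertebrate
mitochondrial, table 5, in which AGA/AGG encode serine) and reports
internal stop codons and gap characters; sequences pass only when both
counts are zero. Neighbor-joining (scikit-bio backend, taxa sorted for
deterministic tie-breaking, negative branch lengths clipped at zero) is
provided as a visualization aid only; likelihood and Bayesian
phylogenetics are out of scope. `clade_partition` operationalizes
"major clades separated by deep divergence" as connected components of
the graph with edges d < threshold (single linkage), with 0.03
substitutions/site as the working threshold between within-clade
(≤ 0.02) and between-clade (≥ 0.045) distance ranges.

## Ecological niche modelling

The niche model is a minimal maximum-entropy (Gibbs) density over
background cells: `q(cell) ∝ exp(Σ_j λ_j f_j(cell))` with linear and
quadratic features of each layer scaled to [0, 1] over the background.
Full maxent "default settings" include feature classes and tuning rules
that are not reproducible in a clean-room build; linear + quadratic
features capture the unimodal response curves that matter here while
keeping the fit a deterministic convex optimization. Coefficients
minimize the L1-penalized presence log-loss. The default penalty per
feature is `0.05/sqrt(m)` (m = presence cells), vanishing as presences
accumulate; at β = 0 the fit reduces to exact moment matching (fitted
feature expectations equal presence-sample means, the maxent KKT
condition, verified to 1e-4). Numerically, the unpenalized problem is
solved directly by L-BFGS-B on the smooth objective; with L1 penalties
each coefficient is split into positive and negative parts (warm-started
from the unpenalized solution) so the objective stays differentiable.
The split formulation alone has a flat ridge at β = 0 on which L-BFGS-B
can stall — hence the direct path.

Occurrences are snapped to cell centers and deduplicated to one record
per cell by default. Background is all ocean cells. Response curves
evaluate the model along one variable's observed background range with
the other variables held at background means, clamped at the range
endpoints (no extrapolation). Variable importance is the drop in mean
presence log-likelihood when the model is refit without a variable,
normalized to sum to 100% — a deterministic leave-one-variable-out gain,
explicitly not the path-dependent "percent contribution" heuristic of
other maxent software; refits reuse exactly the presence cells of the
full model so likelihoods are comparable.

Model accuracy is the rank-based presence-versus-background AUC
(Mann-Whitney with midrank ties). Significance uses the presence-only
null-model approach: the observed training AUC is ranked against AUCs of
models refit on random draws of equally many points from the known
sampling locations — correcting for collection bias — with 99
randomizations by default, so p has resolution 0.01 and is 0.01 when the
observed model ranks first. Niche overlap between two fitted surfaces is
Schoener's `D = 1 - 0.5 Σ |p1 - p2|` after renormalizing both surfaces
over the shared ocean cells; D is 1 for identical and 0 for disjoint
niches.

Layer screening utilities (Spearman rank correlations and PCA of
z-scored layers) report collinearity; variable selection itself is left
to the user.

## Synthetic data

**Shells.** A morphotype is a parametric ventral profile: half-width at
axial fraction t (0 = septum, 1 = aperture) is a linear baseline from
septum width to aperture width plus a beta-like bump
`t^(a-1) (1-t)^(b-1)` normalized to peak 1, with `a = 1 + r·p`,
`b = 1 + r·(1-p)` so the mode sits exactly at `p = max_width_pos` and
`r` (roundness) controls peakedness. This two-parameter family spans
cylindrical shells (bump ≈ baseline, mid-shell maximum) to bottle shapes
(pronounced bump low on the shell). The septum is closed by a
semicircular cap. Default sizes follow the field situation: adult shell
lengths 6–11 mm across morphotypes, length SD 0.4–0.5 mm within a
morphotype. Per-individual variation is a length draw plus optional
multiplicative jitter of the width fractions (2% relative SD in the
pipeline defaults); digitization noise is Gaussian per point with SD
0.02 mm, a small fraction of shell size, since the magnitude of real
digitization error is a free parameter here. Repeat digitization series
add fresh noise plus a random re-rotation (≤ 2°) and re-translation.

**Sequences.** A two-level star model: a random ancestor, deme
ancestors mutated at Poisson(between_divergence × L) sites, individuals
mutated from their deme ancestor at Poisson(within_divergence × L)
sites, under Jukes-Cantor (the simplest model sufficient for testing
distance, diversity and phi_ST code; richer models belong to tree
inference, which is out of scope). Sites can be hit more than once, so
realized p-distances are checked against oracles, not against nominal
branch lengths. The default fragment is 658 bp, the COI barcode length;
divergence defaults (0.01 within, 0.05 between) mirror the observed
within-clade (≤ 2%) versus between-clade (4.5–5.1%) distance ranges.

**Environments.** Each layer is a linear gradient plus Gaussian noise on
a rectangular grid with an ocean mask (all-ocean by default, optional
land fraction). Default gradient directions are spread over a half-turn
so no two default layers are collinear — emulating a set of
pre-screened, weakly correlated layers. True suitability is a separable
Gaussian in layer values, normalized to sum 1 over ocean cells;
presences are cells drawn with that probability (with replacement, as
repeat collection records); sampling locations are drawn uniformly
without replacement, giving the fixed candidate pool the null model
requires.

What the generators deliberately do not emulate: spatial
autocorrelation of sampling effort, coalescent genealogies with
migration or recombination, 3-D shell geometry, seasonal or
depth-resolved environmental structure, and real coastline geometry.
Green tests therefore demonstrate correctness of the statistical
machinery under the assumed generating processes, not robustness to
every property of field data.

## Problem sizes used in the checks

Oracle-equivalence checks run at n ≤ 12 specimens/sequences with
exhaustive (8!) permutation enumeration for phi_ST. Calibration
experiments use 1000 null PerMANOVA datasets (n = 20, 999 permutations
each, vectorized), 500 panmictic phi_ST replicates (n = 40, 658 bp), and
200 null-model meta-replicates (15×15 grid, 2 layers, 20 presences, 99
randomizations each). Parameter-recovery runs use 50 shells per
morphotype, a 40×40 single-layer grid with 400 presences, and two demes
of 20 sequences. These sizes give stable Monte-Carlo estimates at
desk scale; all are configurable upward.

## Known limitations

- The maxent variant is intentionally minimal: no hinge/threshold/
  product features, no cumulative or logistic output transform, no
  projection onto other layer sets.
- GPA convergence to the global consensus is not guaranteed for
  pathological shape mixtures; the result object flags non-convergence.
- The AMOVA is single-level (among groups / within groups); hierarchical
  designs (regions within groups) are not implemented.
- p-distance pairwise deletion can make the distance matrix slightly
  non-metric when gap patterns differ strongly between pairs; NJ and
  clustering operate on it as given.
- The haplotype-collapsing rule treats ambiguity codes as literal
  characters by default; an `ignore_ambiguous` flag drops columns
  containing any gap or ambiguity before comparison, which merges
  sequences differing only at such columns.
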