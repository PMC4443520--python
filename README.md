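# pterotax

Integrative-taxonomy analyses for shelled pteropods (planktonic
gastropods with aragonite shells, e.g. the genus *Cuvierina*): the
package chains three independent lines of evidence used to delimit
species in the open ocean — shell shape, mitochondrial/nuclear sequence
variation, and ecological niches — into one reproducible pipeline. It is
written for plankton taxonomists and marine evolutionary biologists who
have digitized shell outlines, aligned barcode sequences, and
georeferenced occurrence records, and want the complete statistical
workflow behind them scripted and testable.

## What it computes

**Geometric morphometrics.** Shell outlines (no true landmarks) are
resampled to k equally spaced semi-landmarks (75 ventral + 1 aperture
point; 35 apertural), superimposed by generalized least-squares
Procrustes analysis, and decomposed into relative warps (principal
components of the aligned coordinates). Centroid size
CS = √Σᵢ‖xᵢ − x̄‖² is the size variable. Repeatability of each warp
across duplicate digitizations is screened with the two-way
absolute-agreement intraclass correlation (kept when ICC > 0.80).
Morphotype separation is quantified by linear discriminant assignment
with a jackknifed (leave-one-out) confusion matrix and by PerMANOVA:
pseudo-F on Euclidean distances tested against label permutations, with
sequential-Bonferroni (Holm) correction across tests.

**Population genetics.** Uncorrected p-distances with pairwise deletion;
haplotype diversity H = n/(n−1)·(1 − Σ pₕ²); nucleotide diversity
π = mean pairwise per-site distance; AMOVA-based fixation index
φ_ST = σ²ₐ/(σ²ₐ + σ²ᵥ) from pairwise difference counts, tested by
permuting individuals among groups; a stop-codon/indel pseudogene screen
under the invertebrate mitochondrial code; neighbor-joining trees and
single-linkage clade partitioning of the distance matrix.

**Ecological niche modelling.** A minimal maximum-entropy model:
suitability q(cell) ∝ exp(Σ λⱼ fⱼ) over ocean background cells with
linear + quadratic features, fit by convex L1-regularized likelihood
maximization. Response curves (no extrapolation), jackknife variable
importance, rank-based AUC, a presence-only null-model significance test
restricted to known sampling locations (99 randomizations), and
Schoener's niche overlap D = 1 − ½Σ|p₁ − p₂|.

**Synthetic data.** Parametric shell outlines spanning cylindrical to
bottle-shaped morphotypes, two-level (within/between-deme) Jukes-Cantor
sequence sets, and gradient environments with known Gaussian niches —
so every stage is testable end-to-end with no downloads.

## Worked example

Run the full synthetic pipeline (six morphotypes, three genetic clades
with two Atlantic-style demes, three environmental layers):

```python
from pterotax.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))["stages"]
```

With seed 1 this prints, among other things:

```
morpho:  RW1 explains 81.9% of shape variance, RW2 6.8%
         repeatable features: RW1, RW3, RW4, CS (ICC > 0.80)
         jackknifed LDA: 99.4% correct over 6 morphotypes
         PerMANOVA F = 80.3, p = 0.001 (999 permutations)
popgen:  40 sequences, 40 haplotypes, S = 232, H = 1.000, pi = 0.026
         phi_ST (north vs south deme) = 0.330, p = 0.001
niche:   training AUC 0.80-0.87 per morphotype, null-model p = 0.05
         Schoener's D: 0.55 (adjacent niches), 0.20 (distant niches)
```

Read: the first relative warp carries most of the shape signal
(cylinder-to-bottle contrast), the repeatability screen keeps the warps
that survive re-digitization, the six simulated morphotypes are almost
perfectly recoverable from shape + size, the two demes are
significantly differentiated at the sequence level, and each simulated
morphotype occupies a statistically significant niche that overlaps
moderately with its neighbour's and little with a distant one.

The same stages are available from the shell:

```sh
pterotax simulate --seed 1 --out-dir fixtures/
pterotax morpho --tps fixtures/outlines_ventral.tps \
    --groups fixtures/morphotypes.tsv --n-perm 9999 --seed 1 --out-dir out/
pterotax popgen --fasta fixtures/coi.fasta --partition fixtures/partition.tsv \
    --n-perm 10000 --seed 1 --out-dir out/
pterotax niche --layers fixtures/layers --occurrences fixtures/occurrences.csv \
    --sampling-locations fixtures/sampling_locations.csv --seed 1 --out-dir out/
pterotax run --seed 1 --out-dir out/
```

File formats: TPS landmark files, FASTA alignments, ESRI ASCII rasters,
and tab-delimited tables.

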