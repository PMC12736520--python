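# Methods

This note documents the statistical models and procedures implemented in
`delimetrics`, the defaults they use, and the choices made where several
defensible conventions exist.

## Genetic distances

Pairwise distances use the Kimura 2-parameter (K2P) model, which
distinguishes transitions (A↔G, C↔T; observed proportion *P*) from
transversions (proportion *Q*) and corrects for multiple hits:

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

Sites where either sequence carries a gap or an IUPAC ambiguity code are
excluded **pairwise** (each pair keeps its maximal comparable site set),
rather than by complete deletion; this matches the dominant convention of
distance software used in barcoding workflows. Ambiguity codes are
excluded, not probabilistically resolved. When a log argument is
non-positive the distance is saturated: it is reported as undefined,
masked in the matrix, and excluded from range summaries — never clamped.

A column of the alignment counts as *variable* when it contains at least
two distinct unambiguous bases. All columns, including all-gap ones,
enter the denominator of the variable-site proportion; the convention is
stated here because published tables are usually silent on it.

Distances are proportions internally; every user-facing report multiplies
by 100 and rounds to one decimal, following the percent convention of
barcode-gap tables.

## Barcode-gap evaluation

Strain pairs are labelled intraspecific or interspecific from the
reference taxonomy. Summaries:

- **Range overlap** — overlap width of the intra and inter distance
  ranges divided by the total range, ×100. Symmetric in the two classes;
  undefined (error) when the total range is zero.
- **Overlap-minimizing threshold** — the arithmetic mean of the maximum
  intraspecific and minimum interspecific distance.
- **Identification efficiency** — the fraction of species with a *local
  barcode gap*: maximum intraspecific distance strictly below the
  minimum distance to any other species (singletons use 0 as their
  intraspecific maximum). The local-gap rule is adopted because it is
  the standard species-level criterion in the barcode-gap literature;
  a threshold-based alternative is available through the ROC output.
- **ROC analysis** — interspecific pairs are the positive class. AUC is
  the tie-corrected Mann–Whitney statistic (verified in tests against a
  sweep-based trapezoid ROC and scikit-learn); its 95% CI uses DeLong's
  structural-components variance. The Youden threshold maximizes
  sensitivity + specificity − 1 over midpoints between consecutive
  sorted unique distances, bracketed by the observed extremes so the
  reported threshold always lies inside the observed range; ties resolve
  toward the smaller threshold.
- **Distribution overlap area** — a kernel-free histogram overlap with
  shared Freedman–Diaconis bins, reported separately from the
  range-based overlap because the two answer different questions
  (mass overlap vs range overlap).

## Species delimitation and partition scoring

**Threshold clustering** forms MOTUs as connected components of the
graph joining strains at distance ≤ t (single linkage): the transitive
graph-connectivity reading of "cluster at a distance threshold", and the
variant that is exactly checkable against a brute-force transitive
closure. Complete linkage is available behind a flag. Masked distances
are treated as exceeding any threshold (logged).

**K/θ** compares the mean between-clade pairwise distance K to the
within-clade diversity θ, with the conventional cutoff K/θ ≥ 4 for
distinct species. θ is taken as the **larger** of the two within-clade
mean pairwise distances — the conservative choice toward lumping. With
one singleton clade the other clade's diversity is used; with two
singletons θ is undefined and the verdict is *indeterminate*. The
θ estimator (mean pairwise difference, i.e. π) and the clade choice are
package conventions, stated in the output.

**Partition scoring** classifies each reference species S (strain set R)
against the candidate MOTUs: *match* (one MOTU equals R exactly),
*split* (R spans ≥2 MOTUs, each wholly inside R), *merge* (R is a proper
subset of a single MOTU), *mixture* (anything else). Percentages are
counts over the number of reference species, one decimal. External
delimitation programs (ASAP, GMYC, PTP variants) are deliberately not
re-implemented; their output partitions are consumed as TSV and scored
identically.

## Morphology

Multi-state trait tables are expanded into binary indicator vectors (one
column per state; multi-valued cells such as "ellipsoidal, ovoid" set
several indicators — this preserves shared-state counting for
polymorphic descriptions). Strains with fewer than 80% of traits
determined are excluded (the threshold is exposed as a parameter).
Jaccard distance is computed per pair over the traits determined in
both strains; pairs sharing no determined trait are masked.

The per-trait **Mantel test** correlates (Pearson) the overall Jaccard
matrix with the single-trait matrix, permuting strain labels of one
matrix. The permutation p-value is one-tailed upper with the +1
correction, p = (#{r\* ≥ r} + 1)/(n_perm + 1); 10 000 permutations by
default. The permutation loop is written in-package so that a seed can
be passed explicitly; determinism of every stochastic routine given its
seed is a package-wide contract.

**UPGMA** uses average-linkage agglomeration (SciPy's `linkage`; an
independent naive O(n³) implementation guards it in the tests) and
yields an ultrametric dendrogram written as newick. **PCoA** is
classical scaling: double-centre −D²/2, eigendecompose, keep axes with
positive eigenvalues (cross-checked against scikit-bio).

**Congruence** between a morphological and a phylogenetic distance
matrix is tested twice, as two views of one hypothesis: CADM (Kendall's
W over the two rank-transformed off-diagonal vectors, tie-corrected;
for two matrices W = (ρ_Spearman + 1)/2 up to tie corrections, so chance
expectation is 0.5) and protest (PCoA both matrices, centre and scale to
unit sum of squares, optimal orthogonal rotation, t0 = √(1 − m²)). Both
p-values come from 9 999 label permutations; the pair is Holm-adjusted.
Whether patristic distances should be rescaled before Procrustes is
unsettled in the literature; the implementation scales both
configurations to unit sum of squares, the standard protest convention.

## ITS secondary structures and CBCs

Structures are sequence + dot-bracket (folding itself is out of scope;
any folding server's output can be pasted in). Helices are maximal
stacked runs of pairs, numbered 5′→3′; pair positions within a helix are
counted **from the base** (outermost pair = position 1), following the
convention of published ITS structure diagrams. Canonical pairs are
Watson–Crick plus G·U wobble. Through a pairwise alignment, each pair is
classified identical / CBC (both nucleotides change, pairing kept
canonical on both sides) / hemi-CBC (one changes) / mismatch
(non-canonical pairing at an aligned paired position) / pair lost or
gained. The species-cut rule counts CBCs inside conserved spans —
default: basal 5 bp of helix I, 10 bp of helix II, all of helix III —
and returns *distinct* iff at least one is found. Helix numbering and
spans are user-assignable, because automatic ITS helix homology
assignment is out of scope; whether the basal-counting direction applies
to the rule itself is not fixed by convention, so the spans are
configurable.

## Fatty acids

The unsaturation index is UI = Σ(mass%ᵢ × double bondsᵢ)/100 over the
fatty acids listed in the table; trace FAs absent from the table are
ignored. Both the UI of the mean percentages and the mean of
per-replicate UIs can be computed from replicate tables; on the bundled
reference profile they agree within 0.01.

One-way ANOVA works from summary statistics — SSB = Σnᵢ(ȳᵢ − ȳ)²,
SSW = Σ(nᵢ−1)sᵢ², F = (SSB/(k−1))/(SSW/(N−k)), η² = SSB/(SSB+SSW) —
because published tables print only means ± SD with n = 3; the
raw-replicate path gives identical results (tested to 1e-12) and is used
with synthetic replicates. Confidence intervals are mean ±
t₁₋α/2,n−1·sd/√n; negative lower bounds are reported as-is (they flag
means close to zero at n = 3, not an error). Tukey HSD letter groups are
out of scope; pairwise Welch t-tests are offered as a clearly labelled
alternative.

## Synthetic data

The generators produce data with exactly the statistical structure the
analyses consume:

- **Sequences** — a star phylogeny: species ancestors at expected
  distance d_between/2 from a common random root, strains at d_within/2
  from their ancestor; no coalescent, recombination, indels or rate
  heterogeneity. Each branch applies at most one substitution per site,
  drawn with probability equal to the branch length; a substitution is a
  transition with probability κ/(κ+2), otherwise one of the two
  transversions. This two-class process is what the K2P estimator
  inverts, so configured divergences are recovered without bias beyond
  sampling error (double hits across the two branches of a pair are
  O(d²)). Note that with this parameterisation heterospecific strains
  sit at expected distance d_between + d_within. Defaults — 4 species ×
  3 strains, L = 1000, d_within = 0.01, d_between = 0.10, κ = 2 — give
  the clean two-level structure (gap ratio 10) typical of a curated
  barcode reference set of closely-studied congeners.
- **Traits** — cluster-specific modal states (3 states/trait by
  default), uniform deviation with probability `noise`, unknown cells
  placed uniformly at random at rate `missing_frac` (not blockwise, so
  the completeness filter is exercised evenly).
- **Partitions** — controlled splits (a species divided in two at a
  random cut) and merges (disjoint species pairs fused) of a reference
  taxonomy, giving scoring tests with verdicts known by construction.
- **FA replicates** — normal draws around stated means/SDs, truncated
  at zero (clips logged), n = 3 matching standard biological replication.

What passing tests on synthetic data do *not* show: robustness to
alignment error, rate heterogeneity among lineages, incomplete lineage
sorting, correlated trait evolution, or non-normal measurement error —
none of which the generators emulate.

## Problem sizes and numerical choices

The seeded validation suites use 50 simulation seeds for parameter
recovery (4×3 strains, L = 1000), 200 datasets × 199 permutations for
Mantel null calibration, and full 4!-enumeration for the exact Mantel
check; these sizes make the whole suite run in well under a minute while
leaving the binomial/KS bounds comfortably informative. Distance
comparisons in oracle tests are exact or at 1e-9; ultrametricity is
checked at 1e-9; summary-vs-raw ANOVA identity at 1e-12. Degenerate
inputs (zero total range, empty pair classes, zero-variance distance
vectors, both-singleton K/θ) raise typed errors or return labelled
indeterminate verdicts rather than NaNs.
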