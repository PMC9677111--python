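# Methods

This note documents the statistical models, conventions, and design
choices behind `germdiv`, and what the synthetic-data generators do and
do not emulate.

## Marker informativeness

Dominant fingerprints record each band as present (1) or absent (0) per
accession; heterozygotes are indistinguishable from dominant homozygotes,
so all statistics work on band-presence proportions, not genotype
frequencies.  Band frequency is the proportion of *scored* accessions
carrying the band; missing gel calls are excluded from the denominator,
never silently treated as absence.

* **PIC.**  Two conventions are offered because the dominant-data
  literature is split.  The default (`normalized_allele`) treats a
  primer's bands as one allele set — fᵢ is band i's presence count over
  the summed presence counts of the primer, and PIC = 1 − Σ fᵢ² — giving
  one PIC per primer, bounded by 1 − 1/B for B bands.  The alternative
  (`per_band_mean`) averages the biallelic value 1 − p² − (1 − p)² over
  bands and is bounded by 0.5.
* **Resolving power.**  Rp = Σ_b Ib with Ib = 1 − 2|0.5 − p| by default
  (`absolute`), which is bounded by the band count.  A `signed` mode
  drops the absolute value (Ib = 2p, unbounded above by 1 per band);
  some published tables can only be reproduced under that reading, so it
  is provided, but it is never the default and never used in acceptance
  checks on raw data.
* **EMR, MI, EMI.**  A band is polymorphic iff 0 < p < 1 (strict).
  EMR = npb·(npb/tnb); MI = EMR·PIC; EMI = MI·DC·QM·PR with DC = 0.75
  and PR = 1.0, the conventional constants for SSR markers, and QM the
  user's marker-quality score on the 0.25–1 scale (default 1.0 — single,
  clear bands).  The identities MI = EMR·PIC and EMI = MI·DC·QM·PR hold
  to 1e-12 internally; tables are rounded to 3 decimals only for
  display, so a printed MI can differ from printed-EMR×printed-PIC by up
  to ~0.002.

## RCBD quantitative genetics

The trait model is the balanced two-way RCBD, Y_ij = µ + g_i + b_j +
e_ij.  Unbalanced layouts are rejected rather than approximated — the
closed-form estimators are exact only in the balanced case, and that
keeps every downstream number testable.  Variance components come from
expected mean squares (σ²e = MSe, σ²g = (MSg − MSe)/r, truncated at zero
with a warning).  Heritability is broad-sense on a plot basis
(σ²p = σ²g + MSe); mean-basis heritability would divide MSe by r and
read systematically higher.  Genetic advance uses k = 2.06 (5%
selection) by default; GA is reported both in trait units and as a
percentage of the mean (GAM), since published ranges are often ambiguous
between the two.  Pooling over years, when relevant, is expected to be
done upstream by averaging genotype×block cells; no genotype×year term
is modeled.

## Distances

* **Jaccard** s = a/(a+b+c) over pairwise-complete bands; a pair with no
  scored shared-or-private presence (a+b+c = 0) is an error, not a 0 or
  1.  The complement d = 1 − s is a metric on binary profiles
  (property-tested).
* **Binary AMOVA distance**: d² = band-mismatch count, the standard
  convention for dominant data; the matrix stores d = √mismatches so
  AMOVA's squared distances are exact integers.
* **Trait distances**: per-trait z-scores with population (n) variance,
  then Euclidean distance.  Using the population rather than sample
  variance makes the distances independent of the variance convention of
  any external tool; the choice is recorded in the run manifest via the
  config snapshot.
* **Fusion**: each matrix is divided by its maximum off-diagonal entry
  (range-normalization to [0, 1]) and the matrices are averaged with
  weights normalized to sum to one.  Range-normalization was chosen over
  variance-normalization because the fused inputs (Jaccard, Euclidean)
  live on incommensurable scales with very different dispersion shapes;
  the maximum is the only landmark they share.

## Hierarchical clustering

The agglomeration is a direct O(n³) SAHN loop with Lance–Williams
updates.  Tie-breaking is fully deterministic: among minimum-distance
pairs, the pair whose smallest-leaf-label pair sorts first
lexicographically merges first.  Heights: UPGMA records merge height =
average between-cluster distance / 2, so the cophenetic distance
c(i,j) = 2·h(LCA) equals the average distance on the original scale and
`cophenetic(upgma(D)) == D` exactly for ultrametric inputs; complete and
Ward linkage record the merge distance itself.  Newick branch lengths
are parent height − child height, so trees round-trip losslessly.

`cut_tree(k)` applies the n−k lowest merges (ascending height, ties
resolved toward the lower height, stable in merge order); under this
merge-count convention every k in [1, n] is attainable, so the "nearest
attainable k" fallback that a cut-by-height convention would need never
arises.  Cuts are nested across k by construction.

Tree comparison reports the Pearson correlation of off-diagonal
cophenetic entries plus, per k, the adjusted Rand index between the two
k-cuts and the number of accessions whose pairwise co-membership differs
— the quantitative analogue of counting mismatched leaves between two
tanglegram sides.

K-means uses Lloyd's algorithm with a fixed number of restarts (default
25) and a seeded RNG; k is selected over a 2–10 grid by maximum mean
silhouette width, ties toward smaller k.  A best silhouette below 0.25
is flagged as "unsupported" — data with no real cluster structure will
still produce an argmax, and the flag keeps that honest.  Trait/chem
heatmap-style trees default to complete linkage (configurable); marker
trees default to UPGMA.

PCA diagonalizes the correlation matrix by default (traits are on
different scales); component signs are fixed by making each component's
largest-magnitude loading positive.

## AMOVA, PCoA, Mantel, ΔK

One-level AMOVA (among/within populations) on squared distances:
SS_total = (1/N)Σ_{i<j} d², SS_within = Σ_p (1/n_p)Σ_{i<j∈p} d², with
σ²w = MS_within, σ²a = (MS_among − MS_within)/n0 and
n0 = (N − Σn_p²/N)/(P−1).  The Φ_ST point estimate is reported
untruncated (it may be slightly negative); the variance percentages use
the zero-truncated component so they stay in [0, 100] and sum to 100.
The permutation test shuffles individuals among populations with sizes
fixed and uses the add-one rule (b+1)/(m+1); the default is 999
permutations.  The default distance is the binary band-mismatch
distance; a Jaccard-derived distance is accepted anywhere a
DistanceMatrix is.

PCoA double-centers −½d² (Gower), takes the eigendecomposition, and
scales eigenvectors by √λ.  Negative eigenvalues (non-Euclidean input)
are reported but excluded from the percent-variance denominator; axis
signs follow the largest-coordinate-positive convention.

The Mantel statistic is the Pearson correlation of upper triangles; the
p-value is two-sided on |r| under simultaneous row/column permutation,
add-one rule, seeded.

Evanno's ΔK uses mean log-likelihoods over runs: L'(K) = L̄(K) − L̄(K−1),
|L''(K)| = |L'(K+1) − L'(K)|, ΔK = |L''(K)|/sd(L(K)), defined only for
interior K on a contiguous grid with ≥2 runs per K; sd = 0 leaves ΔK
undefined and flagged.  ΔK is invariant to shifting or positively
rescaling all likelihoods (both are asserted).  Only the
post-processing is implemented; the admixture MCMC itself is an
external tool whose per-run log-likelihoods are the input.

## Synthetic data: what it emulates, what it does not

The marker generator is the Balding–Nichols island model — the standard
way to parameterize differentiation by a single Fst.  It captures
frequency divergence among populations and binomial sampling within
them; it does not model linkage between loci, selection, mutation
spectra, scoring error, or the co-ancestry structure of a real
germplasm bank.  "Codominant" banding (band2 = 1 − band1, the default)
mimics two-band primers where the two bands are alternative states of
one locus; "independent" banding draws a second free locus per primer.

The RCBD generator draws independent normal genotype, block, and plot
effects; block variance defaults to half the error variance (blocks
cancel from every reported estimator, so this only shapes raw data
realism).  Chemotype tables are isotropic Gaussian clusters around
chosen compound-mean vectors.

The study-shaped bundle fixes the conditions once: 24 accessions in 6
ecotypes of unequal sizes (6, 5, 4, 4, 3, 2), 13 two-band codominant
primers at Fst = 0.07 (low differentiation, as is typical for a
seed-exchanged, largely selfing medicinal crop), 9 traits whose
heritabilities span ~0.08–0.86 and GCVs ~1.7–15%, two chemotype clusters
of 9 and 15 accessions separated mainly by andrographolide content, and
an admixture log-likelihood profile with a knee at K = 2.  Passing tests
on this bundle demonstrate estimator correctness under the stated model,
not robustness to the messiness of real gels and field trials.

Because only 13 loci are drawn, single-draw Φ_ST estimates on the bundle
are noisy (the worked example's 20% at a true Fst of 7% is ordinary
sampling spread); quantitative recovery checks therefore use 200-locus
panels, where Φ_ST lands within ±0.05 of truth.

## Numerical conventions and problem sizes

Readers auto-detect comma/tab, are strict about domains (a cell outside
{0, 1, missing} is an error with its coordinates), and every writer
round-trips through its reader to 1e-9 or better.  Distance symmetry is
enforced to 1e-8.  All randomness (permutation tests, k-means restarts,
generators) flows from explicit integer seeds; reruns are bit-identical.
Simulation-based tests use deliberately modest sizes — e.g. 200
simulations of a 100-genotype × 3-block trial for heritability recovery,
200 random instances of n ≤ 10 for the UPGMA oracle, 500 draws × 99
permutations for the null-uniformity check — chosen so the full suite
exercises every estimator's sampling behavior while staying fast enough
to run routinely.

## Known limitations

Co-dominant (allele-size) statistics, null-allele handling, mixed-model
REML for unbalanced trials, genotype×environment terms, hierarchical
(region-level) AMOVA, bootstrap support on dendrograms, and graphical
output (heatmaps, tanglegrams, biplots) are out of scope; the testable
data artifacts behind those figures (trees, partitions, coordinates,
tables) are the outputs.
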