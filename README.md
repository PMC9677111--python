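# germdiv

Multi-dataset genetic-diversity analysis for germplasm panels, built
around the workflow used for dominant molecular fingerprints (e.g.
EST-SSR band profiles scored presence/absence), replicated agronomic
trials, and phytochemical profiles of medicinal-plant collections such as
kalmegh (*Andrographis paniculata*).

Breeders assessing a germplasm collection typically ask three questions:
how informative are the markers, how heritable and selectable are the
quantitative traits, and how is diversity structured across accessions
and ecotypes.  `germdiv` answers all three from plain delimited text
files and combines the evidence in a joint (fused-distance) cluster
analysis.

## What it computes

**Marker informativeness** (per primer, dominant/binary data):
polymorphism percentage, polymorphic information content
PIC = 1 − Σ fᵢ², resolving power Rp = Σ Ib with Ib = 1 − 2|0.5 − p|,
effective multiplex ratio EMR = npb·(npb/tnb), marker index
MI = EMR·PIC, and effective marker index EMI = MI·DC·QM·PR with the
conventional SSR constants DC = 0.75, PR = 1.0 and marker quality QM on
a 0.25–1 scale.

**Quantitative genetics** (balanced RCBD, per trait): two-way ANOVA,
variance components σ²g = (MSg − MSe)/r and σ²e = MSe, genotypic and
phenotypic coefficients of variation GCV = 100·σg/µ̄ and PCV = 100·σp/µ̄,
broad-sense heritability h² = σ²g/σ²p, and genetic advance
GA = k·σp·h² at selection intensity k = 2.06 (top 5%).

**Distances and clustering**: Jaccard similarity a/(a+b+c) on band
profiles, band-mismatch (squared) distances, z-scored Euclidean trait
distances, UPGMA/complete/Ward SAHN trees with Newick export and
cophenetic analysis, silhouette-guided k-means, and PCA.

**Population structure**: one-level AMOVA with Φ_ST and a seeded
permutation test, principal coordinate analysis, the Mantel test between
distance matrices, and Evanno ΔK = |L''(K)|/sd(L(K)) from admixture
log-likelihood tables.

**Joint analysis**: range-normalized, weighted fusion of the marker,
trait, and chemotype distance matrices followed by UPGMA.

A seeded synthetic-data module generates all inputs with known truth
(island-model markers at a chosen Fst, RCBD traits with known variance
components, chemotype clusters), so the whole pipeline is testable
without any external data.

## Worked example

```python
from germdiv.io import RunConfig
from germdiv.marker_stats import markers_table
from germdiv.pipeline import PipelineInputs, run_all
from germdiv.synthetic import make_study_shaped_bundle

bundle = make_study_shaped_bundle(seed=11)   # 24 accessions, 6 ecotypes
print(markers_table(bundle.markers).head(4))

manifest = run_all(
    RunConfig(seed=11, n_permutations=199),
    PipelineInputs(markers=bundle.markers, popmap=bundle.popmap,
                   traits=bundle.traits, chem=bundle.chem, lnpd=bundle.lnpd),
    "out/run1")
print({k: manifest.scalars[k] for k in
       ("amova_percent_among", "deltak_best_k", "mantel_p")})
```

prints the per-primer informativeness rows

```
     TNB  NPB     PP    PIC     RP  EMR     MI   QM   QND    EMI
P01  2.0  2.0  100.0  0.330  0.833  2.0  0.660  1.0  0.75  0.495
P02  2.0  2.0  100.0  0.497  1.833  2.0  0.993  1.0  0.75  0.745
P03  2.0  2.0  100.0  0.444  1.333  2.0  0.889  1.0  0.75  0.667
P04  2.0  2.0  100.0  0.080  0.167  2.0  0.160  1.0  0.75  0.120
```

(PIC near 0.5 marks a maximally informative biallelic primer; P04 is
nearly fixed and close to useless) and the headline structure results

```
{'amova_percent_among': 19.79, 'deltak_best_k': 2, 'mantel_p': 0.275}
```

— about 20% of molecular variance between ecotypes on this 13-locus
draw, an admixture log-likelihood knee at K = 2, and no significant
association between chemotype and marker distances.  The run directory
contains the full artifact set (trees as Newick, partitions, AMOVA and
variability tables, PCoA coordinates, ΔK table, fused-distance tree,
`report.md`, `manifest.json`).

The same operations are available from the shell:

```sh
germdiv simulate --seed 11 --out fixture/
germdiv run --markers fixture/markers.csv --popmap fixture/popmap.csv \
            --traits fixture/traits.csv --chem fixture/chem.csv \
            --lnpd fixture/lnpd.csv --seed 11 --out out/run1
```

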