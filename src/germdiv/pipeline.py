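"""End-to-end orchestration of the multi-dataset diversity workflow.

Stages (each skipped, with a log entry, when its input is absent):

1. markers  — informativeness table, Jaccard similarity/distance, band-
   mismatch distance, UPGMA tree + k=2 cut, AMOVA (needs popmap), PCoA
2. traits   — per-trait RCBD ANOVA, variability parameters, genotype-mean
   distance, hierarchical tree + k=3 cut, PCA, silhouette k-means
3. chem     — standardized Euclidean distance, tree + k=2 cut, PCA, k-means
4. mantel   — chem vs marker distance
5. deltak   — Evanno table from the Ln P(D) runs
6. compare  — trait vs marker dendrogram correlation and cut agreement
7. joint    — equal-weight fusion of available distances, UPGMA, k=2 cut

All artifacts are plain text under the run directory, listed in a JSON
manifest together with input digests, seeds, and warnings.
"""
from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (compare_dendrograms, cut_tree, hierarchical,
                         kmeans_select, pca, upgma)
from .distances import (fuse_distances, jaccard_similarity,
                        similarity_to_distance, squared_band_distance,
                        standardize_and_euclid)
from .errors import AlignmentError
from .io import (Dendrogram, DistanceMatrix, MarkerMatrix, PopulationMap,
                 RunConfig, TraitTable, write_newick, write_square_distance,
                 write_square_similarity)
from .marker_stats import markers_table
from .popgen import amova, best_k, evanno_delta_k, mantel, pcoa
from .quantgen import analyze_traits, variability_table

__all__ = ["PipelineInputs", "RunManifest", "run_all", "report"]

#: default reporting cuts: markers and joint trees at k=2, agro traits at
#: k=3, chemotypes at k=2
DEFAULT_CUTS = {"markers": 2, "traits": 3, "chem": 2, "joint": 2}


@dataclass
class PipelineInputs:
    markers: MarkerMatrix | None = None
    popmap: PopulationMap | None = None
    traits: TraitTable | None = None
    chem: pd.DataFrame | None = None
    lnpd: pd.DataFrame | None = None


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    input_digests: dict[str, str]
    outputs: dict[str, list[str]]
    scalars: dict[str, float | int | None]
    skipped: list[str]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


def _check_alignment(inputs: PipelineInputs) -> None:
    sets: dict[str, set[str]] = {}
    if inputs.markers is not None:
        sets["markers"] = set(inputs.markers.accessions)
    if inputs.traits is not None:
        sets["traits"] = set(inputs.traits.genotypes)
    if inputs.chem is not None:
        sets["chem"] = set(str(i) for i in inputs.chem.index)
    names = list(sets)
    for i in range(1, len(names)):
        if sets[names[i]] != sets[names[0]]:
            offenders = sorted(sets[names[i]] ^ sets[names[0]])
            raise AlignmentError(
                f"accession sets differ between {names[0]} and {names[i]}: "
                f"{offenders}")


def run_all(config: RunConfig, inputs: PipelineInputs,
            outdir: str | Path) -> RunManifest:
    """Execute every applicable stage; returns and saves the manifest."""
    if inputs.markers is None and inputs.traits is None and inputs.chem is None:
        raise AlignmentError("at least one of markers/traits/chem is required")
    _check_alignment(inputs)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    outputs: dict[str, list[str]] = {}
    scalars: dict[str, float | int | None] = {}
    skipped: list[str] = []
    caught: list[str] = []
    log: list[str] = []
    distances_for_fusion: list[DistanceMatrix] = []
    trees: dict[str, Dendrogram] = {}

    def emit(stage: str, name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs.setdefault(stage, []).append(name)
        return path

    digests: dict[str, str] = {}
    if inputs.markers is not None:
        digests["markers"] = _digest(inputs.markers.data.to_csv())
    if inputs.popmap is not None:
        digests["popmap"] = _digest(json.dumps(inputs.popmap.mapping, sort_keys=True))
    if inputs.traits is not None:
        digests["traits"] = _digest(inputs.traits.data.to_csv(index=False))
    if inputs.chem is not None:
        digests["chem"] = _digest(inputs.chem.to_csv())
    if inputs.lnpd is not None:
        digests["lnpd"] = _digest(inputs.lnpd.to_csv(index=False))

    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")

        # ---- markers ----
        if inputs.markers is not None:
            mm = inputs.markers
            table = markers_table(mm, config)
            emit("markers", "marker_table.csv", lambda p: table.to_csv(p))
            sim = jaccard_similarity(mm, config.missing_policy)
            emit("markers", "jaccard_similarity.csv",
                 lambda p: write_square_similarity(sim, p))
            jdist = similarity_to_distance(sim)
            emit("markers", "marker_distance.csv",
                 lambda p: write_square_distance(jdist, p))
            bdist = squared_band_distance(mm)
            emit("markers", "band_distance.csv",
                 lambda p: write_square_distance(bdist, p))
            tree = hierarchical(jdist, config.linkage)
            trees["markers"] = tree
            emit("markers", "marker_tree.nwk", lambda p: write_newick(tree, p))
            part = cut_tree(tree, DEFAULT_CUTS["markers"])
            emit("markers", f"marker_partition_k{DEFAULT_CUTS['markers']}.csv",
                 lambda p: part.to_dataframe().to_csv(p, index=False))
            scalars["jaccard_min_similarity"] = float(
                sim.values[np.triu_indices(sim.n, k=1)].min())
            distances_for_fusion.append(jdist)

            if inputs.popmap is not None:
                res = amova(bdist, inputs.popmap, config.n_permutations,
                            config.seed)
                emit("markers", "amova.csv",
                     lambda p: res.to_dataframe().to_csv(p, index=False))
                scalars["amova_percent_among"] = res.percent_among
                scalars["amova_percent_within"] = res.percent_within
                scalars["amova_phi_st"] = res.phi_st
                scalars["amova_p_value"] = res.p_value
            else:
                skipped.append("amova (no population map)")

            ord_res = pcoa(bdist)
            emit("markers", "pcoa_coordinates.csv",
                 lambda p: ord_res.coordinates.to_csv(p, index_label="accession"))
            eig = pd.DataFrame({
                "axis": [f"PCo{i+1}" for i in range(len(ord_res.percent_variance))],
                "percent_variance": ord_res.percent_variance,
                "cumulative_percent": ord_res.cumulative_percent})
            emit("markers", "pcoa_variance.csv", lambda p: eig.to_csv(p, index=False))
        else:
            skipped.append("markers")

        # ---- traits ----
        if inputs.traits is not None:
            anovas, var = analyze_traits(inputs.traits, config.selection_intensity)
            anova_df = pd.concat(
                [a.to_dataframe().assign(trait=t) for t, a in anovas.items()])
            emit("traits", "anova.csv", lambda p: anova_df.to_csv(p, index=False))
            emit("traits", "variability.csv",
                 lambda p: variability_table(var).to_csv(p))
            means = inputs.traits.genotype_means()
            tdist = standardize_and_euclid(means)
            emit("traits", "trait_distance.csv",
                 lambda p: write_square_distance(tdist, p))
            ttree = hierarchical(tdist, config.trait_linkage)
            trees["traits"] = ttree
            emit("traits", "trait_tree.nwk", lambda p: write_newick(ttree, p))
            tpart = cut_tree(ttree, DEFAULT_CUTS["traits"])
            emit("traits", f"trait_partition_k{DEFAULT_CUTS['traits']}.csv",
                 lambda p: tpart.to_dataframe().to_csv(p, index=False))
            tp = pca(means, scale=True)
            emit("traits", "trait_pca_scores.csv",
                 lambda p: tp.scores.to_csv(p, index_label="accession"))
            pvar = pd.DataFrame({"component": tp.scores.columns,
                                 "percent_variance": tp.percent_variance})
            emit("traits", "trait_pca_variance.csv",
                 lambda p: pvar.to_csv(p, index=False))
            scalars["trait_pca_pc12_percent"] = float(tp.percent_variance[:2].sum())
            km = kmeans_select(
                (means - means.mean()) / means.std(ddof=0),
                config.k_range, config.kmeans_restarts, config.seed)
            emit("traits", "trait_kmeans_silhouette.csv",
                 lambda p: km.silhouette.to_csv(p, index=False))
            emit("traits", "trait_kmeans_partition.csv",
                 lambda p: km.partition.to_dataframe().to_csv(p, index=False))
            scalars["trait_kmeans_k"] = km.best_k
            distances_for_fusion.append(tdist)
        else:
            skipped.append("traits")

        # ---- chem ----
        if inputs.chem is not None:
            chem = inputs.chem
            cdist = standardize_and_euclid(chem)
            emit("chem", "chem_distance.csv",
                 lambda p: write_square_distance(cdist, p))
            ctree = hierarchical(cdist, config.trait_linkage)
            trees["chem"] = ctree
            emit("chem", "chem_tree.nwk", lambda p: write_newick(ctree, p))
            cpart = cut_tree(ctree, DEFAULT_CUTS["chem"])
            emit("chem", f"chem_partition_k{DEFAULT_CUTS['chem']}.csv",
                 lambda p: cpart.to_dataframe().to_csv(p, index=False))
            cp = pca(chem, scale=True)
            emit("chem", "chem_pca_scores.csv",
                 lambda p: cp.scores.to_csv(p, index_label="accession"))
            cvar = pd.DataFrame({"component": cp.scores.columns,
                                 "percent_variance": cp.percent_variance})
            emit("chem", "chem_pca_variance.csv", lambda p: cvar.to_csv(p, index=False))
            scalars["chem_pca_pc12_percent"] = float(cp.percent_variance[:2].sum())
            ckm = kmeans_select((chem - chem.mean()) / chem.std(ddof=0),
                                config.k_range, config.kmeans_restarts, config.seed)
            emit("chem", "chem_kmeans_silhouette.csv",
                 lambda p: ckm.silhouette.to_csv(p, index=False))
            emit("chem", "chem_kmeans_partition.csv",
                 lambda p: ckm.partition.to_dataframe().to_csv(p, index=False))
            scalars["chem_kmeans_k"] = ckm.best_k
            distances_for_fusion.append(cdist)
        else:
            skipped.append("chem")

        # ---- mantel: chem vs marker distance ----
        if inputs.chem is not None and inputs.markers is not None:
            r, p_val = mantel(distances_for_fusion[0],
                              distances_for_fusion[-1],
                              config.n_permutations, config.seed)
            scalars["mantel_r"] = r
            scalars["mantel_r2"] = r * r
            scalars["mantel_p"] = p_val
        else:
            skipped.append("mantel (needs markers and chem)")

        # ---- delta-K ----
        if inputs.lnpd is not None:
            dk = evanno_delta_k(inputs.lnpd)
            emit("deltak", "deltak.csv", lambda p: dk.to_csv(p, index=False))
            scalars["deltak_best_k"] = best_k(dk)
        else:
            skipped.append("deltak")

        # ---- dendrogram comparison (trait vs marker) ----
        if "traits" in trees and "markers" in trees:
            comp = compare_dendrograms(trees["traits"], trees["markers"],
                                       config.k_range)
            emit("compare", "tree_comparison.csv",
                 lambda p: comp.cut_agreement.to_csv(p, index=False))
            scalars["tree_cophenetic_correlation"] = comp.cophenetic_correlation
        else:
            skipped.append("compare (needs marker and trait trees)")

        # ---- joint fusion ----
        if len(distances_for_fusion) >= 2:
            weights = config.fusion_weights[: len(distances_for_fusion)]
            fused = fuse_distances(distances_for_fusion, weights)
            emit("joint", "joint_distance.csv",
                 lambda p: write_square_distance(fused, p))
            jtree = upgma(fused)
            emit("joint", "joint_tree.nwk", lambda p: write_newick(jtree, p))
            jpart = cut_tree(jtree, DEFAULT_CUTS["joint"])
            emit("joint", f"joint_partition_k{DEFAULT_CUTS['joint']}.csv",
                 lambda p: jpart.to_dataframe().to_csv(p, index=False))
        else:
            skipped.append("joint (needs >=2 distance matrices)")

        caught = [str(w.message) for w in wlist]

    manifest = RunManifest(
        config=config.to_dict(), version=__version__, seed=config.seed,
        input_digests=digests, outputs=outputs, scalars=scalars,
        skipped=skipped, warnings=caught)
    manifest.save(outdir / "manifest.json")
    log.extend(f"stage {s}: {len(files)} artifact(s)" for s, files in outputs.items())
    log.extend(f"skipped: {s}" for s in skipped)
    (outdir / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    report_text = report(outdir)
    (outdir / "report.md").write_text(report_text, encoding="utf-8")
    return manifest


def report(outdir: str | Path) -> str:
    """Human-readable markdown summary regenerated from the run directory."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text(encoding="utf-8"))
    lines = ["# Diversity analysis report", ""]
    scal = manifest.get("scalars", {})

    def fnum(x):
        return "n/a" if x is None else (f"{x:.4g}" if isinstance(x, float) else str(x))

    if (outdir / "marker_table.csv").exists():
        lines += ["## Marker informativeness", "",
                  (outdir / "marker_table.csv").read_text(encoding="utf-8").rstrip(),
                  ""]
    if (outdir / "variability.csv").exists():
        lines += ["## Trait variability (RCBD)", "",
                  (outdir / "variability.csv").read_text(encoding="utf-8").rstrip(),
                  ""]
    if "amova_percent_among" in scal:
        lines += ["## AMOVA", "",
                  f"- among populations: {fnum(scal['amova_percent_among'])}%",
                  f"- within populations: {fnum(scal['amova_percent_within'])}%",
                  f"- Phi_ST = {fnum(scal['amova_phi_st'])} "
                  f"(p = {fnum(scal['amova_p_value'])})", ""]
    if "mantel_r" in scal:
        lines += ["## Mantel test (chem vs marker distances)", "",
                  f"- r = {fnum(scal['mantel_r'])}, "
                  f"r^2 = {fnum(scal['mantel_r2'])}, "
                  f"p = {fnum(scal['mantel_p'])}", ""]
    if "deltak_best_k" in scal:
        lines += ["## Evanno delta-K", "",
                  f"- best K = {scal['deltak_best_k']}", ""]
    parts = sorted(outdir.glob("*partition*.csv"))
    if parts:
        lines += ["## Cluster memberships", ""]
        for p in parts:
            df = pd.read_csv(p)
            sizes = df["cluster"].value_counts().sort_index()
            lines.append(f"- {p.name}: " + ", ".join(
                f"cluster {c}: n={n}" for c, n in sizes.items()))
        lines.append("")
    if manifest.get("skipped"):
        lines += ["## Skipped stages", ""]
        lines += [f"- {s}" for s in manifest["skipped"]]
        lines.append("")
    return "\n".join(lines)
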