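"""Seeded generators for every input the analysis consumes.

Dominant marker fingerprints come from a Balding-Nichols island model:
per locus an ancestral presence frequency p0 ~ Uniform(0.1, 0.9), per
population p_pop ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F) with F the target
Fst, and per accession a Bernoulli(p_pop) band call.  Two-band primers
are generated in "codominant" banding mode (band2 = 1 - band1, the two
visible states of one locus) or "independent" mode (a second independent
locus).

RCBD traits follow Y_ij = mu + g_i + b_j + e_ij with independent normal
genotype, block, and plot-error effects of known variance, so heritability
recovery can be checked against truth.  Chemotype tables draw accession
profiles from cluster-specific mean vectors over the four quantified
diterpenes (AG, NAG, DDAG, AN, % dry weight) with isotropic normal noise.

``make_study_shaped_bundle`` emits a full input set shaped like a typical
diversity panel in this crop: 24 accessions from 6 ecotypes of unequal
size, 13 two-band primers, 9 agro-morphological traits in 3 blocks, 4
compounds, and an admixture log-likelihood table with a planted knee at
K = 2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (MarkerMatrix, PopulationMap, TraitTable, write_marker_matrix,
                 write_population_map, write_trait_table)

__all__ = [
    "TraitSpec",
    "ChemClusterSpec",
    "SimulationSpec",
    "MarkerTruth",
    "simulate_dominant_markers",
    "simulate_rcbd_traits",
    "simulate_chemotypes",
    "simulate_lnpd_profile",
    "make_study_shaped_bundle",
    "StudyBundle",
    "ECOTYPES",
    "STUDY_POP_SIZES",
]

#: six agroecological ecotype labels and the unequal panel sizes used by
#: the study-shaped bundle (24 accessions total)
ECOTYPES = ("GP", "WG", "EG", "SPH", "WDR", "IR")
STUDY_POP_SIZES = (6, 5, 4, 4, 3, 2)


@dataclass
class TraitSpec:
    """One quantitative trait's generative parameters (units implicit)."""

    name: str
    mean: float
    sigma2_g: float
    sigma2_e: float
    n_blocks: int = 3
    sigma2_b: float | None = None  # default: half the error variance

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_e) < 0:
            raise ConfigError(f"trait {self.name!r}: variances must be >= 0")
        if self.sigma2_b is None:
            self.sigma2_b = 0.5 * self.sigma2_e

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class ChemClusterSpec:
    """One chemotype cluster: compound mean vector (% dry weight) + noise."""

    means: dict[str, float]
    noise_sd: float
    size: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.size < 1:
            raise ConfigError("chem cluster needs noise_sd >= 0 and size >= 1")


@dataclass
class SimulationSpec:
    """Joint specification of a synthetic diversity panel."""

    pop_sizes: tuple[int, ...] = STUDY_POP_SIZES
    pop_names: tuple[str, ...] = ECOTYPES
    n_primers: int = 13
    fst: float = 0.07
    banding: str = "codominant"            # or "independent"
    trait_specs: tuple[TraitSpec, ...] = ()
    chem_specs: tuple[ChemClusterSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst < 1):
            raise ConfigError(f"fst must lie in (0, 1), got {self.fst}")
        if any(s < 1 for s in self.pop_sizes):
            raise ConfigError("population sizes must be >= 1")
        if len(self.pop_names) != len(self.pop_sizes):
            raise ConfigError("pop_names and pop_sizes lengths differ")
        if self.banding not in ("codominant", "independent"):
            raise ConfigError(f"unknown banding mode {self.banding!r}")

    @property
    def n_accessions(self) -> int:
        return int(sum(self.pop_sizes))


@dataclass
class MarkerTruth:
    """Generator-side truth: drawn frequencies per locus and population."""

    fst: float
    p0: np.ndarray          # (n_loci,)
    p_pop: np.ndarray       # (n_pops, n_loci)


def _accession_names(n: int) -> list[str]:
    return [f"AP{i + 1}" for i in range(n)]


def simulate_dominant_markers(
    spec: SimulationSpec, rng: np.random.Generator | None = None,
) -> tuple[MarkerMatrix, PopulationMap, MarkerTruth]:
    """Balding-Nichols dominant marker panel with known differentiation."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_pops = len(spec.pop_sizes)
    n_loci = spec.n_primers
    f = spec.fst
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    shape = (1.0 - f) / f
    p_pop = rng.beta(p0 * shape, (1.0 - p0) * shape, size=(n_pops, n_loci))

    accs = _accession_names(spec.n_accessions)
    popmap: dict[str, str] = {}
    rows = []
    a = 0
    for pop_i, (pop_name, size) in enumerate(zip(spec.pop_names, spec.pop_sizes)):
        for _ in range(size):
            band1 = (rng.random(n_loci) < p_pop[pop_i]).astype(float)
            if spec.banding == "codominant":
                band2 = 1.0 - band1
            else:
                band2 = (rng.random(n_loci) < p_pop[pop_i]).astype(float)
            rows.append(np.column_stack([band1, band2]).ravel())
            popmap[accs[a]] = pop_name
            a += 1
    bands = []
    primers = {}
    for l in range(n_loci):
        primer = f"P{l + 1:02d}"
        for suffix in ("a", "b"):
            band = f"{primer}.{suffix}"
            bands.append(band)
            primers[band] = primer
    data = pd.DataFrame(np.vstack(rows), index=accs, columns=bands)
    matrix = MarkerMatrix(data=data, primers=pd.Series(primers))
    return matrix, PopulationMap(mapping=popmap), MarkerTruth(fst=f, p0=p0, p_pop=p_pop)


def simulate_rcbd_traits(
    trait_specs: tuple[TraitSpec, ...], n_genotypes: int,
    seed: int = 0, rng: np.random.Generator | None = None,
    genotypes: list[str] | None = None,
) -> tuple[TraitTable, dict[str, TraitSpec]]:
    """RCBD observations with known variance components; the returned
    truth maps trait name to its generative spec."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    genos = genotypes or _accession_names(n_genotypes)
    records = []
    for ts in trait_specs:
        g = rng.normal(0.0, np.sqrt(ts.sigma2_g), size=len(genos))
        b = rng.normal(0.0, np.sqrt(ts.sigma2_b), size=ts.n_blocks)
        e = rng.normal(0.0, np.sqrt(ts.sigma2_e), size=(len(genos), ts.n_blocks))
        for i, geno in enumerate(genos):
            for j in range(ts.n_blocks):
                records.append((geno, f"B{j + 1}", ts.name,
                                ts.mean + g[i] + b[j] + e[i, j]))
    table = TraitTable(data=pd.DataFrame(
        records, columns=["genotype", "block", "trait", "value"]))
    return table, {ts.name: ts for ts in trait_specs}


def simulate_chemotypes(
    chem_specs: tuple[ChemClusterSpec, ...], seed: int = 0,
    rng: np.random.Generator | None = None,
    accessions: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Accession x compound table with known cluster membership."""
    if len(chem_specs) < 1:
        raise ConfigError("need at least one chemotype cluster")
    compounds = list(chem_specs[0].means)
    for cs in chem_specs:
        if list(cs.means) != compounds:
            raise ConfigError("all clusters must share the same compound set")
    if len(chem_specs) > 1:
        vectors = [tuple(cs.means.values()) for cs in chem_specs]
        if len(set(vectors)) < len(vectors) and all(cs.noise_sd == 0 for cs in chem_specs):
            import warnings
            warnings.warn("degenerate chemotype spec: identical means with "
                          "zero noise", stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng(seed)
    total = sum(cs.size for cs in chem_specs)
    accs = accessions or _accession_names(total)
    if len(accs) != total:
        raise ConfigError(f"{len(accs)} accession names for {total} samples")
    rows, truth = [], {}
    a = 0
    for ci, cs in enumerate(chem_specs, start=1):
        mu = np.array([cs.means[c] for c in compounds])
        for _ in range(cs.size):
            rows.append(mu + rng.normal(0.0, cs.noise_sd, size=len(compounds)))
            truth[accs[a]] = ci
            a += 1
    return pd.DataFrame(rows, index=accs, columns=compounds), truth


def simulate_lnpd_profile(k_max: int = 10, n_runs: int = 3, peak_k: int = 2,
                          run_sd: float = 8.0, seed: int = 0,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Admixture log-likelihood table with a planted knee at ``peak_k``:
    a large gain up to the true K, a gentle decline beyond it."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    base, gain, decline = -5200.0, 600.0, 15.0
    rows = []
    for k in range(1, k_max + 1):
        mean = base + gain * min(k - 1, peak_k - 1) - decline * max(k - peak_k, 0)
        for run in range(1, n_runs + 1):
            rows.append((k, run, mean + rng.normal(0.0, run_sd)))
    return pd.DataFrame(rows, columns=["K", "run", "lnpd"])


# ---------------------------------------------------------------------------
# Study-shaped bundle
# ---------------------------------------------------------------------------

def default_trait_specs() -> tuple[TraitSpec, ...]:
    """Nine agro-morphological descriptors with heritabilities spanning
    ~0.08-0.86 and GCVs ~1.7-15%, the realistic range for this crop:
    days to 50% flowering (DFF), days to maturity (DM), plant height (PH,
    cm), nodes/plant (NNP), secondary branches/plant (NSBP), leaf length
    (LL, cm), leaf width (LW, cm), inflorescence length (IL, cm), dry
    herb yield/plant (DHY, g)."""
    return (
        TraitSpec("DFF", 95.0, 72.0, 12.0),
        TraitSpec("DM", 150.0, 7.0, 9.0),
        TraitSpec("PH", 60.0, 16.0, 20.0),
        TraitSpec("NNP", 12.0, 1.2, 1.6),
        TraitSpec("NSBP", 18.0, 6.5, 4.0),
        TraitSpec("LL", 7.0, 0.04, 0.45),
        TraitSpec("LW", 2.2, 0.11, 0.05),
        TraitSpec("IL", 9.0, 0.8, 1.0),
        TraitSpec("DHY", 38.0, 30.0, 18.0),
    )


def default_chem_specs() -> tuple[ChemClusterSpec, ...]:
    """Two chemotypes separated mainly by andrographolide content."""
    return (
        ChemClusterSpec({"AG": 2.6, "NAG": 0.45, "DDAG": 0.55, "AN": 0.18},
                        noise_sd=0.18, size=9),
        ChemClusterSpec({"AG": 1.1, "NAG": 0.90, "DDAG": 1.00, "AN": 0.30},
                        noise_sd=0.15, size=15),
    )


@dataclass
class StudyBundle:
    markers: MarkerMatrix
    popmap: PopulationMap
    traits: TraitTable
    chem: pd.DataFrame
    lnpd: pd.DataFrame
    marker_truth: MarkerTruth
    trait_truth: dict[str, TraitSpec]
    chem_truth: dict[str, int]
    paths: dict[str, Path] = field(default_factory=dict)


def make_study_shaped_bundle(seed: int = 0,
                             outdir: str | Path | None = None) -> StudyBundle:
    """One full input bundle shaped like the 24-accession study panel.

    Deterministic given the seed; when ``outdir`` is given the five input
    files (markers, popmap, traits, chem, lnpd) are written there in the
    formats the readers consume, byte-identically across re-runs.
    """
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(seed=seed)
    markers, popmap, marker_truth = simulate_dominant_markers(spec, rng=rng)
    accs = markers.accessions
    traits, trait_truth = simulate_rcbd_traits(default_trait_specs(),
                                               len(accs), rng=rng,
                                               genotypes=accs)
    # chemotype membership deliberately cuts across ecotypes: shuffle
    shuffled = [accs[i] for i in rng.permutation(len(accs))]
    chem, chem_truth = simulate_chemotypes(default_chem_specs(), rng=rng,
                                           accessions=shuffled)
    chem = chem.loc[accs]
    lnpd = simulate_lnpd_profile(rng=rng)

    bundle = StudyBundle(markers=markers, popmap=popmap, traits=traits,
                         chem=chem, lnpd=lnpd, marker_truth=marker_truth,
                         trait_truth=trait_truth, chem_truth=chem_truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "markers": outdir / "markers.csv",
            "popmap": outdir / "popmap.csv",
            "traits": outdir / "traits.csv",
            "chem": outdir / "chem.csv",
            "lnpd": outdir / "lnpd.csv",
        }
        write_marker_matrix(markers, paths["markers"])
        write_population_map(popmap, paths["popmap"])
        write_trait_table(traits, paths["traits"])
        chem.to_csv(paths["chem"], index_label="accession", float_format="%.6f")
        lnpd.to_csv(paths["lnpd"], index=False, float_format="%.4f")
        bundle.paths = paths
    return bundle
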