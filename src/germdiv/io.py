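"""Validated containers and text I/O for every external artifact.

All inputs and outputs are plain text: delimited matrices and tables
(comma or tab, auto-detected), Newick trees, labeled square distance
matrices, and a flat YAML run configuration.  Containers validate their
invariants on construction, so downstream statistics never see malformed
data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, ConfigError, FormatError

__all__ = [
    "MarkerMatrix",
    "TraitTable",
    "PopulationMap",
    "DistanceMatrix",
    "SimilarityMatrix",
    "Dendrogram",
    "RunConfig",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_trait_table",
    "write_trait_table",
    "read_population_map",
    "write_population_map",
    "read_square_distance",
    "write_square_distance",
    "read_square_similarity",
    "write_square_similarity",
    "read_newick",
    "write_newick",
    "newick_string",
    "read_config",
    "write_config",
]

_SYM_TOL = 1e-8


def _sniff_delimiter(path: Path) -> str:
    """Choose between tab and comma from the header line."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


# ---------------------------------------------------------------------------
# MarkerMatrix
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    """Binary accession x band table for dominant (presence/absence) markers.

    ``data`` holds floats: 0.0 (absent), 1.0 (present), NaN (missing —
    flagged, never silently zero).  ``primers`` maps each band to the
    primer that amplified it.
    """

    data: pd.DataFrame
    primers: pd.Series  # index: band id -> primer id

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise FormatError("marker matrix needs at least 1 accession and 1 band")
        _check_unique(self.data.index.astype(str), "accession")
        _check_unique(self.data.columns.astype(str), "band")
        vals = self.data.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"marker value {vals[i, j]!r} at accession "
                f"{self.data.index[i]!r}, band {self.data.columns[j]!r} "
                "is not 0, 1 or missing"
            )
        missing_bands = set(self.data.columns) - set(self.primers.index)
        if missing_bands:
            raise FormatError(f"bands without a primer assignment: {sorted(missing_bands)}")
        self.primers = self.primers.loc[self.data.columns]

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def bands(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_accessions(self) -> int:
        return self.data.shape[0]

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]

    def primer_groups(self) -> dict[str, list[str]]:
        """Primer id -> bands, preserving band order of first appearance."""
        groups: dict[str, list[str]] = {}
        for band, primer in self.primers.items():
            groups.setdefault(str(primer), []).append(str(band))
        return groups

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_marker_matrix(
    path: str | Path,
    delimiter: str | None = None,
    missing_token: str = "NA",
    primer_map: Mapping[str, str] | str | Path | None = None,
) -> MarkerMatrix:
    """Read a band-scoring matrix: first column accession labels, header
    band ids as ``PRIMER.suffix`` (or supply an explicit band->primer map).
    Cells must be 0, 1 or the missing token."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.empty or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty marker matrix")
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()

    data = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    for j, band in enumerate(raw.columns):
        col = raw.iloc[:, j].str.strip()
        for i, cell in enumerate(col):
            if cell == missing_token:
                continue
            if cell == "0":
                data.iloc[i, j] = 0.0
            elif cell == "1":
                data.iloc[i, j] = 1.0
            else:
                raise FormatError(
                    f"{path}: invalid cell {cell!r} at accession "
                    f"{raw.index[i]!r}, band {band!r} (expected 0, 1 or "
                    f"{missing_token!r})"
                )

    if primer_map is None:
        primers = {}
        for band in data.columns:
            if "." not in band:
                raise FormatError(
                    f"{path}: band {band!r} has no 'PRIMER.suffix' form and no "
                    "primer map was given"
                )
            primers[band] = band.split(".", 1)[0]
        primer_series = pd.Series(primers)
    elif isinstance(primer_map, (str, Path)):
        pm = pd.read_csv(primer_map, sep=_sniff_delimiter(Path(primer_map)), dtype=str)
        if pm.shape[1] < 2:
            raise FormatError(f"{primer_map}: primer map needs two columns (band, primer)")
        primer_series = pd.Series(pm.iloc[:, 1].str.strip().values,
                                  index=pm.iloc[:, 0].str.strip())
    else:
        primer_series = pd.Series(dict(primer_map))
    return MarkerMatrix(data=data, primers=primer_series)


def write_marker_matrix(
    matrix: MarkerMatrix, path: str | Path, missing_token: str = "NA", delimiter: str = ","
) -> None:
    out = matrix.data.copy()
    fmt = out.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    fmt.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Long-format RCBD observations: one row per (genotype, block, trait)."""

    data: pd.DataFrame  # columns: genotype, block, trait, value
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["genotype", "block", "trait", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"trait table missing column(s): {missing}")
        self.data = self.data[required].copy()
        for col in ("genotype", "block", "trait"):
            self.data[col] = self.data[col].astype(str).str.strip()
        try:
            self.data["value"] = pd.to_numeric(self.data["value"])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric trait value: {exc}") from exc
        dup = self.data.duplicated(subset=["genotype", "block", "trait"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise FormatError(
                "duplicated observation for genotype "
                f"{row['genotype']!r}, block {row['block']!r}, trait {row['trait']!r}"
            )

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.data["trait"]))

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.data["genotype"]))

    @property
    def blocks(self) -> list[str]:
        return list(dict.fromkeys(self.data["block"]))

    def __len__(self) -> int:
        return len(self.data)

    def pivot(self, trait: str) -> pd.DataFrame:
        """Genotype x block layout for one trait (NaN where unobserved)."""
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise FormatError(f"unknown trait {trait!r}")
        return sub.pivot(index="genotype", columns="block", values="value")

    def genotype_means(self) -> pd.DataFrame:
        """Accession x trait matrix of means over blocks (clustering input)."""
        wide = self.data.pivot_table(index="genotype", columns="trait",
                                     values="value", aggfunc="mean")
        return wide[self.traits].loc[self.genotypes]


def read_trait_table(path: str | Path, delimiter: str | None = None) -> TraitTable:
    """Read RCBD observations in long layout (genotype, block, trait, value)
    or wide layout (genotype, block, one column per trait)."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    for needed in ("genotype", "block"):
        if needed not in lower:
            raise FormatError(f"{path}: missing required column '{needed}'")
    df = df.rename(columns={lower["genotype"]: "genotype", lower["block"]: "block"})
    if "trait" in lower and "value" in lower:
        df = df.rename(columns={lower["trait"]: "trait", lower["value"]: "value"})
        return TraitTable(data=df)
    trait_cols = [c for c in df.columns if c not in ("genotype", "block")]
    if not trait_cols:
        raise FormatError(f"{path}: no trait columns found")
    long = df.melt(id_vars=["genotype", "block"], value_vars=trait_cols,
                   var_name="trait", value_name="value")
    return TraitTable(data=long)


def write_trait_table(table: TraitTable, path: str | Path, delimiter: str = ",") -> None:
    table.data.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# PopulationMap
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """Accession label -> population (ecotype) label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise FormatError("population map is empty")
        self.mapping = {str(k).strip(): str(v).strip() for k, v in self.mapping.items()}

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def __getitem__(self, accession: str) -> str:
        try:
            return self.mapping[accession]
        except KeyError:
            raise AlignmentError(f"accession {accession!r} has no population assignment")

    def labels_for(self, accessions: Iterable[str]) -> list[str]:
        return [self[a] for a in accessions]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for pop in self.mapping.values():
            out[pop] = out.get(pop, 0) + 1
        return out


def read_population_map(path: str | Path, delimiter: str | None = None) -> PopulationMap:
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: population map needs columns (accession, population)")
    acc = df.iloc[:, 0].str.strip()
    _check_unique(acc, "accession")
    return PopulationMap(mapping=dict(zip(acc, df.iloc[:, 1].str.strip())))


def write_population_map(popmap: PopulationMap, path: str | Path, delimiter: str = ",") -> None:
    pd.DataFrame(
        {"accession": list(popmap.mapping), "population": list(popmap.mapping.values())}
    ).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Distance / similarity matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, keyed by labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        _check_unique(self.labels, "accession")
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise FormatError(f"distance matrix shape {v.shape} does not match {n} labels")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise FormatError("distance matrix is asymmetric beyond 1e-8")
        v = (v + v.T) / 2.0
        if np.abs(np.diag(v)).max(initial=0.0) > _SYM_TOL:
            raise FormatError("distance matrix diagonal is not zero")
        np.fill_diagonal(v, 0.0)
        if v.min(initial=0.0) < -_SYM_TOL:
            raise FormatError("distance matrix has negative entries")
        self.values = np.clip(v, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = [str(x) for x in labels]
        if set(labels) != set(self.labels):
            raise AlignmentError("cannot reorder: label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


@dataclass
class SimilarityMatrix:
    """Symmetric matrix with entries in [0, 1] and unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        _check_unique(self.labels, "accession")
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise FormatError(f"similarity matrix shape {v.shape} does not match {n} labels")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise FormatError("similarity matrix is asymmetric beyond 1e-8")
        v = (v + v.T) / 2.0
        if v.min(initial=0.0) < -_SYM_TOL or v.max(initial=0.0) > 1.0 + _SYM_TOL:
            raise FormatError("similarity entries outside [0, 1]")
        if np.abs(np.diag(v) - 1.0).max(initial=0.0) > _SYM_TOL:
            raise FormatError("similarity diagonal is not one")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _read_labeled_square(path: Path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return df


def read_square_distance(path: str | Path, delimiter: str | None = None) -> DistanceMatrix:
    df = _read_labeled_square(Path(path), delimiter)
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_square_distance(matrix: DistanceMatrix, path: str | Path, delimiter: str = ",") -> None:
    matrix.to_dataframe().to_csv(path, sep=delimiter, float_format="%.12f")


def read_square_similarity(path: str | Path, delimiter: str | None = None) -> SimilarityMatrix:
    df = _read_labeled_square(Path(path), delimiter)
    return SimilarityMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_square_similarity(matrix: SimilarityMatrix, path: str | Path, delimiter: str = ",") -> None:
    matrix.to_dataframe().to_csv(path, sep=delimiter, float_format="%.12f")


# ---------------------------------------------------------------------------
# Dendrogram + Newick
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Rooted binary merge tree with heights.

    Node ids follow the scipy convention: leaves are ``0..n-1`` in label
    order; merge ``m`` creates node ``n+m``.  ``merges`` rows are
    ``(left_id, right_id, height)`` with heights non-decreasing along any
    root path.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        _check_unique(self.labels, "leaf")
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise FormatError(f"dendrogram with {n} leaves needs {n - 1} merges, "
                              f"got {len(self.merges)}")
        heights = {i: 0.0 for i in range(n)}
        used: set[int] = set()
        norm = []
        for m, (left, right, h) in enumerate(self.merges):
            left, right, h = int(left), int(right), float(h)
            node = n + m
            for child in (left, right):
                if child not in heights:
                    raise FormatError(f"merge {m} references unknown node {child}")
                if child in used:
                    raise FormatError(f"node {child} used in two merges")
                if h < heights[child] - 1e-9:
                    raise FormatError(
                        f"merge {m} height {h} below child height {heights[child]}")
                used.add(child)
            if h < 0:
                raise FormatError("negative merge height")
            heights[node] = h
            norm.append((left, right, h))
        self.merges = tuple(norm)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_heights(self) -> dict[int, float]:
        n = self.n_leaves
        h = {i: 0.0 for i in range(n)}
        for m, (_, _, height) in enumerate(self.merges):
            h[n + m] = height
        return h

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Node id -> set of descendant leaf indices."""
        n = self.n_leaves
        out: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for m, (left, right, _) in enumerate(self.merges):
            out[n + m] = out[left] | out[right]
        return out


def newick_string(tree: Dendrogram, precision: int = 12) -> str:
    """Serialize with branch lengths = parent height - child height."""
    n = tree.n_leaves
    heights = tree.node_heights()
    children = {n + m: (l, r) for m, (l, r, _) in enumerate(tree.merges)}
    for lab in tree.labels:
        if any(ch in lab for ch in "(),:;'\"\t\n "):
            raise FormatError(f"leaf label {lab!r} not serializable to Newick")

    def fmt(x: float) -> str:
        return format(x, f".{precision}g")

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if bl < -1e-9:
            raise FormatError(f"negative branch length at node {node}")
        bl = max(bl, 0.0)
        if node < n:
            return f"{tree.labels[node]}:{fmt(bl)}"
        l, r = children[node]
        inner = f"({render(l, heights[node])},{render(r, heights[node])})"
        return inner if node == n + len(tree.merges) - 1 else f"{inner}:{fmt(bl)}"

    root = n + len(tree.merges) - 1
    return render(root, heights[root]) + ";"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n", encoding="utf-8")


def read_newick(path_or_text: str | Path) -> Dendrogram:
    """Parse a Newick string written by :func:`write_newick` back into a
    Dendrogram.  The tree must be binary with height-consistent branch
    lengths (all leaves at height zero)."""
    text = str(path_or_text)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text(encoding="utf-8")
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    heights: dict[int, float] = {}
    labels: list[str] = []
    ids: dict[int, int] = {}
    pending: list[tuple[float, object]] = []  # internal nodes, post-order

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or "")
            if not label:
                raise FormatError("Newick leaf without a label")
            heights[id(node)] = 0.0
            ids[id(node)] = len(labels)
            labels.append(label)
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise FormatError("only binary trees are supported")
            hs = [heights[id(c)] + (c.edge.length or 0.0) for c in kids]
            if max(hs) - min(hs) > 1e-6:
                raise FormatError(
                    "tree is not height-consistent (children imply different "
                    f"parent heights {hs})")
            heights[id(node)] = sum(hs) / 2.0
            pending.append((heights[id(node)], node))

    n = len(labels)
    # stable sort by height keeps children before parents (post-order input)
    pending.sort(key=lambda t: t[0])
    merges: list[tuple[int, int, float]] = []
    for m, (h, node) in enumerate(pending):
        kids = node.child_nodes()
        merges.append((ids[id(kids[0])], ids[id(kids[1])], h))
        ids[id(node)] = n + m
    return Dendrogram(labels=tuple(labels), merges=tuple(merges))


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

_PIC_MODES = ("normalized_allele", "per_band_mean")
_RP_MODES = ("absolute", "signed")
_LINKAGES = ("upgma", "complete", "ward")
_MISSING_POLICIES = ("drop_pairwise", "error")


@dataclass
class RunConfig:
    """Tunable parameters for a full analysis run.

    QM (marker quality, 0.25-1 scale), DC (documentation capability) and PR
    (reproducibility) parameterize the effective marker index; DC and PR
    default to the conventional SSR constants 0.75 and 1.0.
    """

    qm: float = 1.0
    dc: float = 0.75
    pr: float = 1.0
    pic_mode: str = "normalized_allele"
    rp_mode: str = "absolute"
    n_permutations: int = 999
    seed: int = 0
    linkage: str = "upgma"
    trait_linkage: str = "complete"
    k_range: tuple[int, int] = (2, 10)
    kmeans_restarts: int = 25
    fusion_weights: tuple[float, ...] = (1.0, 1.0, 1.0)
    missing_policy: str = "drop_pairwise"
    selection_intensity: float = 2.06

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.25 <= self.qm <= 1.0):
            raise ConfigError(f"qm must lie in [0.25, 1], got {self.qm}")
        if self.dc <= 0 or self.pr <= 0:
            raise ConfigError("dc and pr must be positive")
        if self.pic_mode not in _PIC_MODES:
            raise ConfigError(f"pic_mode must be one of {_PIC_MODES}")
        if self.rp_mode not in _RP_MODES:
            raise ConfigError(f"rp_mode must be one of {_RP_MODES}")
        if int(self.n_permutations) < 1:
            raise ConfigError("n_permutations must be a positive integer")
        self.n_permutations = int(self.n_permutations)
        self.seed = int(self.seed)
        if self.linkage not in _LINKAGES or self.trait_linkage not in _LINKAGES:
            raise ConfigError(f"linkage must be one of {_LINKAGES}")
        lo, hi = (int(self.k_range[0]), int(self.k_range[1]))
        if not (2 <= lo <= hi):
            raise ConfigError(f"invalid k_range {self.k_range}")
        self.k_range = (lo, hi)
        weights = tuple(float(w) for w in self.fusion_weights)
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ConfigError("fusion_weights must be non-negative with a positive sum")
        self.fusion_weights = weights
        if self.missing_policy not in _MISSING_POLICIES:
            raise ConfigError(f"missing_policy must be one of {_MISSING_POLICIES}")
        if self.selection_intensity <= 0:
            raise ConfigError("selection_intensity must be positive")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def read_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat key: value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    for key in ("k_range", "fusion_weights"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False),
                          encoding="utf-8")
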