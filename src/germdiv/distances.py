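"""Similarity and distance construction, and distance-matrix fusion.

Marker data yield (i) Jaccard similarity s = a/(a+b+c) over pairwise-
complete bands and its complement distance, and (ii) the binary AMOVA
distance whose square is the band-mismatch count.  Quantitative traits
are z-scored per trait (population variance) before Euclidean distance.
Heterogeneous matrices are fused by range-normalizing each to [0, 1]
(division by its maximum off-diagonal entry) and averaging with
normalized non-negative weights.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import AlignmentError, DegenerateDataError, FormatError
from .io import DistanceMatrix, MarkerMatrix, SimilarityMatrix

__all__ = [
    "jaccard_similarity",
    "similarity_to_distance",
    "squared_band_distance",
    "standardize_and_euclid",
    "fuse_distances",
]


def jaccard_similarity(matrix: MarkerMatrix,
                       missing_policy: str = "drop_pairwise") -> SimilarityMatrix:
    """Jaccard similarity on the binary band matrix.

    For each accession pair, bands are restricted to those scored in both
    (pairwise-complete); a = shared presences, b/c = private presences.
    A pair with a+b+c = 0 has undefined similarity and is rejected.
    """
    x = matrix.values()
    if missing_policy == "error" and np.isnan(x).any():
        raise FormatError("missing marker calls present (missing_policy='error')")
    n = matrix.n_accessions
    s = np.eye(n)
    scored = ~np.isnan(x)
    for i in range(n):
        for j in range(i + 1, n):
            both = scored[i] & scored[j]
            xi, xj = x[i, both], x[j, both]
            a = float(np.sum((xi == 1) & (xj == 1)))
            bc = float(np.sum(xi != xj))
            if a + bc == 0:
                raise DegenerateDataError(
                    "Jaccard similarity undefined for accession pair "
                    f"({matrix.accessions[i]!r}, {matrix.accessions[j]!r}): "
                    "no shared scored band with a presence")
            s[i, j] = s[j, i] = a / (a + bc)
    return SimilarityMatrix(tuple(matrix.accessions), s)


def similarity_to_distance(sim: SimilarityMatrix) -> DistanceMatrix:
    """d = 1 - s."""
    return DistanceMatrix(sim.labels, 1.0 - sim.values)


def squared_band_distance(matrix: MarkerMatrix) -> DistanceMatrix:
    """Binary AMOVA distance: d^2 = number of mismatching bands
    (pairwise-complete); the matrix stores d = sqrt(mismatches)."""
    x = matrix.values()
    n = matrix.n_accessions
    scored = ~np.isnan(x)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = scored[i] & scored[j]
            d2[i, j] = d2[j, i] = float(np.sum(x[i, both] != x[j, both]))
    return DistanceMatrix(tuple(matrix.accessions), np.sqrt(d2))


def standardize_and_euclid(trait_means: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance after z-scoring each trait column
    (population variance, ddof=0)."""
    x = trait_means.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise FormatError("trait-mean matrix contains missing values")
    sd = x.std(axis=0, ddof=0)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise DegenerateDataError(
            f"zero-variance trait(s): {[trait_means.columns[i] for i in zero]}")
    z = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(tuple(str(i) for i in trait_means.index), d)


def fuse_distances(matrices: Sequence[DistanceMatrix],
                   weights: Sequence[float] | None = None) -> DistanceMatrix:
    """Range-normalize each matrix by its maximum off-diagonal entry, then
    average with weights normalized to sum to one."""
    if not matrices:
        raise FormatError("no distance matrices to fuse")
    if weights is None:
        weights = [1.0] * len(matrices)
    w = np.asarray(list(weights), dtype=float)
    if len(w) != len(matrices):
        raise FormatError("one weight per matrix required")
    if (w < 0).any() or w.sum() <= 0:
        raise FormatError("weights must be non-negative with a positive sum")
    ref = matrices[0]
    aligned = [ref]
    for m in matrices[1:]:
        if set(m.labels) != set(ref.labels):
            extra = sorted(set(m.labels) ^ set(ref.labels))
            raise AlignmentError(f"label sets differ between matrices: {extra}")
        aligned.append(m.reorder(ref.labels))
    w = w / w.sum()
    fused = np.zeros_like(ref.values)
    for wi, m in zip(w, aligned):
        peak = m.values.max()
        if peak <= 0:
            raise DegenerateDataError("cannot range-normalize an all-zero "
                                      "distance matrix")
        fused += wi * (m.values / peak)
    return DistanceMatrix(ref.labels, fused)
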