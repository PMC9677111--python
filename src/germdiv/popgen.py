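"""Distance-based population genetics: one-level AMOVA with Phi_ST and
permutation testing, principal coordinate analysis, the Mantel test, and
Evanno delta-K post-processing of admixture log-likelihood tables.

AMOVA partitions squared pairwise distances among and within populations
(Excoffier's one-level layout).  With N individuals in P populations of
sizes n_p:

    SS_total  = (1/N) * sum_{i<j} d2_ij                 (all pairs)
    SS_within = sum_p (1/n_p) * sum_{i<j in p} d2_ij
    SS_among  = SS_total - SS_within
    sigma2_w  = MS_within
    sigma2_a  = (MS_among - MS_within) / n0,  n0 = (N - sum n_p^2 / N) / (P-1)
    Phi_ST    = sigma2_a / (sigma2_a + sigma2_w)

The permutation p-value shuffles individuals among populations (sizes
fixed) and uses the add-one rule (b+1)/(m+1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (AlignmentError, DegenerateDataError, DesignError,
                     FormatError)
from .io import DistanceMatrix, PopulationMap

__all__ = [
    "AmovaResult",
    "PcoaResult",
    "amova",
    "pcoa",
    "mantel",
    "evanno_delta_k",
    "best_k",
]


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    sigma2_among: float       # truncated at 0
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_st: float             # untruncated estimator (may be slightly < 0)
    p_value: float
    n_permutations: int
    n0: float
    truncated: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [["among_populations", self.df_among, self.ss_among, self.ms_among,
              self.sigma2_among, self.percent_among],
             ["within_populations", self.df_within, self.ss_within,
              self.ms_within, self.sigma2_within, self.percent_within]],
            columns=["source", "df", "SS", "MS", "variance", "percent"])


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame       # accession x axis
    eigenvalues: np.ndarray         # all, non-increasing
    percent_variance: np.ndarray    # over positive eigenvalues, sums to 100
    cumulative_percent: np.ndarray
    negative_eigenvalues: np.ndarray


def _amova_ss(d2: np.ndarray, groups: np.ndarray,
              group_sizes: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g, size in enumerate(group_sizes):
        idx = np.where(groups == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * size)
    return ss_total - ss_within, ss_within


def _phi_st(d2: np.ndarray, groups: np.ndarray, group_sizes: np.ndarray,
            n0: float, df_a: int, df_w: int) -> float:
    ss_a, ss_w = _amova_ss(d2, groups, group_sizes)
    ms_a, ms_w = ss_a / df_a, ss_w / df_w
    s2a = (ms_a - ms_w) / n0
    denom = s2a + ms_w
    if denom == 0:
        return 0.0
    return s2a / denom


def amova(distance: DistanceMatrix, popmap: PopulationMap,
          n_permutations: int = 999, seed: int = 0) -> AmovaResult:
    """One-level AMOVA on squared pairwise distances with a seeded
    permutation test of Phi_ST."""
    labels = list(distance.labels)
    pop_labels = popmap.labels_for(labels)   # raises AlignmentError if unmapped
    pops = sorted(set(pop_labels))
    if len(pops) < 2:
        raise DesignError("AMOVA needs at least two populations")
    groups = np.array([pops.index(p) for p in pop_labels])
    sizes = np.bincount(groups, minlength=len(pops))
    singletons = [pops[i] for i in np.where(sizes < 2)[0]]
    if singletons:
        raise DesignError(f"singleton population(s): {singletons}")
    n, p = len(labels), len(pops)
    d2 = distance.values ** 2
    if d2.max() == 0:
        raise DegenerateDataError("all distances are zero; Phi_ST undefined")

    df_a, df_w = p - 1, n - p
    ss_a, ss_w = _amova_ss(d2, groups, sizes)
    ms_a, ms_w = ss_a / df_a, ss_w / df_w
    n0 = (n - float(np.sum(sizes ** 2)) / n) / (p - 1)
    sigma2_w = ms_w
    sigma2_a_raw = (ms_a - ms_w) / n0
    truncated = sigma2_a_raw < 0
    sigma2_a = max(sigma2_a_raw, 0.0)
    total = sigma2_a + sigma2_w
    pct_a = 100.0 * sigma2_a / total if total > 0 else 0.0
    phi_obs = sigma2_a_raw / (sigma2_a_raw + sigma2_w) \
        if (sigma2_a_raw + sigma2_w) != 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(groups)
        if _phi_st(d2, perm, sizes, n0, df_a, df_w) >= phi_obs:
            exceed += 1
    p_value = (exceed + 1) / (int(n_permutations) + 1)

    return AmovaResult(
        df_among=df_a, df_within=df_w, ss_among=ss_a, ss_within=ss_w,
        ms_among=ms_a, ms_within=ms_w, sigma2_among=sigma2_a,
        sigma2_within=sigma2_w, percent_among=pct_a,
        percent_within=100.0 - pct_a, phi_st=float(phi_obs),
        p_value=float(p_value), n_permutations=int(n_permutations),
        n0=float(n0), truncated=truncated)


def pcoa(distance: DistanceMatrix) -> PcoaResult:
    """Metric MDS by Gower double-centering of -0.5 * d^2.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; negative eigenvalues are reported but excluded from the
    percent-variance denominator.  Axis signs follow the largest-
    magnitude-coordinate-positive convention.
    """
    d2 = distance.values ** 2
    n = distance.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), abs(eigval[-1]), 1.0) * 1e-12
    pos = eigval > tol
    neg = eigval[eigval < -tol]
    pos_vals = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(pos_vals)
    for jx in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, jx])))
        if coords[i, jx] < 0:
            coords[:, jx] *= -1
    if pos_vals.size:
        percent = 100.0 * pos_vals / pos_vals.sum()
    else:
        percent = np.zeros(0)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(distance.labels), columns=axes),
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        negative_eigenvalues=neg)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_permutations: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """Two-sided Mantel test: Pearson correlation of the upper triangles,
    p by simultaneous row/column permutation of the second matrix."""
    if set(d1.labels) != set(d2.labels):
        raise AlignmentError("Mantel test requires identical label sets")
    m2 = d2.reorder(d1.labels).values
    m1 = d1.values
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]
    if v1.std() == 0 or m2[iu].std() == 0:
        raise DegenerateDataError("zero off-diagonal variance; Mantel "
                                  "correlation undefined")
    r_obs = float(np.corrcoef(v1, m2[iu])[0, 1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(n)
        r_p = float(np.corrcoef(v1, m2[np.ix_(perm, perm)][iu])[0, 1])
        if abs(r_p) >= abs(r_obs) - 1e-12:
            exceed += 1
    p = (exceed + 1) / (int(n_permutations) + 1)
    return r_obs, float(p)


def evanno_delta_k(lnpd_runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno table from admixture log-likelihoods Ln P(D) per (K, run).

    Input columns: ``K``, ``run``, ``lnpd``.  Output per K: run count,
    mean and sd of L(K), L'(K) = mean L(K) - mean L(K-1),
    |L''(K)| = |L'(K+1) - L'(K)|, and delta_k = |L''(K)| / sd(L(K)) for
    interior K (NaN where undefined; sd = 0 leaves delta_k NaN, flagged
    in the ``sd_zero`` column).
    """
    cols = {c.lower(): c for c in lnpd_runs.columns}
    for need in ("k", "run", "lnpd"):
        if need not in cols:
            raise FormatError(f"Ln P(D) table missing column {need!r}")
    df = lnpd_runs.rename(columns={cols["k"]: "K", cols["run"]: "run",
                                   cols["lnpd"]: "lnpd"})
    df["K"] = df["K"].astype(int)
    grouped = df.groupby("K")["lnpd"]
    ks = sorted(grouped.groups)
    if len(ks) < 3:
        raise FormatError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise FormatError(f"K grid {ks} is not contiguous")
    counts = grouped.count()
    if (counts < 2).any():
        raise FormatError("need >=2 runs per K for the sd in delta-K")
    mean = grouped.mean()
    sd = grouped.std(ddof=1)

    lprime = pd.Series(index=ks, dtype=float)
    for k in ks[1:]:
        lprime[k] = mean[k] - mean[k - 1]
    lsecond = pd.Series(index=ks, dtype=float)
    delta = pd.Series(index=ks, dtype=float)
    for k in ks[1:-1]:
        lsecond[k] = abs(lprime[k + 1] - lprime[k])
        if sd[k] > 0:
            delta[k] = lsecond[k] / sd[k]
    out = pd.DataFrame({
        "K": ks,
        "n_runs": [int(counts[k]) for k in ks],
        "mean_lnpd": [mean[k] for k in ks],
        "sd_lnpd": [sd[k] for k in ks],
        "lprime": [lprime.get(k, np.nan) for k in ks],
        "lsecond_abs": [lsecond.get(k, np.nan) for k in ks],
        "delta_k": [delta.get(k, np.nan) for k in ks],
    })
    out["sd_zero"] = out["sd_lnpd"] == 0
    return out


def best_k(delta_table: pd.DataFrame) -> int:
    """K with the largest defined delta-K."""
    defined = delta_table.dropna(subset=["delta_k"])
    if defined.empty:
        raise DegenerateDataError("delta-K undefined at every interior K")
    return int(defined.loc[defined["delta_k"].idxmax(), "K"])
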