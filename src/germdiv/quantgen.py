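"""RCBD analysis of variance and derived variability parameters.

For a balanced randomized complete block design Y_ij = mu + g_i + b_j + e_ij
with g genotypes and r blocks, the classical partition is

    SS_genotype = r * sum_i (ybar_i. - ybar..)^2        df = g - 1
    SS_block    = g * sum_j (ybar_.j - ybar..)^2        df = r - 1
    SS_error    = SS_total - SS_genotype - SS_block     df = (g-1)(r-1)

Variance components use the expected-mean-square estimators
sigma2_e = MS_error, sigma2_g = (MS_genotype - MS_error) / r (truncated at
zero).  From these, with grand mean m and sigma2_p = sigma2_g + sigma2_e:

    GCV = 100 * sqrt(sigma2_g) / m        PCV = 100 * sqrt(sigma2_p) / m
    h2  = 100 * sigma2_g / sigma2_p       (broad sense, plot basis)
    GA  = k * sqrt(sigma2_p) * h2/100     GAM = 100 * GA / m

with selection intensity k = 2.06 (top 5%) by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DesignError
from .io import TraitTable

__all__ = [
    "AnovaTable",
    "VariabilityStats",
    "rcbd_anova",
    "variance_components",
    "variability_stats",
    "analyze_traits",
    "variability_table",
]

DEFAULT_SELECTION_INTENSITY = 2.06  # 5% truncation selection


@dataclass
class AnovaTable:
    """Two-way RCBD ANOVA for one trait."""

    trait: str
    df: dict[str, int]            # genotype, block, error
    ss: dict[str, float]
    ms: dict[str, float]
    f_genotype: float             # NaN when MS_error == 0
    p_genotype: float
    grand_mean: float
    n_genotypes: int
    n_blocks: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for src in ("genotype", "block", "error"):
            rows.append([src, self.df[src], self.ss[src], self.ms[src]])
        out = pd.DataFrame(rows, columns=["source", "df", "SS", "MS"])
        out["F"] = [self.f_genotype, np.nan, np.nan]
        out["p"] = [self.p_genotype, np.nan, np.nan]
        return out


@dataclass
class VariabilityStats:
    """Variance components and selection parameters for one trait."""

    trait: str
    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    gcv: float          # %
    pcv: float          # %
    h2_broad: float     # %
    ga: float           # trait units
    gam: float          # % of mean
    k_intensity: float
    grand_mean: float


def rcbd_anova(traits: TraitTable, trait_name: str) -> AnovaTable:
    """Balanced RCBD ANOVA for one trait; unbalanced layouts are rejected."""
    table = traits.pivot(trait_name)
    if table.isna().any().any():
        missing = int(table.isna().sum().sum())
        raise DesignError(
            f"trait {trait_name!r}: unbalanced layout ({missing} empty "
            "genotype x block cells); balanced RCBD required")
    g, r = table.shape
    if g < 2 or r < 2:
        raise DesignError(
            f"trait {trait_name!r}: need >=2 genotypes and >=2 blocks, "
            f"got {g} x {r}")
    y = table.to_numpy(dtype=float)
    grand = float(y.mean())
    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_b = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_e = max(ss_total - ss_g - ss_b, 0.0)
    df = {"genotype": g - 1, "block": r - 1, "error": (g - 1) * (r - 1)}
    ss = {"genotype": ss_g, "block": ss_b, "error": ss_e}
    ms = {k: ss[k] / df[k] for k in ss}
    if ms["error"] > 0:
        f_stat = ms["genotype"] / ms["error"]
        p = float(stats.f.sf(f_stat, df["genotype"], df["error"]))
    else:
        f_stat, p = float("nan"), float("nan")
    return AnovaTable(trait=trait_name, df=df, ss=ss, ms=ms, f_genotype=f_stat,
                      p_genotype=p, grand_mean=grand, n_genotypes=g, n_blocks=r)


def variance_components(anova: AnovaTable,
                        n_blocks: int | None = None) -> tuple[float, float]:
    """(sigma2_g, sigma2_e) from expected mean squares; negative genotypic
    estimates are truncated to zero with a warning."""
    r = n_blocks if n_blocks is not None else anova.n_blocks
    sigma2_e = anova.ms["error"]
    sigma2_g = (anova.ms["genotype"] - anova.ms["error"]) / r
    if sigma2_g < 0:
        warnings.warn(
            f"trait {anova.trait!r}: negative genotypic variance estimate "
            f"({sigma2_g:.4g}) truncated to 0", stacklevel=2)
        sigma2_g = 0.0
    return float(sigma2_g), float(sigma2_e)


def variability_stats(components: tuple[float, float], grand_mean: float,
                      k_intensity: float = DEFAULT_SELECTION_INTENSITY,
                      trait: str = "") -> VariabilityStats:
    sigma2_g, sigma2_e = components
    if grand_mean <= 0:
        raise DegenerateDataError(
            f"trait {trait!r}: grand mean must be positive for coefficient-of-"
            f"variation statistics, got {grand_mean}")
    sigma2_p = sigma2_g + sigma2_e
    gcv = 100.0 * np.sqrt(sigma2_g) / grand_mean
    pcv = 100.0 * np.sqrt(sigma2_p) / grand_mean
    if sigma2_p > 0:
        h2 = 100.0 * sigma2_g / sigma2_p
        ga = k_intensity * np.sqrt(sigma2_p) * (sigma2_g / sigma2_p)
    else:
        h2, ga = 0.0, 0.0
    return VariabilityStats(
        trait=trait, sigma2_g=sigma2_g, sigma2_e=sigma2_e, sigma2_p=sigma2_p,
        gcv=float(gcv), pcv=float(pcv), h2_broad=float(h2), ga=float(ga),
        gam=float(100.0 * ga / grand_mean), k_intensity=k_intensity,
        grand_mean=grand_mean)


def analyze_traits(traits: TraitTable,
                   k_intensity: float = DEFAULT_SELECTION_INTENSITY,
                   ) -> tuple[dict[str, AnovaTable], dict[str, VariabilityStats]]:
    """RCBD ANOVA plus variability parameters for every trait in the table."""
    anovas: dict[str, AnovaTable] = {}
    var: dict[str, VariabilityStats] = {}
    for trait in traits.traits:
        a = rcbd_anova(traits, trait)
        anovas[trait] = a
        var[trait] = variability_stats(variance_components(a), a.grand_mean,
                                       k_intensity, trait=trait)
    return anovas, var


def variability_table(stats_by_trait: dict[str, VariabilityStats]) -> pd.DataFrame:
    rows = []
    for t, s in stats_by_trait.items():
        rows.append([t, s.grand_mean, s.sigma2_g, s.sigma2_e, s.sigma2_p,
                     s.gcv, s.pcv, s.h2_broad, s.ga, s.gam])
    return pd.DataFrame(rows, columns=[
        "trait", "mean", "sigma2_g", "sigma2_e", "sigma2_p",
        "GCV", "PCV", "h2", "GA", "GAM"]).set_index("trait")
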