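"""Informativeness statistics for dominant (presence/absence) fingerprints.

Per primer: total and polymorphic band counts, percent polymorphism,
polymorphic information content (PIC), resolving power (Rp), effective
multiplex ratio (EMR), marker index (MI = EMR x PIC) and effective marker
index (EMI = MI x DC x QM x PR, with QND = DC x QM x PR the qualitative
data-quality weight).

Band frequencies are proportions of scored (non-missing) accessions.
PIC offers two conventions for multi-band primers:

``normalized_allele`` (default)
    treat the primer's bands as one allele set: fi = presence count of
    band i over the summed presence counts, PIC = 1 - sum(fi^2).
``per_band_mean``
    per-band biallelic PIC, 1 - p^2 - (1-p)^2, averaged over bands.

Resolving power sums band informativeness Ib over bands.  The standard
formula is Ib = 1 - 2|0.5 - p| (``absolute`` mode, bounded by the band
count); ``signed`` mode drops the absolute value, giving Ib = 2p, a
convention that appears in parts of the applied literature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError
from .io import MarkerMatrix, RunConfig

__all__ = [
    "MarkerInformativeness",
    "band_frequency",
    "pic",
    "resolving_power",
    "emr",
    "marker_index",
    "effective_marker_index",
    "qualitative_weight",
    "summarize_markers",
    "markers_table",
]

#: conventional SSR constants for the effective marker index
DEFAULT_DC = 0.75
DEFAULT_PR = 1.0


@dataclass
class MarkerInformativeness:
    """One primer's row of the informativeness table."""

    primer: str
    tnb: int
    npb: int
    pp: float       # percent polymorphism
    pic: float
    rp: float
    emr: float
    mi: float
    qm: float
    qnd: float
    emi: float


def _usable_bands(matrix: MarkerMatrix, bands: list[str], policy: str) -> list[str]:
    """Bands retained for per-primer statistics under the missing policy:
    any band with a missing call is dropped (drop_pairwise) or rejected."""
    vals = matrix.data[bands].to_numpy(dtype=float)
    has_missing = np.isnan(vals).any(axis=0)
    if policy == "error" and has_missing.any():
        bad = [b for b, m in zip(bands, has_missing) if m]
        raise DegenerateDataError(f"missing marker calls in band(s) {bad} "
                                  "(missing_policy='error')")
    return [b for b, m in zip(bands, has_missing) if not m]


def band_frequency(matrix: MarkerMatrix, band: str) -> float:
    """Proportion of scored accessions carrying the band."""
    if band not in matrix.data.columns:
        raise DegenerateDataError(f"unknown band {band!r}")
    col = matrix.data[band].to_numpy(dtype=float)
    scored = ~np.isnan(col)
    if not scored.any():
        raise DegenerateDataError(f"band {band!r} has no scored accessions; "
                                  "frequency undefined")
    return float(col[scored].sum() / scored.sum())


def _presence_counts(matrix: MarkerMatrix, bands: list[str]) -> np.ndarray:
    return np.array([np.nansum(matrix.data[b].to_numpy(dtype=float)) for b in bands])


def pic(matrix: MarkerMatrix, primer: str, mode: str = "normalized_allele",
        missing_policy: str = "drop_pairwise") -> float:
    groups = matrix.primer_groups()
    if primer not in groups:
        raise DegenerateDataError(f"unknown primer {primer!r}")
    bands = _usable_bands(matrix, groups[primer], missing_policy)
    if not bands:
        raise DegenerateDataError(f"primer {primer!r} has no usable bands")
    if mode == "normalized_allele":
        counts = _presence_counts(matrix, bands)
        total = counts.sum()
        if total == 0:
            raise DegenerateDataError(
                f"primer {primer!r} has zero total band presence; PIC undefined")
        f = counts / total
        return float(1.0 - np.sum(f ** 2))
    if mode == "per_band_mean":
        ps = np.array([band_frequency(matrix, b) for b in bands])
        return float(np.mean(1.0 - ps ** 2 - (1.0 - ps) ** 2))
    raise ConfigError(f"unknown pic mode {mode!r}")


def resolving_power(matrix: MarkerMatrix, primer: str, rp_mode: str = "absolute",
                    missing_policy: str = "drop_pairwise") -> float:
    groups = matrix.primer_groups()
    if primer not in groups:
        raise DegenerateDataError(f"unknown primer {primer!r}")
    bands = _usable_bands(matrix, groups[primer], missing_policy)
    if not bands:
        raise DegenerateDataError(f"primer {primer!r} has no usable bands")
    ps = np.array([band_frequency(matrix, b) for b in bands])
    if rp_mode == "absolute":
        ib = 1.0 - 2.0 * np.abs(0.5 - ps)
    elif rp_mode == "signed":
        ib = 1.0 - 2.0 * (0.5 - ps)   # = 2p
    else:
        raise ConfigError(f"unknown rp mode {rp_mode!r}")
    return float(ib.sum())


def emr(matrix: MarkerMatrix, primer: str,
        missing_policy: str = "drop_pairwise") -> tuple[float, int, int]:
    """Effective multiplex ratio: npb * (npb / tnb).

    Returns ``(emr, npb, tnb)``.  A band is polymorphic iff its presence
    proportion lies strictly between 0 and 1.
    """
    groups = matrix.primer_groups()
    if primer not in groups:
        raise DegenerateDataError(f"unknown primer {primer!r}")
    bands = _usable_bands(matrix, groups[primer], missing_policy)
    if not bands:
        raise DegenerateDataError(f"primer {primer!r} has no usable bands")
    ps = np.array([band_frequency(matrix, b) for b in bands])
    tnb = len(bands)
    npb = int(np.sum((ps > 0.0) & (ps < 1.0)))
    return npb * (npb / tnb), npb, tnb


def marker_index(pic_value: float, emr_value: float) -> float:
    """MI = EMR x PIC."""
    return float(emr_value * pic_value)


def qualitative_weight(qm: float, dc: float = DEFAULT_DC, pr: float = DEFAULT_PR) -> float:
    """QND = DC x QM x PR (data-quality weight on the marker index)."""
    return float(dc * qm * pr)


def effective_marker_index(mi: float, qm: float = 1.0, dc: float = DEFAULT_DC,
                           pr: float = DEFAULT_PR) -> float:
    """EMI = MI x DC x QM x PR."""
    if not (0.25 <= qm <= 1.0):
        raise ConfigError(f"qm must lie on the 0.25-1.0 scale, got {qm}")
    return float(mi * dc * qm * pr)


def summarize_markers(matrix: MarkerMatrix,
                      config: RunConfig | None = None) -> list[MarkerInformativeness]:
    """One informativeness row per primer, in primer order of appearance."""
    config = config or RunConfig()
    rows: list[MarkerInformativeness] = []
    for primer in matrix.primer_groups():
        pic_v = pic(matrix, primer, config.pic_mode, config.missing_policy)
        rp_v = resolving_power(matrix, primer, config.rp_mode, config.missing_policy)
        emr_v, npb, tnb = emr(matrix, primer, config.missing_policy)
        mi_v = marker_index(pic_v, emr_v)
        emi_v = effective_marker_index(mi_v, config.qm, config.dc, config.pr)
        rows.append(MarkerInformativeness(
            primer=primer, tnb=tnb, npb=npb, pp=100.0 * npb / tnb,
            pic=pic_v, rp=rp_v, emr=emr_v, mi=mi_v, qm=config.qm,
            qnd=qualitative_weight(config.qm, config.dc, config.pr), emi=emi_v,
        ))
    return rows


def markers_table(matrix: MarkerMatrix, config: RunConfig | None = None,
                  decimals: int | None = 3) -> pd.DataFrame:
    """Informativeness table with an arithmetic-mean Average row.

    Columns: TNB, NPB, PP, PIC, RP, EMR, MI, QM, QND, EMI.  Full precision
    is kept internally; set ``decimals=None`` to disable display rounding.
    """
    rows = summarize_markers(matrix, config)
    df = pd.DataFrame(
        [[r.tnb, r.npb, r.pp, r.pic, r.rp, r.emr, r.mi, r.qm, r.qnd, r.emi]
         for r in rows],
        index=[r.primer for r in rows],
        columns=["TNB", "NPB", "PP", "PIC", "RP", "EMR", "MI", "QM", "QND", "EMI"],
    )
    df.loc["Average"] = df.mean(axis=0)
    if decimals is not None:
        df = df.round(decimals)
    return df
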