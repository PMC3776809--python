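"""Hemispheric sector aggregation and the circular-shift Monte Carlo null.

Sites are stratified at 23 degrees latitude into Northern-Hemisphere
extra-tropics, tropics, and Southern-Hemisphere extra-tropics. Within a
sector the normalized 12-month climatologies are averaged with equal weight
per site. Aggregate seasonality is tested two ways: Hewitt's circular
rank-sum test on the 12 aggregate means, and a Monte Carlo null in which
each site's 12-vector keeps its internal sequence but is circularly rotated
by an independent uniform shift before averaging; the statistic is the
largest difference between any two aggregate months (= max - min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import hewitt as _hewitt
from .montecarlo import half_split
from .prep import MonthlySeries, normalized_climatology

__all__ = [
    "NH_EXTRATROPICS",
    "TROPICS",
    "SH_EXTRATROPICS",
    "SectorAggregate",
    "SectorMcResult",
    "HalfSplitSectorReport",
    "assign_sector",
    "aggregate_sector",
    "sector_mc_test",
    "hewitt_on_aggregate",
    "half_split_sector",
    "circular_month_distance",
]

NH_EXTRATROPICS = "NH-extratropics"
TROPICS = "tropics"
SH_EXTRATROPICS = "SH-extratropics"
_FLAT_TOL = 1e-12


@dataclass(frozen=True)
class SectorAggregate:
    sector: str
    site_ids: tuple[str, ...]
    aggregate: np.ndarray  # 12 mean ratios, equal weight per site
    peak_month: int  # 1..12
    trough_month: int  # 1..12
    excess_pct: float  # (max - min) / min * 100
    n_cases_total: float
    flat: bool = False  # degenerate flat aggregate (Hewitt unreliable)


@dataclass(frozen=True)
class SectorMcResult:
    observed_stat: float  # largest difference between any two aggregate months
    n_sims: int
    p_value: float
    seed: int


@dataclass(frozen=True)
class HalfSplitSectorReport:
    first: SectorAggregate
    second: SectorAggregate
    first_mc: SectorMcResult
    second_mc: SectorMcResult
    peak_distance: int  # circular months between the two halves' peaks
    excluded_sites: tuple[str, ...]


def assign_sector(latitude: float) -> str:
    """Latitude sector; the 23-degree boundary itself belongs to the tropics."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} out of [-90, 90]")
    if latitude > 23.0:
        return NH_EXTRATROPICS
    if latitude < -23.0:
        return SH_EXTRATROPICS
    return TROPICS


def _ratio_matrix(normalized: Mapping[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    if not normalized:
        raise ValueError("empty sector: no normalized climatologies")
    ids = list(normalized)
    mat = np.asarray([np.asarray(normalized[s], dtype=float) for s in ids])
    if mat.shape[1] != 12:
        raise ValueError("normalized climatologies must have 12 values")
    return ids, mat


def aggregate_sector(
    normalized: Mapping[str, np.ndarray],
    sector: str = "",
    totals: Mapping[str, float] | None = None,
) -> SectorAggregate:
    """Unweighted mean of normalized climatologies over the sector's sites."""
    ids, mat = _ratio_matrix(normalized)
    agg = mat.mean(axis=0)
    peak = int(np.argmax(agg)) + 1
    trough = int(np.argmin(agg)) + 1
    flat = bool(np.ptp(agg) < _FLAT_TOL)
    if flat:
        warnings.warn(
            f"sector {sector or '<unnamed>'}: flat aggregate climatology; "
            "peak/trough and Hewitt output are unreliable",
            stacklevel=2,
        )
    lo = agg.min()
    excess = float((agg.max() - lo) / lo * 100.0) if lo > 0 else float("inf")
    n_cases = float(sum(totals.get(s, 0.0) for s in ids)) if totals else float("nan")
    return SectorAggregate(
        sector=sector,
        site_ids=tuple(ids),
        aggregate=agg,
        peak_month=peak,
        trough_month=trough,
        excess_pct=excess,
        n_cases_total=n_cases,
        flat=flat,
    )


def sector_mc_test(
    normalized: Mapping[str, np.ndarray],
    n_sims: int = 10000,
    seed: int = 0,
) -> SectorMcResult:
    """Circular-shift Monte Carlo on the sector aggregate.

    Each replicate rotates every site's normalized 12-vector by an
    independent uniform shift in 0..11 (internal month sequence preserved),
    averages across sites and takes max - min; the p-value is the add-one
    rank of the observed statistic.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    _, mat = _ratio_matrix(normalized)
    n_sites = mat.shape[0]
    agg = mat.mean(axis=0)
    observed = float(agg.max() - agg.min())
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, int(4e6 // (n_sites * 12)))
    base = np.arange(12)
    site_idx = np.arange(n_sites)[None, :, None]
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        shifts = rng.integers(0, 12, size=(b, n_sites))
        rotated = mat[site_idx, (base[None, None, :] + shifts[:, :, None]) % 12]
        sim_agg = rotated.mean(axis=1)
        stats = sim_agg.max(axis=1) - sim_agg.min(axis=1)
        exceed += int(np.count_nonzero(stats >= observed - 1e-12))
        done += b
    p = (exceed + 1) / (n_sims + 1)
    return SectorMcResult(observed_stat=observed, n_sims=n_sims, p_value=p, seed=seed)


def hewitt_on_aggregate(
    agg: SectorAggregate,
    method: str = "montecarlo",
    n_sims: int = 10**6,
    seed: int = 0,
) -> _hewitt.HewittResult:
    """Hewitt's test on the 12 aggregate means (flat input warns)."""
    if agg.flat:
        warnings.warn(
            f"sector {agg.sector or '<unnamed>'}: Hewitt on a flat aggregate is "
            "degenerate (ranks fall back to month order)",
            stacklevel=2,
        )
    return _hewitt.hewitt_test(agg.aggregate, method=method, n_sims=n_sims, seed=seed)


def circular_month_distance(a: int, b: int) -> int:
    """Shortest distance between two calendar months on the 12-month circle."""
    d = abs(int(a) - int(b)) % 12
    return min(d, 12 - d)


def half_split_sector(
    series: Sequence[MonthlySeries],
    sector: str = "",
    n_sims: int = 10000,
    seed: int = 0,
) -> HalfSplitSectorReport:
    """Consistency check: aggregate and test each half of every record.

    Sites shorter than 24 months cannot be split and are excluded with a
    warning. Each half is normalized, aggregated and run through the
    circular-shift Monte Carlo; the report pairs the two halves' peak
    months, p-values, and the circular distance between the peaks.
    """
    usable: list[MonthlySeries] = []
    excluded: list[str] = []
    for s in series:
        if s.n_months < 24:
            excluded.append(s.site_id)
        else:
            usable.append(s)
    if excluded:
        warnings.warn(
            f"sector {sector or '<unnamed>'}: excluded from half-split "
            f"(span < 24 months): {', '.join(excluded)}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError(f"sector {sector or '<unnamed>'}: no site long enough to split")
    halves = [half_split(s) for s in usable]
    reports = []
    for part in (0, 1):
        normalized = {s[part].site_id: normalized_climatology(s[part]) for s in halves}
        totals = {s[part].site_id: s[part].total for s in halves}
        agg = aggregate_sector(normalized, sector=sector, totals=totals)
        mc = sector_mc_test(normalized, n_sims=n_sims, seed=seed + part)
        reports.append((agg, mc))
    (agg1, mc1), (agg2, mc2) = reports
    return HalfSplitSectorReport(
        first=agg1,
        second=agg2,
        first_mc=mc1,
        second_mc=mc2,
        peak_distance=circular_month_distance(agg1.peak_month, agg2.peak_month),
        excluded_sites=tuple(excluded),
    )
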