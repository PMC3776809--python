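"""Synthetic multi-site surveillance-count generator.

Monthly counts are independent Poisson draws around a deterministic
intensity combining a smooth (up to quadratic) secular trend, a 12-month
cosine seasonal cycle that is multiplicative on the trend, and an optional
linear reporting ramp-up that reproduces the near-zero counts often seen at
the start of real records:

    lambda(t) = r(t) * (c0 + c1*t + c2*t^2) * (1 + A*cos(2*pi*(m(t) - phi)/12))

with ``m(t)`` the calendar month of index ``t``, amplitude ``A`` in [0, 1)
(so the intensity stays non-negative) and ``phi`` the peak calendar month.
The normalized climatology of a flat-trend site is then analytically
``1 + A*cos(2*pi*(m - phi)/12)``, which downstream tests exploit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .prep import MonthlySeries

__all__ = [
    "SiteSpec",
    "site_seed",
    "intensity",
    "simulate_site",
    "sector_specs",
    "simulate_sector",
    "cases_from_counts",
    "read_specs",
    "write_specs",
]


@dataclass(frozen=True)
class SiteSpec:
    """Full parameterization of one synthetic site."""

    site_id: str
    latitude: float
    start_year: int
    start_month: int
    n_months: int
    trend_coeffs: tuple[float, float, float]  # (c0, c1, c2) on month index t
    amplitude: float  # A in [0, 1)
    peak_month: int  # phi, 1..12
    ramp_months: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"{self.site_id}: start_month must be in 1..12")
        if self.n_months < 12:
            raise ValueError(f"{self.site_id}: n_months must be >= 12")
        if len(self.trend_coeffs) != 3:
            raise ValueError(f"{self.site_id}: trend_coeffs must be (c0, c1, c2)")
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError(f"{self.site_id}: amplitude must be in [0, 1)")
        if not 1 <= self.peak_month <= 12:
            raise ValueError(f"{self.site_id}: peak_month must be in 1..12")
        if self.ramp_months < 0:
            raise ValueError(f"{self.site_id}: ramp_months must be >= 0")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.site_id}: latitude out of [-90, 90]")
        object.__setattr__(self, "trend_coeffs", tuple(float(c) for c in self.trend_coeffs))


def site_seed(master_seed: int, site_id: str) -> int:
    """Derive a per-site substream seed by stable hashing of the site id.

    Stable across processes and runs (unlike builtin ``hash``), so subsetting
    a simulated world never changes the remaining sites' draws.
    """
    digest = hashlib.sha256(f"{master_seed}:{site_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def intensity(spec: SiteSpec) -> np.ndarray:
    """Deterministic Poisson mean lambda(t) for every month of the span."""
    t = np.arange(spec.n_months, dtype=float)
    c0, c1, c2 = spec.trend_coeffs
    base = c0 + c1 * t + c2 * t**2
    if np.any(base <= 0):
        bad = int(np.flatnonzero(base <= 0)[0])
        raise ValueError(
            f"{spec.site_id}: non-positive trend baseline at month index {bad}"
        )
    month = (spec.start_month - 1 + np.arange(spec.n_months)) % 12 + 1
    seasonal = 1.0 + spec.amplitude * np.cos(2 * np.pi * (month - spec.peak_month) / 12.0)
    ramp = (
        np.minimum(t / spec.ramp_months, 1.0) if spec.ramp_months > 0 else np.ones_like(t)
    )
    return ramp * base * seasonal


def simulate_site(spec: SiteSpec) -> MonthlySeries:
    """Draw one site's monthly counts; reproducible given ``spec.seed``."""
    lam = intensity(spec)  # rejects invalid trends before any sampling
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(lam).astype(float)
    return MonthlySeries(spec.site_id, spec.latitude, spec.start_year, spec.start_month, counts)


def _check_range(name: str, lo, hi) -> None:
    if lo > hi:
        raise ValueError(f"empty {name} range ({lo}, {hi})")


def sector_specs(
    n_sites: int,
    shared_peak: int,
    peak_jitter: int,
    size_range: tuple[float, float],
    span_range: tuple[int, int],
    seed: int,
    amplitude_range: tuple[float, float] = (0.2, 0.5),
    latitude_range: tuple[float, float] = (30.0, 60.0),
    start_year: int = 1990,
    ramp_months: int = 0,
    site_prefix: str = "site",
) -> list[SiteSpec]:
    """Independent site specs sharing a sector-wide peak month (+- jitter).

    Peak months are ``shared_peak`` plus an integer uniform offset in
    [-peak_jitter, +peak_jitter], wrapped modulo 12; ``peak_jitter=6`` makes
    phases effectively uniform over the year (a phase-null sector). Baselines
    (cases/month), spans, amplitudes and latitudes are drawn uniformly from
    their ranges; trends are flat (tune per-site via ``SiteSpec`` directly).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 1 <= shared_peak <= 12:
        raise ValueError("shared_peak must be in 1..12")
    if peak_jitter < 0:
        raise ValueError("peak_jitter must be >= 0")
    _check_range("size", *size_range)
    _check_range("span", *span_range)
    _check_range("amplitude", *amplitude_range)
    _check_range("latitude", *latitude_range)
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_sites):
        sid = f"{site_prefix}{i:02d}"
        jitter = int(rng.integers(-peak_jitter, peak_jitter + 1)) if peak_jitter else 0
        specs.append(
            SiteSpec(
                site_id=sid,
                latitude=float(rng.uniform(*latitude_range)),
                start_year=start_year,
                start_month=1,
                n_months=int(rng.integers(span_range[0], span_range[1] + 1)),
                trend_coeffs=(float(rng.uniform(*size_range)), 0.0, 0.0),
                amplitude=float(rng.uniform(*amplitude_range)),
                peak_month=(shared_peak - 1 + jitter) % 12 + 1,
                ramp_months=ramp_months,
                seed=site_seed(seed, sid),
            )
        )
    return specs


def simulate_sector(
    n_sites: int,
    shared_peak: int,
    peak_jitter: int,
    size_range: tuple[float, float],
    span_range: tuple[int, int],
    seed: int,
    **kwargs,
) -> list[MonthlySeries]:
    """Simulate a whole latitude sector; deterministic under ``seed``."""
    specs = sector_specs(
        n_sites, shared_peak, peak_jitter, size_range, span_range, seed, **kwargs
    )
    return [simulate_site(s) for s in specs]


def cases_from_counts(series: MonthlySeries) -> pd.DataFrame:
    """Expand monthly counts into one case record per case (``site,year,month``).

    The record count in every month equals the input count, and the order is
    stable (chronological). Non-integer counts are an error.
    """
    counts = series.counts
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-9):
        raise ValueError(f"{series.site_id}: counts are not integers")
    reps = rounded.astype(int)
    return pd.DataFrame(
        {
            "site": series.site_id,
            "year": np.repeat(series.years, reps),
            "month": np.repeat(series.calendar_months, reps),
        }
    )


# -- spec collections as human-editable YAML --------------------------------


def write_specs(specs: Sequence[SiteSpec], path) -> None:
    payload = {"sites": [asdict(s) for s in specs]}
    for entry in payload["sites"]:
        entry["trend_coeffs"] = list(entry["trend_coeffs"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_specs(path) -> list[SiteSpec]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "sites" not in payload:
        raise ValueError(f"{path}: expected a mapping with a 'sites' list")
    specs = []
    for entry in payload["sites"]:
        entry = dict(entry)
        entry["trend_coeffs"] = tuple(entry["trend_coeffs"])
        specs.append(SiteSpec(**entry))
    return specs
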