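"""Monthly surveillance series: containers, preprocessing, and delimited-text I/O.

The preprocessing chain mirrors a standard seasonality work-up for
multi-site monthly case counts:

1. drop sites with too few total cases to estimate a seasonal cycle,
2. discard leading calendar years with very low reporting,
3. divide by a fitted quadratic trend to remove secular growth and the
   heteroscedasticity that comes with it,
4. reduce each series to a 12-month climatology (per-calendar-month means)
   and normalize by the overall monthly mean so sites of very different
   sizes carry equal weight downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "Climatology",
    "add_months",
    "aggregate_to_monthly",
    "filter_min_cases",
    "trim_low_years",
    "detrend",
    "climatology",
    "normalize",
    "normalized_climatology",
    "read_cases",
    "read_counts",
    "read_sites",
    "write_cases",
    "write_counts",
]

CASE_COLUMNS = ("site", "year", "month")
COUNT_COLUMNS = ("site", "year", "month", "count")
SITE_COLUMNS = ("site", "latitude")


def add_months(year: int, month: int, k: int) -> tuple[int, int]:
    """Return the (year, month) pair ``k`` months after ``(year, month)``."""
    z = year * 12 + (month - 1) + k
    return z // 12, z % 12 + 1


@dataclass(frozen=True)
class MonthlySeries:
    """A site's consecutive calendar-month count (or ratio) vector.

    Parameters
    ----------
    site_id : str
        Site identifier.
    latitude : float
        Site latitude in degrees, in [-90, 90]; ``nan`` allowed when unknown.
    start_year, start_month : int
        Calendar position of ``counts[0]``; months are 1..12 (January = 1).
    counts : array-like
        One non-negative value per consecutive calendar month. Raw data are
        integer counts; after detrending the values are dimensionless ratios.
    """

    site_id: str
    latitude: float
    start_year: int
    start_month: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError(f"{self.site_id}: counts must be a non-empty 1-D vector")
        if not np.all(np.isfinite(counts)):
            raise ValueError(f"{self.site_id}: counts contain non-finite values")
        if np.any(counts < 0):
            raise ValueError(f"{self.site_id}: counts must be non-negative")
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"{self.site_id}: start_month must be in 1..12")
        if not np.isnan(self.latitude) and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.site_id}: latitude out of [-90, 90]")
        object.__setattr__(self, "counts", counts)

    @property
    def n_months(self) -> int:
        return self.counts.size

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def calendar_months(self) -> np.ndarray:
        """Calendar month (1..12) of every entry."""
        return (self.start_month - 1 + np.arange(self.n_months)) % 12 + 1

    @property
    def years(self) -> np.ndarray:
        """Calendar year of every entry."""
        z = self.start_year * 12 + self.start_month - 1 + np.arange(self.n_months)
        return z // 12

    @property
    def end(self) -> tuple[int, int]:
        """(year, month) of the last entry."""
        return add_months(self.start_year, self.start_month, self.n_months - 1)

    def slice_months(self, i: int, j: int) -> "MonthlySeries":
        """Sub-series covering month indices ``i`` (inclusive) to ``j`` (exclusive)."""
        if not 0 <= i < j <= self.n_months:
            raise ValueError(f"invalid slice [{i}, {j}) of {self.n_months} months")
        y, m = add_months(self.start_year, self.start_month, i)
        return MonthlySeries(self.site_id, self.latitude, y, m, self.counts[i:j])

    def replace_counts(self, values: np.ndarray) -> "MonthlySeries":
        return MonthlySeries(
            self.site_id, self.latitude, self.start_year, self.start_month, values
        )


@dataclass(frozen=True)
class Climatology:
    """Per-calendar-month means with their occurrence counts.

    ``means[m-1]`` is the average value in calendar month ``m`` over the span;
    ``occurrences[m-1]`` is how many times month ``m`` appears; ``overall_mean``
    is total cases divided by total months.
    """

    means: np.ndarray
    occurrences: np.ndarray
    overall_mean: float

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        occ = np.asarray(self.occurrences, dtype=int)
        if means.shape != (12,) or occ.shape != (12,):
            raise ValueError("climatology requires 12 means and 12 occurrence counts")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "occurrences", occ)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def aggregate_to_monthly(
    cases: pd.DataFrame,
    site_id: str,
    start: tuple[int, int],
    n_months: int,
    latitude: float = float("nan"),
) -> MonthlySeries:
    """Count case records of ``site_id`` into consecutive monthly bins.

    Rows belonging to other sites are ignored. A case dated outside the span
    raises ``ValueError`` naming the offending record.
    """
    _validate_case_frame(cases)
    sy, sm = start
    sub = cases[cases["site"] == site_id]
    t = (sub["year"].to_numpy(int) - sy) * 12 + (sub["month"].to_numpy(int) - sm)
    bad = (t < 0) | (t >= n_months)
    if bad.any():
        row = sub[bad].iloc[0]
        raise ValueError(
            f"case outside span for site {site_id}: "
            f"({row['site']!r}, {row['year']}, {row['month']})"
        )
    counts = np.bincount(t, minlength=n_months).astype(float)
    return MonthlySeries(site_id, latitude, sy, sm, counts)


def filter_min_cases(series: MonthlySeries, threshold: int = 30) -> bool:
    """Keep/drop decision: ``True`` (keep) iff total cases >= ``threshold``."""
    return series.total >= threshold


def trim_low_years(
    series: MonthlySeries, primary: int = 24, fallback: int = 12
) -> MonthlySeries:
    """Discard whole leading calendar years with fewer than ``primary`` cases.

    Trimming walks forward from the first (possibly partial) calendar year and
    stops at the first year whose total meets the threshold; interior sparse
    years are never removed. If the primary threshold would discard the entire
    series, the rule is re-applied with ``fallback``. A series empty even under
    the fallback raises ``ValueError`` ("untestable series").

    "Observations" are read as reported cases per calendar year; the result
    always starts at a calendar-year boundary of the original span (or at the
    original start when nothing is trimmed).
    """
    if series.n_months < 12:
        raise ValueError(f"{series.site_id}: series shorter than 12 months")
    years = series.years
    boundaries = np.flatnonzero(np.r_[True, np.diff(years) != 0])
    year_totals = np.add.reduceat(series.counts, boundaries)

    def first_kept(threshold: float) -> int | None:
        for start_idx, total in zip(boundaries, year_totals):
            if total >= threshold:
                return int(start_idx)
        return None

    i0 = first_kept(primary)
    if i0 is None:
        i0 = first_kept(fallback)
    if i0 is None:
        raise ValueError(f"{series.site_id}: untestable series (empty after fallback)")
    if i0 == 0:
        return series
    return series.slice_months(i0, series.n_months)


def detrend(series: MonthlySeries) -> MonthlySeries:
    """Divide by the least-squares quadratic fit over the month index.

    Removes the secular trend and stabilizes the trend-linked variance; output
    values are dimensionless ratios with mean ~1. Zero-count months remain in
    the output as true zeros.
    """
    n = series.n_months
    if n < 3:
        raise ValueError(f"{series.site_id}: need >= 3 months to fit a quadratic")
    t = np.arange(n, dtype=float)
    coeffs = np.polyfit(t, series.counts, 2)
    fit = np.polyval(coeffs, t)
    eps = 1e-6 * float(series.counts.mean())
    if np.any(fit <= eps):
        raise ValueError(f"{series.site_id}: degenerate trend fit")
    return series.replace_counts(series.counts / fit)


def climatology(series: MonthlySeries) -> Climatology:
    """Per-calendar-month means, occurrence counts and the overall mean."""
    cal = series.calendar_months
    occ = np.bincount(cal - 1, minlength=12)
    if np.any(occ == 0):
        missing = int(np.flatnonzero(occ == 0)[0]) + 1
        raise ValueError(
            f"{series.site_id}: calendar month {missing} never occurs in span"
        )
    sums = np.bincount(cal - 1, weights=series.counts, minlength=12)
    return Climatology(sums / occ, occ, series.total / series.n_months)


def normalize(clim: Climatology) -> np.ndarray:
    """Monthly means divided by the overall monthly mean (12 ratios)."""
    if clim.overall_mean <= 0:
        raise ValueError("cannot normalize: overall mean is zero")
    return clim.means / clim.overall_mean


def normalized_climatology(series: MonthlySeries) -> np.ndarray:
    return normalize(climatology(series))


# ---------------------------------------------------------------------------
# delimited-text I/O (UTF-8, comma-delimited, header required)
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _validate_case_frame(df: pd.DataFrame, path: str = "case table") -> None:
    _require_columns(df, CASE_COLUMNS, path)
    month = df["month"]
    if len(df) and not ((month >= 1) & (month <= 12)).all():
        bad = df[(month < 1) | (month > 12)].iloc[0]
        raise ValueError(
            f"{path}: month out of 1..12 in record "
            f"({bad['site']}, {bad['year']}, {bad['month']})"
        )


def read_cases(path) -> pd.DataFrame:
    """Read a case-level table ``site,year,month`` (one row per case)."""
    df = pd.read_csv(path, dtype={"site": str})
    _validate_case_frame(df, path)
    return df[list(CASE_COLUMNS)]


def write_cases(cases: pd.DataFrame, path) -> None:
    _validate_case_frame(cases, path)
    cases[list(CASE_COLUMNS)].to_csv(path, index=False)


def read_sites(path) -> dict[str, float]:
    """Read site metadata ``site,latitude`` into a mapping."""
    df = pd.read_csv(path, dtype={"site": str})
    _require_columns(df, SITE_COLUMNS, path)
    lat = df["latitude"].astype(float)
    if ((lat < -90) | (lat > 90)).any():
        bad = df[(lat < -90) | (lat > 90)].iloc[0]
        raise ValueError(f"{path}: latitude out of range for site {bad['site']}")
    if df["site"].duplicated().any():
        dup = df[df["site"].duplicated()].iloc[0]["site"]
        raise ValueError(f"{path}: duplicate site metadata row for {dup}")
    return dict(zip(df["site"], lat))


def read_counts(
    path, latitudes: Mapping[str, float] | None = None
) -> list[MonthlySeries]:
    """Read long-format monthly counts ``site,year,month,count``.

    Rows of each site must form a gap-free run of consecutive calendar months
    (missing months must be written as explicit zeros); anything else is a
    data error, reported with the site name.
    """
    df = pd.read_csv(path, dtype={"site": str})
    _require_columns(df, COUNT_COLUMNS, path)
    if len(df) and not ((df["month"] >= 1) & (df["month"] <= 12)).all():
        raise ValueError(f"{path}: month values out of 1..12")
    if len(df) and (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    out: list[MonthlySeries] = []
    for site, sub in df.groupby("site", sort=False):
        sub = sub.sort_values(["year", "month"], kind="stable")
        z = sub["year"].to_numpy(int) * 12 + sub["month"].to_numpy(int) - 1
        if len(z) > 1 and not np.all(np.diff(z) == 1):
            raise ValueError(
                f"{path}: site {site} has gaps or duplicate months "
                "(missing months must be explicit zeros)"
            )
        lat = float("nan") if latitudes is None else float(latitudes.get(site, float("nan")))
        out.append(
            MonthlySeries(
                str(site),
                lat,
                int(sub["year"].iloc[0]),
                int(sub["month"].iloc[0]),
                sub["count"].to_numpy(float),
            )
        )
    return out


def write_counts(series: Iterable[MonthlySeries], path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "site": s.site_id,
                    "year": s.years,
                    "month": s.calendar_months,
                    "count": s.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
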