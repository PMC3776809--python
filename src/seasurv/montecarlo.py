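"""Per-site Monte Carlo test of the largest monthly-mean difference.

The observed statistic is D = (highest calendar-month mean) minus (lowest
calendar-month mean). Its null distribution is built by repeatedly
reassigning every case of the record to a random month and recomputing D
through the identical climatology pipeline; the p-value is the add-one rank
of the observed D within the simulated set, so it can never be zero and its
floor with 10,000 replicates is 1/10001 (prints as 0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prep import Climatology, MonthlySeries, climatology, detrend

__all__ = ["McResult", "observed_stat", "site_mc_test", "half_split"]


@dataclass(frozen=True)
class McResult:
    observed_stat: float  # D, in cases/month
    n_sims: int
    p_value: float  # add-one rank p, in [1/(n_sims+1), 1]
    seed: int


def observed_stat(clim: Climatology) -> float:
    """D = max monthly mean - min monthly mean."""
    return float(clim.means.max() - clim.means.min())


def _means_from_slot_counts(counts: np.ndarray, cal: np.ndarray, occ: np.ndarray) -> np.ndarray:
    """Calendar-month means for each row of a (reps, n_months) count matrix."""
    weight = np.zeros((cal.size, 12))
    weight[np.arange(cal.size), cal - 1] = 1.0 / occ[cal - 1]
    return counts @ weight


def site_mc_test(
    series: MonthlySeries,
    n_sims: int = 10000,
    seed: int = 0,
    method: str = "slots",
    detrended: bool = False,
) -> McResult:
    """Monte Carlo significance of the observed max-minus-min monthly mean.

    Parameters
    ----------
    series : MonthlySeries
        Raw integer monthly counts spanning all 12 calendar months.
    n_sims : int
        Number of random case reassignments (default 10,000).
    method : {"slots", "labels"}
        "slots" (default) reassigns each case uniformly over the record's
        individual months, so calendar months appearing more often in the
        span receive proportionally more mass; "labels" reassigns uniformly
        over the 12 calendar-month labels.
    detrended : bool
        Compute the statistic on quadratically detrended values instead of
        raw counts; the identical transform is applied to observed data and
        to every replicate ("slots" only).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    counts = series.counts
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-9):
        raise ValueError(f"{series.site_id}: Monte Carlo test requires integer counts")
    total = int(rounded.sum())
    if total == 0:
        raise ValueError(f"{series.site_id}: zero cases, nothing to reassign")
    cal = series.calendar_months
    occ = np.bincount(cal - 1, minlength=12)
    if np.any(occ == 0):
        raise ValueError(f"{series.site_id}: span does not cover all 12 calendar months")
    if method not in ("slots", "labels"):
        raise ValueError(f"unknown reassignment method {method!r}")
    if detrended and method == "labels":
        raise ValueError("detrended statistic requires the 'slots' method")

    n = series.n_months
    if detrended:
        # shared quadratic hat matrix: fitted = counts @ hat.T
        x = np.vander(np.arange(n, dtype=float), 3, increasing=True)
        hat = x @ np.linalg.pinv(x)

        def pipeline(mat: np.ndarray) -> np.ndarray:
            fitted = mat @ hat.T
            eps = 1e-6 * mat.mean(axis=1, keepdims=True)
            if np.any(fitted <= eps):
                raise ValueError(f"{series.site_id}: degenerate trend fit in replicate")
            return _means_from_slot_counts(mat / fitted, cal, occ)

    else:

        def pipeline(mat: np.ndarray) -> np.ndarray:
            return _means_from_slot_counts(mat, cal, occ)

    if detrended:
        obs_means = climatology(detrend(series)).means
    else:
        obs_means = climatology(series).means
    d_obs = float(obs_means.max() - obs_means.min())

    rng = np.random.default_rng(np.random.SeedSequence([seed & (2**63 - 1)]))
    exceed = 0
    chunk = max(1, int(2e7 // max(n, 12)))
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        if method == "slots":
            sims = rng.multinomial(total, np.full(n, 1.0 / n), size=b).astype(float)
            means = pipeline(sims)
        else:
            label_counts = rng.multinomial(total, np.full(12, 1.0 / 12), size=b)
            means = label_counts / occ
        d_sim = means.max(axis=1) - means.min(axis=1)
        exceed += int(np.count_nonzero(d_sim >= d_obs))
        done += b
    p = (exceed + 1) / (n_sims + 1)
    return McResult(observed_stat=d_obs, n_sims=n_sims, p_value=p, seed=seed)


def half_split(series: MonthlySeries) -> tuple[MonthlySeries, MonthlySeries]:
    """Split into first ceil(n/2) months and the remainder, at a month boundary."""
    n = series.n_months
    if n < 24:
        raise ValueError(f"{series.site_id}: span too short to split ({n} < 24 months)")
    k = (n + 1) // 2
    return series.slice_months(0, k), series.slice_months(k, n)
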