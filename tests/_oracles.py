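"""Independent brute-force oracles, deliberately naive (loops, no numpy tricks).

These stay decoupled from the package implementations they check.
"""


def brute_max_rank_sum(ranks):
    """(T, window_start) by direct summation over all 12 circular windows."""
    ranks = list(ranks)
    best, best_start = -1, None
    for start in range(12):
        total = 0
        for j in range(6):
            total += ranks[(start + j) % 12]
        if total > best:
            best, best_start = total, start + 1
    return best, best_start


def brute_monthly_mean_range(counts, start_month):
    """max - min calendar-month mean computed with plain dicts and loops."""
    sums: dict[int, float] = {}
    occ: dict[int, int] = {}
    for t, c in enumerate(counts):
        m = (start_month - 1 + t) % 12 + 1
        sums[m] = sums.get(m, 0.0) + float(c)
        occ[m] = occ.get(m, 0) + 1
    means = [sums[m] / occ[m] for m in sorted(sums)]
    return max(means) - min(means)
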