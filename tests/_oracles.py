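"""Independent brute-force oracles used to check the fast implementations.

These deliberately use per-day boolean grids and exhaustive pair counting,
not the interval arithmetic of the package.
"""

from __future__ import annotations

import math


def day_grid_pdc_mpr(
    dispenses: list[tuple[int, int | None]], n_days: int
) -> tuple[float, float]:
    """(pdc, mpr) by walking every day of the window.

    ``dispenses`` are (day offset, days supplied or None) pairs with unique
    offsets; offsets outside [0, n_days) are ignored, mirroring the window
    rule.
    """
    inw = sorted((d for d in dispenses if 0 <= d[0] < n_days), key=lambda t: t[0])
    excluded = [False] * n_days
    for i, (off, days) in enumerate(inw):
        if days is None:
            end = inw[i + 1][0] if i + 1 < len(inw) else n_days
            for d in range(off, end):
                excluded[d] = True
    covered = [False] * n_days
    supply_end: float | None = None
    starts = {off: days for off, days in inw}
    for day in range(n_days):
        if day in starts:
            days = starts[day]
            supply_end = None if days is None else day + days
        if supply_end is not None and day < supply_end:
            covered[day] = True
    denom = sum(1 for e in excluded if not e)
    if not inw or denom == 0:
        return math.nan, math.nan
    pdc = sum(1 for c, e in zip(covered, excluded) if c and not e) / denom
    total_supply = sum(d for _, d in inw if d is not None)
    mpr = min(1.0, total_supply / denom)
    return pdc, mpr


def brute_tvr(dispenses: list[tuple[int, int | None]], n_days: int) -> float:
    """Timely-visit ratio by enumerating every refill due date."""
    all_offsets = sorted(off for off, _ in dispenses)
    opportunities = 0
    timely = 0
    for off, days in dispenses:
        if days is None:
            continue
        due = off + days
        if not 0 <= due < n_days:
            continue
        opportunities += 1
        if any(off < x <= due + 2 for x in all_offsets):
            timely += 1
    return timely / opportunities if opportunities else math.nan


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive comparison of every positive-negative pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def empirical_survival(times, period: int) -> float:
    """Uncensored survival fraction: P(T > period)."""
    times = list(times)
    return sum(1 for t in times if t > period) / len(times)
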