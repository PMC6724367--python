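"""Shared fixtures and independent brute-force / closed-form oracles.

The oracles here deliberately avoid the code paths they check: connected
components by recursive flood fill over explicit neighbour offsets, p-values
from textbook formulas evaluated through scipy.special CDFs, and exact
Mann-Whitney tail probabilities by enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import special


# ---------------------------------------------------------------------------
# brute-force connected components


def _neighbors(ndim: int, full: bool):
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        if not full and sum(abs(o) for o in off) != 1:
            continue
        yield off


def flood_fill_count(binary: np.ndarray, full_connectivity: bool,
                     min_size: int = 1) -> int:
    """Component count by iterative flood fill (oracle for label-based counts)."""
    binary = np.asarray(binary).astype(bool)
    offsets = list(_neighbors(binary.ndim, full_connectivity))
    seen = np.zeros_like(binary, dtype=bool)
    count = 0
    for idx in zip(*np.nonzero(binary)):
        if seen[idx]:
            continue
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if any(not 0 <= c < s for c, s in zip(nxt, binary.shape)):
                    continue
                if binary[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    stack.append(nxt)
        if size >= min_size:
            count += 1
    return count


# ---------------------------------------------------------------------------
# closed-form p-value oracles


def rank_average(values: np.ndarray) -> np.ndarray:
    """Average ranks, hand-built from argsort (oracle rankdata)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def oracle_student_p(a, b) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * special.stdtr(na + nb - 2, -abs(t))


def oracle_welch_p(a, b) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, 2 * special.stdtr(df, -abs(t))


def oracle_mw_asymptotic_p(a, b) -> tuple[float, float]:
    """Normal approximation with tie and continuity corrections."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    big_n = na + nb
    r = rank_average(combined)
    u1 = r[:na].sum() - na * (na + 1) / 2.0
    u = max(u1, na * nb - u1)
    mu = na * nb / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie = float((counts**3 - counts).sum())
    sigma2 = na * nb / 12.0 * (big_n + 1 - tie / (big_n * (big_n - 1)))
    z = (u - mu - 0.5) / math.sqrt(sigma2)
    return u1, min(1.0, 2 * special.ndtr(-z))


def oracle_mw_exact_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    assert np.unique(combined).size == combined.size, "exact oracle needs no ties"
    ranks = rank_average(combined)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    u_obs = max(u_obs, na * nb - u_obs)
    total = 0
    extreme = 0
    all_ranks = np.arange(1, na + nb + 1)
    for subset in itertools.combinations(range(na + nb), na):
        u = all_ranks[list(subset)].sum() - na * (na + 1) / 2.0
        u = max(u, na * nb - u)
        total += 1
        extreme += u >= u_obs
    return u_obs, extreme / total


def oracle_kruskal_p(groups) -> tuple[float, float]:
    arrays = [np.asarray(g, float) for g in groups]
    combined = np.concatenate(arrays)
    big_n = combined.size
    r = rank_average(combined)
    h = 0.0
    idx = 0
    for g in arrays:
        h += r[idx:idx + g.size].sum() ** 2 / g.size
        idx += g.size
    h = 12.0 / (big_n * (big_n + 1)) * h - 3 * (big_n + 1)
    _, counts = np.unique(combined, return_counts=True)
    h /= 1.0 - float((counts**3 - counts).sum()) / (big_n**3 - big_n)
    return h, special.chdtrc(len(arrays) - 1, h)


def oracle_ols(x, y) -> tuple[float, float, float]:
    """Slope, intercept, R^2 from the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    return slope, intercept, 1.0 - ss_res / ss_tot


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
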