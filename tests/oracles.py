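"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths of the package (separable
uniform filters, scipy labeling, scipy test statistics): local window
statistics come from explicit mirror padding plus a window view, the
component count from an explicit flood fill, and the exact p-values
from direct enumeration of the null distributions.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sliding_local_stats(pixels: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Window mean and population SD via explicit symmetric padding."""
    padded = np.pad(pixels, radius, mode="symmetric")
    windows = sliding_window_view(padded, (2 * radius + 1, 2 * radius + 1))
    mean = windows.mean(axis=(-1, -2))
    sd = windows.std(axis=(-1, -2))  # population (ddof=0)
    return mean, sd


def sliding_phansalkar_mask(
    pixels: np.ndarray, radius: int, k=0.25, p=2.0, q=10.0, r_dyn=0.5
) -> np.ndarray:
    """Deficit mask from the sliding-window stats; deficit iff v <= T."""
    m, s = sliding_local_stats(pixels, radius)
    threshold = m * (1.0 + p * np.exp(-q * m) + k * (s / r_dyn - 1.0))
    return pixels <= threshold


def flood_fill_components(mask: np.ndarray) -> list[int]:
    """Component sizes under 8-connectivity via explicit stack flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    sizes = []
    rows, cols = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            r, c = stack.pop()
            size += 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        sizes.append(size)
    return sorted(sizes)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks computed from scratch (average of 1-based positions)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def enumerate_signed_rank_p(x, y) -> float:
    """Exact two-sided signed-rank p by enumerating every sign assignment."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = _midranks(np.abs(d))
    observed = ranks[d > 0].sum()
    dist = [
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product((False, True), repeat=d.size)
    ]
    dist = np.asarray(dist)
    lo = np.mean(dist <= observed + 1e-9)
    hi = np.mean(dist >= observed - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def enumerate_mann_whitney_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1 = x.size
    ranks = _midranks(np.concatenate([x, y]))
    observed = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dist = np.asarray(
        [sum(c) - n1 * (n1 + 1) / 2.0 for c in itertools.combinations(ranks, n1)]
    )
    lo = np.mean(dist <= observed + 1e-9)
    hi = np.mean(dist >= observed - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))
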