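"""Brute-force reference implementations used only to cross-check the package.

Each oracle recomputes a quantity by the most literal method available —
explicit loops, flood fill, root bracketing — independent of the package's
vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np


def phansalkar_brute_force(
    normalized: np.ndarray,
    radius: int,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Per-pixel loop over the circular window, truncated at image borders."""
    rows, cols = normalized.shape
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    out = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            vals = [
                normalized[i + dr, j + dc]
                for dr, dc in offsets
                if 0 <= i + dr < rows and 0 <= j + dc < cols
            ]
            n = len(vals)
            mu = sum(vals) / n
            var = sum(v * v for v in vals) / n - mu * mu
            sd = math.sqrt(max(var, 0.0))
            thresh = mu * (1.0 + p * math.exp(-q * mu) + k * (sd / r - 1.0))
            out[i, j] = normalized[i, j] > thresh
    return out


def count_components_flood_fill(mask: np.ndarray, connectivity: int = 8) -> int:
    """Count foreground components by iterative flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        neigh = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    rows, cols = mask.shape
    n = 0
    for i in range(rows):
        for j in range(cols):
            if not mask[i, j] or seen[i, j]:
                continue
            n += 1
            stack = [(i, j)]
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                for da, db in neigh:
                    r2, c2 = a + da, b + db
                    if 0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2] and not seen[r2, c2]:
                        seen[r2, c2] = True
                        stack.append((r2, c2))
    return n


def half_max_width_by_bracketing(a: float, b: float, c: float, d: float) -> float:
    """Width of y = a + (b-a)exp(-(x-c)²/2d²) at half height, by bisection."""
    half = (a + b) / 2.0

    def f(x):
        return a + (b - a) * math.exp(-((x - c) ** 2) / (2.0 * d * d)) - half

    def bisect(lo, hi):
        flo = f(lo)
        for _ in range(200):
            mid = (lo + hi) / 2.0
            fm = f(mid)
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        return (lo + hi) / 2.0

    span = 20.0 * abs(d)
    left = bisect(c - span, c)
    right = bisect(c + span, c)
    return right - left


def group_rows_by_key(rows: list[dict], key: str) -> dict[str, list[dict]]:
    """Hand-rolled group-by for cross-checking table aggregation."""
    out: dict[str, list[dict]] = {}
    for row in rows:
        out.setdefault(row[key], []).append(row)
    return out
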