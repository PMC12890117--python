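"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def ols_slope_oracle(x, y) -> float:
    """Closed-form least-squares slope: Σ(x−x̄)(y−ȳ) / Σ(x−x̄)²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    return float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))


def ols_line_oracle(x, y) -> tuple[float, float, float]:
    """Slope, intercept and R² from the normal equations, written naively."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    m = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    b = (sy - m * sx) / n
    pred = m * x + b
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(m), float(b), r2


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> list[set]:
    """Brute-force connected components by iterative flood fill.

    Returns a list of pixel-coordinate sets, one per component.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    components = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            comp = set()
            while stack:
                rr, cc = stack.pop()
                comp.add((rr, cc))
                for dr, dc in neigh:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            components.append(comp)
    return components


def anova_oracle(groups) -> tuple[float, int, int]:
    """From-scratch one-way ANOVA F statistic and degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n = all_values.size
    return float((ssb / (k - 1)) / (ssw / (n - k))), k - 1, n - k
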