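"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain loops and per-class renormalization, sharing no
code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def kapur_oracle(histogram) -> int:
    """Exhaustive search over all 256 candidate thresholds.

    For each t, normalize the histogram within the <=t and >t classes and
    sum their Shannon entropies (natural log, 0*ln 0 := 0); skip t if either
    class is empty.  Return the lowest t attaining the maximal sum.
    """
    hist = [float(c) for c in histogram]
    assert len(hist) == 256
    best_t, best_score = None, -math.inf
    for t in range(256):
        low = hist[: t + 1]
        high = hist[t + 1 :]
        w_low, w_high = sum(low), sum(high)
        if w_low == 0 or w_high == 0:
            continue
        score = 0.0
        for c in low:
            p = c / w_low
            if p > 0:
                score -= p * math.log(p)
        for c in high:
            p = c / w_high
            if p > 0:
                score -= p * math.log(p)
        if score > best_score:
            best_score, best_t = score, t
    if best_t is None:
        raise ValueError("degenerate histogram")
    return best_t


def count_components_floodfill(mask) -> list[int]:
    """8-connected component sizes by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    sizes = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                sizes.append(size)
    return sizes
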