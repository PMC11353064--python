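"""Independent brute-force oracles for the constrained cosine fits.

These deliberately avoid the closed-form regression algebra used by the
implementation: they evaluate the residual sum of squares directly on
dense parameter grids and keep the best point, refining once around it.
"""

from __future__ import annotations

import numpy as np


def sse_direct(x: np.ndarray, y: np.ndarray, a: float, b: float, c: float = 0.0) -> float:
    resid = y - (a * np.cos(x + c) + b)
    return float(resid @ resid)


def brute_force_fixed(x, y, a_lo=-12.0, a_hi=0.0, b_lo=-15.0, b_hi=15.0,
                      coarse=0.01, fine=0.0005):
    """Two-stage 2-D grid search over (a <= 0, b) with c = 0.

    Coarse pass at `coarse` step over the full ranges, then a `fine`-step
    refinement in a +/- 2*coarse box around the coarse optimum.  The
    discretization SSE excess at the fine step is far below 1e-4 for
    profiles of order-unity scale.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def search(a_grid, b_grid):
        best = (np.inf, 0.0, 0.0)
        w = np.cos(x)
        for a in a_grid:
            # vectorized over b: residual (B, 5)
            resid = y[None, :] - (a * w)[None, :] - b_grid[:, None]
            sse = np.einsum("ij,ij->i", resid, resid)
            k = int(np.argmin(sse))
            if sse[k] < best[0]:
                best = (float(sse[k]), float(a), float(b_grid[k]))
        return best

    a_grid = np.arange(a_lo, a_hi + coarse / 2, coarse)
    b_grid = np.arange(b_lo, b_hi + coarse / 2, coarse)
    sse0, a0, b0 = search(a_grid, b_grid)
    a_grid = np.arange(max(a_lo, a0 - 2 * coarse), min(a_hi, a0 + 2 * coarse) + fine / 2, fine)
    b_grid = np.arange(b0 - 2 * coarse, b0 + 2 * coarse + fine / 2, fine)
    sse1, a1, b1 = search(a_grid, b_grid)
    return {"sse": sse1, "a": a1, "b": b1}


def brute_force_free(x, y, c_step=0.01, a_lo=-12.0, a_hi=0.0,
                     b_lo=-15.0, b_hi=15.0, ab_step=0.05, fine=0.002):
    """3-D grid search over (a <= 0, b, c), refined once around the optimum."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def search(c_grid, a_grid, b_grid):
        best = (np.inf, 0.0, 0.0, 0.0)
        for c in c_grid:
            w = np.cos(x + c)
            # (A, B) SSE surface via residual evaluation, chunked over a
            for a in a_grid:
                resid = y[None, :] - (a * w)[None, :] - b_grid[:, None]
                sse = np.einsum("ij,ij->i", resid, resid)
                k = int(np.argmin(sse))
                if sse[k] < best[0]:
                    best = (float(sse[k]), float(a), float(b_grid[k]), float(c))
        return best

    c_grid = np.arange(0.0, 2.0 * np.pi, c_step)
    a_grid = np.arange(a_lo, a_hi + ab_step / 2, ab_step)
    b_grid = np.arange(b_lo, b_hi + ab_step / 2, ab_step)
    _, a0, b0, c0 = search(c_grid, a_grid, b_grid)

    c_grid = np.arange(c0 - 2 * c_step, c0 + 2 * c_step, fine)
    a_grid = np.arange(max(a_lo, a0 - 2 * ab_step), min(a_hi, a0 + 2 * ab_step) + fine / 2, fine)
    b_grid = np.arange(b0 - 2 * ab_step, b0 + 2 * ab_step + fine / 2, fine)
    sse1, a1, b1, c1 = search(c_grid, a_grid, b_grid)
    return {"sse": sse1, "a": a1, "b": b1, "c": float(np.mod(c1, 2.0 * np.pi))}
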