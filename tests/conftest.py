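import numpy as np
import pytest

from syntroflux.catalog import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def grid_search_extents(S, y, weights=None, lo=0.0, hi=0.5, step=1e-3):
    """Solver-independent oracle: grid search for the weighted NNLS optimum.

    Exhaustive 11-point-per-axis grids, iteratively zoomed around the best
    point until the grid spacing reaches ``step``.  The objective is convex,
    so zooming tracks the global constrained minimum.  Returns (best point,
    best SSE).
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float)
    d = S.shape[1]
    if weights is None:
        weights = np.ones(S.shape[0])
    W = np.diag(weights)
    lo = np.full(d, float(lo))
    hi = np.full(d, float(hi))
    while True:
        axes = [np.linspace(lo[i], hi[i], 11) for i in range(d)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        resid = W @ (S @ pts.T - y[:, None])
        sse = (resid**2).sum(axis=0)
        k = int(np.argmin(sse))
        best, best_sse = pts[k], float(sse[k])
        spacing = (hi - lo) / 10.0
        if spacing.max() <= step:
            return best, best_sse
        lo = np.maximum(best - spacing, 0.0)
        hi = best + spacing


@pytest.fixture(scope="session")
def grid_oracle():
    return grid_search_extents
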