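"""Numerical kernels for the pruning likelihood.

A numba-jitted fused kernel (matrix-vector products, partial products,
per-pattern rescaling in one pass) is used when numba is importable; a
vectorized numpy fallback keeps results identical (same operation order per
node) at lower speed.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _prune_numba(partial, logscale, nodes, child_flat, child_ptr, P):
    n_cat = partial.shape[1]
    n_pat = partial.shape[2]
    acc = np.empty((n_cat, n_pat, 4))
    sc = np.empty(n_pat)
    for vi in range(nodes.shape[0]):
        v = nodes[vi]
        first = True
        for p in range(n_pat):
            sc[p] = 0.0
        for ci in range(child_ptr[v], child_ptr[v + 1]):
            c = child_flat[ci]
            for cat in range(n_cat):
                Pm = P[c, cat]
                for p in range(n_pat):
                    b0 = partial[c, cat, p, 0]
                    b1 = partial[c, cat, p, 1]
                    b2 = partial[c, cat, p, 2]
                    b3 = partial[c, cat, p, 3]
                    for i in range(4):
                        m = (
                            Pm[i, 0] * b0 + Pm[i, 1] * b1
                            + Pm[i, 2] * b2 + Pm[i, 3] * b3
                        )
                        if first:
                            acc[cat, p, i] = m
                        else:
                            acc[cat, p, i] *= m
            for p in range(n_pat):
                sc[p] += logscale[c, p]
            first = False
        for p in range(n_pat):
            mx = 0.0
            for cat in range(n_cat):
                for i in range(4):
                    if acc[cat, p, i] > mx:
                        mx = acc[cat, p, i]
            if mx <= 0.0:
                mx = 1.0
            inv = 1.0 / mx
            for cat in range(n_cat):
                for i in range(4):
                    partial[v, cat, p, i] = acc[cat, p, i] * inv
            logscale[v, p] = sc[p] + np.log(mx)


def _prune_numpy(partial, logscale, nodes, child_flat, child_ptr, P):
    for v in nodes:
        acc = None
        sc = None
        for ci in range(child_ptr[v], child_ptr[v + 1]):
            c = child_flat[ci]
            M = np.empty_like(partial[c])
            for cat in range(partial.shape[1]):
                np.dot(partial[c, cat], P[c, cat].T, out=M[cat])
            acc = M if acc is None else acc * M
            sc = logscale[c].copy() if sc is None else sc + logscale[c]
        mx = acc.max(axis=2).max(axis=0)
        mx = np.where(mx > 0, mx, 1.0)
        partial[v] = acc / mx[None, :, None]
        logscale[v] = sc + np.log(mx)


def prune(partial, logscale, nodes, child_flat, child_ptr, P):
    """Recompute conditional likelihoods at ``nodes`` (a postorder-ordered
    int64 array of internal node indices) in place."""
    if len(nodes) == 0:
        return
    if HAVE_NUMBA:
        _prune_numba(partial, logscale, nodes, child_flat, child_ptr, P)
    else:
        _prune_numpy(partial, logscale, nodes, child_flat, child_ptr, P)
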