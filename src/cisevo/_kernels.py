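"""Numba-compiled inner loops.

These kernels mirror the reference (pure NumPy) implementations exactly;
they exist only because the population model calls them millions of times.
If numba is unavailable the callers fall back to the NumPy paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def scan_codes(codes: np.ndarray) -> np.ndarray:
    """Rolling 8-mer indices over a base-code array (A=0..T=3)."""
    k = 8
    m = codes.size - k + 1
    out = np.empty(m, dtype=np.int64)
    idx = 0
    for p in range(k):
        idx = idx * 4 + codes[p]
    out[0] = idx
    top = 4 ** (k - 1)
    for t in range(1, m):
        idx = (idx - codes[t - 1] * top) * 4 + codes[t + k - 1]
        out[t] = idx
    return out


@njit(cache=True)
def develop_kernel(wv, init, alpha, tau, tol, max_iter):
    """Iterate s -> sigmoid(wv @ s); windowed-variance stability test.

    Returns (stable, iterations, phenotype); phenotype is the window mean
    (zeros when unstable).
    """
    n = wv.shape[0]
    hist = np.empty((max_iter + 1, n))
    s = init.copy()
    for i in range(n):
        hist[0, i] = s[i]
    for t in range(1, max_iter + 1):
        new = np.empty(n)
        for i in range(n):
            u = 0.0
            for j in range(n):
                u += wv[i, j] * s[j]
            new[i] = 1.0 / (1.0 + np.exp(-alpha * u))
        s = new
        for i in range(n):
            hist[t, i] = s[i]
        if t >= tau:
            total = 0.0
            for i in range(n):
                m = 0.0
                for tp in range(t - tau + 1, t + 1):
                    m += hist[tp, i]
                m /= tau
                for tp in range(t - tau + 1, t + 1):
                    d = hist[tp, i] - m
                    total += d * d
            if total / (tau * n) < tol:
                # phenotype = the equilibrium pattern itself (current state);
                # the window mean only defines the stability measure
                return True, t, s
    return False, max_iter, np.zeros(n)


@njit(cache=True)
def row_sums(stack, idx):
    """Per-TF kappa sums over a window-index array: one w row."""
    n_tf = stack.shape[0]
    out = np.zeros(n_tf)
    for t in range(idx.size):
        col = idx[t]
        for j in range(n_tf):
            out[j] += stack[j, col]
    return out
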