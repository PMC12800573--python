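"""Numba-accelerated pruning kernel.

The likelihood of one trait (or trait pair) is evaluated tens of thousands
of times during screening and calibration, so the hot path — transition
matrices for every edge plus the postorder partial-likelihood recursion —
is compiled with numba.  The kernel signals ill-conditioned
eigendecompositions (near-defective generators) by returning NaN, in which
case the caller falls back to the plain numpy/scipy path.

If numba is unavailable the package silently uses the numpy implementation.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


LOG_ZERO = -1e308


@njit(cache=True)
def _loglik_eig(
    Q: np.ndarray,
    edge_len: np.ndarray,
    postorder: np.ndarray,
    child_flat: np.ndarray,
    child_off: np.ndarray,
    tip_partial: np.ndarray,
    root: int,
    prior: np.ndarray,
) -> float:
    """Pruning log-likelihood with eigendecomposition transition matrices.

    Returns NaN when the eigendecomposition is unreliable (caller must fall
    back), LOG_ZERO when the data have zero likelihood.
    """
    S = Q.shape[0]
    n = edge_len.shape[0]
    w, V = np.linalg.eig(Q.astype(np.complex128))
    Vinv = np.linalg.inv(V)
    P = np.empty((n, S, S))
    for v in range(n):
        t = edge_len[v]
        ew = np.exp(w * t)
        bad = False
        for i in range(S):
            rowsum = 0.0
            for j in range(S):
                acc = 0.0 + 0.0j
                for k in range(S):
                    acc += V[i, k] * ew[k] * Vinv[k, j]
                p = acc.real
                if p < 0.0:
                    p = 0.0
                elif p > 1.0:
                    p = 1.0
                P[v, i, j] = p
                rowsum += p
            if np.abs(rowsum - 1.0) > 1e-8:
                bad = True
            if rowsum > 0.0:
                for j in range(S):
                    P[v, i, j] /= rowsum
        if bad:
            return np.nan
    L = tip_partial.copy()
    logscale = 0.0
    buf = np.empty(S)
    for idx in range(postorder.shape[0]):
        v = postorder[idx]
        c0, c1 = child_off[v], child_off[v + 1]
        if c1 == c0:
            continue
        for s in range(S):
            buf[s] = 1.0
        for ci in range(c0, c1):
            c = child_flat[ci]
            for s in range(S):
                acc = 0.0
                for sp in range(S):
                    acc += P[c, s, sp] * L[c, sp]
                buf[s] *= acc
        mx = buf[0]
        for s in range(1, S):
            if buf[s] > mx:
                mx = buf[s]
        if mx <= 0.0:
            return LOG_ZERO
        for s in range(S):
            L[v, s] = buf[s] / mx
        logscale += np.log(mx)
    lik = 0.0
    for s in range(S):
        lik += prior[s] * L[root, s]
    if lik <= 0.0:
        return LOG_ZERO
    return np.log(lik) + logscale
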