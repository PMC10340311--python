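"""GRU recurrence kernels.

The sequential time loop dominates training cost, so it is compiled with
numba when available; the big input/weight GEMMs stay in NumPy/BLAS.  A
pure-NumPy fallback keeps the package importable without numba (identical
results, just slower).

Layouts are batch-major: ``gx`` is the precomputed input projection
(B, T, 3H) with gate order (update z, reset r, candidate n); ``U`` is the
recurrent kernel (H, 3H).  ``reverse=True`` processes time back-to-front
(the backward direction of a bidirectional layer) without any array copies;
cache slices stay indexed by absolute time.
"""

from __future__ import annotations

import numpy as np


def _gru_forward_py(gx: np.ndarray, U: np.ndarray, reverse: bool):
    B, T, H3 = gx.shape
    H = H3 // 3
    dt = gx.dtype
    Z = np.empty((B, T, H), dt)
    R = np.empty((B, T, H), dt)
    N = np.empty((B, T, H), dt)
    UN = np.empty((B, T, H), dt)
    HP = np.empty((B, T, H), dt)
    out = np.empty((B, T, H), dt)
    h = np.zeros((B, H), dt)
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        u = h @ U
        g = gx[:, t]
        with np.errstate(over="ignore"):
            z = 1.0 / (1.0 + np.exp(-(g[:, :H] + u[:, :H])))
            r = 1.0 / (1.0 + np.exp(-(g[:, H : 2 * H] + u[:, H : 2 * H])))
        un = u[:, 2 * H :]
        n = np.tanh(g[:, 2 * H :] + r * un)
        HP[:, t] = h
        h = (1.0 - z) * n + z * h
        Z[:, t], R[:, t], N[:, t], UN[:, t], out[:, t] = z, r, n, un, h
    return out, Z, R, N, UN, HP


def _gru_backward_py(dy, Z, R, N, UN, HP, Ut, reverse: bool):
    B, T, H = Z.shape
    dt = Z.dtype
    dGx = np.empty((B, T, 3 * H), dt)
    dUin = np.empty((B, T, 3 * H), dt)
    dh = np.zeros((B, H), dt)
    order = range(T) if reverse else range(T - 1, -1, -1)
    for t in order:
        dht = dy[:, t] + dh
        z, r, n, un, hp = Z[:, t], R[:, t], N[:, t], UN[:, t], HP[:, t]
        dn = dht * (1.0 - z)
        dz = dht * (hp - n)
        dh = dht * z
        dan = dn * (1.0 - n * n)
        dun = dan * r
        dr = dan * un
        daz = dz * z * (1.0 - z)
        dar = dr * r * (1.0 - r)
        dGx[:, t, :H] = daz
        dGx[:, t, H : 2 * H] = dar
        dGx[:, t, 2 * H :] = dan
        dUin[:, t, :H] = daz
        dUin[:, t, H : 2 * H] = dar
        dUin[:, t, 2 * H :] = dun
        dh = dh + dUin[:, t] @ Ut
    return dGx, dUin


try:  # pragma: no cover - numba path is the one normally exercised
    import numba

    @numba.njit(cache=True, inline="always", fastmath=True)
    def _sig(v):
        if v >= 0.0:
            return 1.0 / (1.0 + np.exp(-v))
        e = np.exp(v)
        return e / (1.0 + e)

    @numba.njit(cache=True, fastmath=True)
    def _gru_forward_nb(gx, U, reverse):
        B, T, H3 = gx.shape
        H = H3 // 3
        dt = gx.dtype
        Z = np.empty((B, T, H), dt)
        R = np.empty((B, T, H), dt)
        N = np.empty((B, T, H), dt)
        UN = np.empty((B, T, H), dt)
        HP = np.empty((B, T, H), dt)
        out = np.empty((B, T, H), dt)
        h = np.zeros((B, H), dt)
        for s in range(T):
            t = T - 1 - s if reverse else s
            u = np.dot(h, U)
            for i in range(B):
                for j in range(H):
                    z = _sig(gx[i, t, j] + u[i, j])
                    r = _sig(gx[i, t, H + j] + u[i, H + j])
                    un = u[i, 2 * H + j]
                    n = np.tanh(gx[i, t, 2 * H + j] + r * un)
                    hp = h[i, j]
                    hn = (1.0 - z) * n + z * hp
                    Z[i, t, j] = z
                    R[i, t, j] = r
                    N[i, t, j] = n
                    UN[i, t, j] = un
                    HP[i, t, j] = hp
                    out[i, t, j] = hn
                    h[i, j] = hn
        return out, Z, R, N, UN, HP

    @numba.njit(cache=True, fastmath=True)
    def _gru_backward_nb(dy, Z, R, N, UN, HP, Ut, reverse):
        B, T, H = Z.shape
        dt = Z.dtype
        dGx = np.empty((B, T, 3 * H), dt)
        dUin = np.empty((B, T, 3 * H), dt)
        dh = np.zeros((B, H), dt)
        ui = np.empty((B, 3 * H), dt)
        for s in range(T):
            t = s if reverse else T - 1 - s
            for i in range(B):
                for j in range(H):
                    dht = dy[i, t, j] + dh[i, j]
                    z = Z[i, t, j]
                    r = R[i, t, j]
                    n = N[i, t, j]
                    un = UN[i, t, j]
                    hp = HP[i, t, j]
                    dn = dht * (1.0 - z)
                    dz = dht * (hp - n)
                    dan = dn * (1.0 - n * n)
                    dun = dan * r
                    dr = dan * un
                    daz = dz * z * (1.0 - z)
                    dar = dr * r * (1.0 - r)
                    ui[i, j] = daz
                    ui[i, H + j] = dar
                    ui[i, 2 * H + j] = dun
                    dGx[i, t, j] = daz
                    dGx[i, t, H + j] = dar
                    dGx[i, t, 2 * H + j] = dan
                    dUin[i, t, j] = daz
                    dUin[i, t, H + j] = dar
                    dUin[i, t, 2 * H + j] = dun
                    dh[i, j] = dht * z
            dh += np.dot(ui, Ut)
        return dGx, dUin

    gru_forward = _gru_forward_nb
    gru_backward = _gru_backward_nb
except ImportError:  # pragma: no cover
    gru_forward = _gru_forward_py
    gru_backward = _gru_backward_py
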