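"""Low-level LSTM recurrence kernels (numba-jitted).

The input projections (x @ Wx + b) are hoisted out of the time loop and
done as single large matrix products by the caller; these kernels only
carry the sequential hidden-state recurrence and its reverse-mode
adjoint, which is where a pure-NumPy implementation spends most of its
time in Python overhead.  Elementwise work uses explicit loops so no
temporaries are allocated inside the time loop.

Gate layout along the last axis is (input, forget, cell, output), each a
block of ``hidden`` units.  ``lstm_core_backward`` returns the gradient
with respect to the pre-activation gate inputs; weight gradients are
again large matmuls assembled by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def lstm_core_forward(xp, Wh, one):
    """Run one LSTM direction over a sequence.

    xp : (T, B, 4H) pre-computed input projections including bias.
    Wh : (H, 4H) recurrent weights.
    one : scalar 1 of xp's dtype (prevents float64 promotion in jitted
    arithmetic).
    Returns (hs, cs, gates): hs/cs have shape (T+1, B, H) with the zero
    initial state at index 0; gates (T, B, 4H) hold the activated gate
    values needed by the backward pass.
    """
    T, B, H4 = xp.shape
    H = H4 // 4
    hs = np.zeros((T + 1, B, H), dtype=xp.dtype)
    cs = np.zeros((T + 1, B, H), dtype=xp.dtype)
    gates = np.empty((T, B, H4), dtype=xp.dtype)
    for t in range(T):
        a = xp[t] + np.dot(hs[t], Wh)
        for b in range(B):
            for j in range(H):
                i = one / (one + np.exp(-a[b, j]))
                f = one / (one + np.exp(-a[b, H + j]))
                g = np.tanh(a[b, 2 * H + j])
                o = one / (one + np.exp(-a[b, 3 * H + j]))
                c = f * cs[t, b, j] + i * g
                cs[t + 1, b, j] = c
                hs[t + 1, b, j] = o * np.tanh(c)
                gates[t, b, j] = i
                gates[t, b, H + j] = f
                gates[t, b, 2 * H + j] = g
                gates[t, b, 3 * H + j] = o
    return hs, cs, gates


@njit(cache=True, fastmath=True)
def lstm_core_backward(dh_out, hs, cs, gates, WhT):
    """Adjoint of :func:`lstm_core_forward`.

    dh_out : (T, B, H) gradient of the loss w.r.t. each emitted hidden
    state.  WhT is the transposed recurrent weight matrix (contiguous).
    Returns dxp (T, B, 4H), the gradient w.r.t. the pre-activation gate
    inputs (which equals the gradient w.r.t. xp).
    """
    Tp1, B, H = hs.shape
    T = Tp1 - 1
    dxp = np.empty((T, B, 4 * H), dtype=hs.dtype)
    dh = np.zeros((B, H), dtype=hs.dtype)
    dc = np.zeros((B, H), dtype=hs.dtype)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(H):
                dht = dh_out[t, b, j] + dh[b, j]
                i = gates[t, b, j]
                f = gates[t, b, H + j]
                g = gates[t, b, 2 * H + j]
                o = gates[t, b, 3 * H + j]
                tc = np.tanh(cs[t + 1, b, j])
                do = dht * tc
                dhto = dht * o
                dct = dc[b, j] + dhto - dhto * tc * tc
                di = dct * g
                dg = dct * i
                df = dct * cs[t, b, j]
                dc[b, j] = dct * f
                dxp[t, b, j] = di * (i - i * i)
                dxp[t, b, H + j] = df * (f - f * f)
                dxp[t, b, 2 * H + j] = dg - dg * g * g
                dxp[t, b, 3 * H + j] = do * (o - o * o)
        dh = np.dot(dxp[t], WhT)
    return dxp
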