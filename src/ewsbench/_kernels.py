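"""Euler-Maruyama inner loop.

The hot loop is compiled with numba when available; the pure-Python body is
identical and serves as a (much slower) fallback so the package stays
importable without a working JIT.

Noise increments are supplied by the caller in chunks (float32 draws from a
PCG64 generator): generating the Gaussians vectorised in NumPy and streaming
them through the compiled loop is substantially faster than drawing scalars
inside the kernel, and keeps the noise stream a pure function of the seed,
independent of chunk size.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True, fastmath=True)
def em_chunk(
    A,
    P,
    r_A,
    r_P,
    gamma_A,
    gamma_P,
    c_A,
    c_P,
    h_A,
    h_P,
    sigma_A,
    sigma_P,
    multiplicative,
    dt,
    noise,
    step0,
    burn_steps,
    stride,
    out,
    rec0,
    clip_count,
):
    """Advance the state through one chunk of pre-drawn noise increments.

    ``A`` and ``P`` are updated in place.  Rows are recorded into ``out``
    every ``stride`` integration steps once ``burn_steps`` steps have been
    consumed; ``step0`` is the absolute step index at the start of this
    chunk and ``rec0`` the next output row.  Returns the new output row
    index.  Negative excursions are clipped to zero (counted in
    ``clip_count[0]``).
    """
    S_A = A.shape[0]
    S_P = P.shape[0]
    dA = np.empty(S_A)
    dP = np.empty(S_P)
    sqdt = np.sqrt(dt)
    rec = rec0
    for m in range(noise.shape[0]):
        for k in range(S_A):
            gain = 0.0
            for i in range(S_P):
                gain += gamma_A[k, i] * P[i]
            comp = 0.0
            for l in range(S_A):
                comp += c_A[k, l] * A[l]
            dA[k] = A[k] * (r_A[k] + gain / (1.0 + h_A[k] * gain) - comp)
        for i in range(S_P):
            gain = 0.0
            for k in range(S_A):
                gain += gamma_P[i, k] * A[k]
            comp = 0.0
            for j in range(S_P):
                comp += c_P[i, j] * P[j]
            dP[i] = P[i] * (r_P[i] + gain / (1.0 + h_P[i] * gain) - comp)
        for k in range(S_A):
            amp = sigma_A[k] * A[k] if multiplicative else sigma_A[k]
            v = A[k] + dA[k] * dt + amp * sqdt * noise[m, k]
            if v < 0.0:
                v = 0.0
                clip_count[0] += 1
            A[k] = v
        for i in range(S_P):
            amp = sigma_P[i] * P[i] if multiplicative else sigma_P[i]
            v = P[i] + dP[i] * dt + amp * sqdt * noise[m, S_A + i]
            if v < 0.0:
                v = 0.0
                clip_count[0] += 1
            P[i] = v
        t = step0 + m - burn_steps + 1
        if t > 0 and t % stride == 0:
            for k in range(S_A):
                out[rec, k] = A[k]
            for i in range(S_P):
                out[rec, S_A + i] = P[i]
            rec += 1
    return rec
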