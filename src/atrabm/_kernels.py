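"""Numba-compiled inner loops for the explicit finite-difference solver."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def diffuse_react(v, wx, wy, src, decay, inv_dx2, dt, nsub):
    """``nsub`` explicit flux-form steps of dv/dt = div(D grad v) + src - decay*v.

    ``wx[r, c]`` is the harmonic-mean interface diffusivity between (r, c)
    and (r, c+1); ``wy[r, c]`` between (r, c) and (r+1, c).  Boundaries are
    zero-flux (missing edges are simply absent).  Returns the final array.
    """
    H, W = v.shape
    a = v.copy()
    b = np.empty_like(v)
    for _ in range(nsub):
        for r in range(H):
            for c in range(W):
                acc = 0.0
                if c + 1 < W:
                    acc += wx[r, c] * (a[r, c + 1] - a[r, c])
                if c >= 1:
                    acc += wx[r, c - 1] * (a[r, c - 1] - a[r, c])
                if r + 1 < H:
                    acc += wy[r, c] * (a[r + 1, c] - a[r, c])
                if r >= 1:
                    acc += wy[r - 1, c] * (a[r - 1, c] - a[r, c])
                b[r, c] = a[r, c] + dt * (acc * inv_dx2 + src[r, c]
                                          - decay * a[r, c])
        a, b = b, a
    return a
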