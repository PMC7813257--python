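"""Numba-jitted single-spin-flip chain kernels (Metropolis and Glauber)."""

from __future__ import annotations

import numpy as np
from numba import njit

# kernel codes
METROPOLIS = 0
GLAUBER = 1


@njit(cache=True)
def run_chain(h, J, beta, s0, n_sweeps, sites, us, kernel, out_occ):
    """Advance a +/-1 spin chain by ``n_sweeps`` sweeps of N site updates.

    sites/us are pre-drawn arrays of length n_sweeps * N (site indices and
    uniforms); occupancy (0/1) after each sweep is written into out_occ
    (n_sweeps x N).  Returns the final spin state.
    """
    n = h.shape[0]
    s = s0.copy()
    idx = 0
    for t in range(n_sweeps):
        for _ in range(n):
            k = sites[idx]
            u = us[idx]
            idx += 1
            local = h[k]
            for m in range(n):
                local += J[k, m] * s[m]
            d_energy = 2.0 * s[k] * local
            if kernel == METROPOLIS:
                accept = d_energy <= 0.0 or u < np.exp(-beta * d_energy)
            else:  # Glauber heat bath
                accept = u < 1.0 / (1.0 + np.exp(beta * d_energy))
            if accept:
                s[k] = -s[k]
        for m in range(n):
            out_occ[t, m] = (s[m] + 1) // 2
    return s
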