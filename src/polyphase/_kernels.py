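"""Compiled inner loops for the Metropolis sampler.

The displacement sweep dominates the cost of a replica-exchange run; its
per-move energy difference touches only the two bonds, the three bond
angles and the N-3 non-bonded partners of the moved monomer, which is ideal
for a tight compiled loop.  When numba is unavailable the sampler falls
back to an equivalent (much slower) numpy path, so results never depend on
the accelerator being present - only wall time does.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def _local_energy(pos, i, n, sigma, eps, v_shift, r_cut, r0, r_fene, k_fene,
                  kappa, theta0):
    """All energy terms touching monomer i; inf if a bond leaves FENE range."""
    e = 0.0
    # bonds (i-1, i) and (i, i+1)
    for j in (i - 1, i + 1):
        if 0 <= j < n:
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            u = (r - r0) / r_fene
            if u * u >= 1.0:
                return np.inf
            sr6 = (sigma / r) ** 6
            e += (-0.5 * k_fene * r_fene * r_fene * np.log(1.0 - u * u)
                  + 4.0 * eps * (sr6 * sr6 - sr6) - v_shift)
    # non-bonded partners |j - i| >= 2
    for j in range(n):
        if j < i - 1 or j > i + 1:
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < r_cut:
                sr6 = (sigma / r) ** 6
                e += 4.0 * eps * (sr6 * sr6 - sr6) - v_shift
    # bond angles centred at i-1, i, i+1
    if kappa != 0.0 and n > 2:
        lo = i - 1 if i - 1 > 1 else 1
        hi = i + 1 if i + 1 < n - 2 else n - 2
        for c in range(lo, hi + 1):
            b1x = pos[c, 0] - pos[c - 1, 0]
            b1y = pos[c, 1] - pos[c - 1, 1]
            b1z = pos[c, 2] - pos[c - 1, 2]
            b2x = pos[c + 1, 0] - pos[c, 0]
            b2y = pos[c + 1, 1] - pos[c, 1]
            b2z = pos[c + 1, 2] - pos[c, 2]
            n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            ca = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
            if ca > 1.0:
                ca = 1.0
            elif ca < -1.0:
                ca = -1.0
            theta = np.arccos(ca)
            e += kappa * (1.0 - np.cos(theta - theta0))
    return e


@njit(cache=True, fastmath=False)
def displacement_sweep(pos, idx, shifts, us, beta, sigma, eps, v_shift, r_cut,
                       r0, r_fene, k_fene, kappa, theta0):
    """One sweep of single-monomer displacement attempts, in place.

    Returns (energy change, accepted count).  idx, shifts and us are the
    pre-drawn random numbers for the sweep, so the caller owns the RNG
    stream and reproducibility.
    """
    n = pos.shape[0]
    de_total = 0.0
    accepted = 0
    for m in range(idx.shape[0]):
        i = idx[m]
        e_old = _local_energy(pos, i, n, sigma, eps, v_shift, r_cut, r0,
                              r_fene, k_fene, kappa, theta0)
        ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
        pos[i, 0] = ox + shifts[m, 0]
        pos[i, 1] = oy + shifts[m, 1]
        pos[i, 2] = oz + shifts[m, 2]
        e_new = _local_energy(pos, i, n, sigma, eps, v_shift, r_cut, r0,
                              r_fene, k_fene, kappa, theta0)
        de = e_new - e_old
        if np.isfinite(de) and (de <= 0.0 or us[m] < np.exp(-de * beta)):
            de_total += de
            accepted += 1
        else:
            pos[i, 0] = ox
            pos[i, 1] = oy
            pos[i, 2] = oz
    return de_total, accepted
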