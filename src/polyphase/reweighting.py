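"""Multi-histogram reweighting (WHAM) and canonical observables.

Canonical energy histograms measured at a ladder of temperatures are combined
into a single estimate of the density of states g(E) by iterating

    g(E) = sum_k h(E; T_k) / sum_k M_k Z_k^-1 exp(-E / k_B T_k),
    Z_k  = sum_E g(E) exp(-E / k_B T_k),

to a fixed point.  g(E) spans hundreds of orders of magnitude for chains of
interesting length, so every accumulation here is done in the log domain with
log-sum-exp.  Canonical curves (mean energy, heat capacity, reweighted
structural observables and their temperature derivatives) follow directly
from the estimated density of states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sampler import HistogramSet

__all__ = [
    "DensityOfStates",
    "CanonicalCurves",
    "single_histogram_dos",
    "wham_iterate",
    "canonical_mean_energy",
    "heat_capacity",
    "canonical_observable",
    "canonical_curves",
]


@dataclass
class DensityOfStates:
    """Binned log density of states, normalised so max ln g = 0."""

    energies: np.ndarray              # occupied bin centers, increasing
    ln_g: np.ndarray
    stderr: np.ndarray | None = None  # per-bin uncertainty (from independent runs)
    normalization: str = "max0"
    obs_means: np.ndarray | None = None  # per-bin conditional mean of an observable
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.ln_g = np.asarray(self.ln_g, dtype=float)
        if self.energies.shape != self.ln_g.shape:
            raise ValueError("energies and ln_g must have the same shape")
        if self.energies.size and np.any(np.diff(self.energies) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    def normalized(self) -> "DensityOfStates":
        return DensityOfStates(
            self.energies, self.ln_g - self.ln_g.max(), self.stderr,
            "max0", self.obs_means, dict(self.meta),
        )

    def to_frame(self):
        import pandas as pd

        data = {"bin_center": self.energies, "ln_g": self.ln_g}
        if self.stderr is not None:
            data["stderr"] = self.stderr
        if self.obs_means is not None:
            data["obs_mean"] = self.obs_means
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CanonicalCurves:
    """Canonical observables on a grid of inverse heat-bath temperatures."""

    beta: np.ndarray
    mean_energy: np.ndarray
    heat_capacity: np.ndarray
    mean_rg2: np.ndarray | None = None
    d_rg2_dt: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        data = {
            "beta_can": self.beta,
            "mean_energy": self.mean_energy,
            "heat_capacity": self.heat_capacity,
        }
        if self.mean_rg2 is not None:
            data["mean_rg2"] = self.mean_rg2
            data["d_rg2_dT"] = self.d_rg2_dt
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def single_histogram_dos(counts: np.ndarray, bin_centers: np.ndarray,
                         temperature: float) -> DensityOfStates:
    """Single-histogram estimate ln g(E) = ln h(E; T) + E / k_B T.

    Empty bins carry no information about g and are dropped.
    """
    counts = np.asarray(counts, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    occ = counts > 0
    if not np.any(occ):
        raise ValueError("histogram is empty")
    ln_g = np.log(counts[occ]) + bin_centers[occ] / temperature
    return DensityOfStates(bin_centers[occ], ln_g - ln_g.max())


def _check_overlap(counts: np.ndarray) -> None:
    """Threads must form one connected component through shared occupied bins."""
    k = counts.shape[0]
    occ = counts > 0
    adj = (occ @ occ.T) > 0
    seen = np.zeros(k, dtype=bool)
    stack = [0]
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        stack.extend(np.nonzero(adj[i] & ~seen)[0].tolist())
    if not seen.all():
        groups = [np.nonzero(seen)[0].tolist(), np.nonzero(~seen)[0].tolist()]
        raise ValueError(
            "histograms fall into non-overlapping energy islands; "
            f"disconnected thread groups: {groups}"
        )


def wham_iterate(
    hists: HistogramSet,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> DensityOfStates:
    """Iterate the multi-histogram equations to their fixed point.

    Convergence is declared when every thread's ln Z_k changes by less than
    ``tol`` between iterations; the returned ln g is normalised to max 0.
    Bins with zero total counts are excluded (no information, no interpolated
    entropy).  Raises if the thread histograms do not overlap into a single
    connected energy range.
    """
    counts = np.asarray(hists.counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be (K, nbins)")
    _check_overlap(counts)
    centers = hists.bin_centers
    beta_k = 1.0 / np.asarray(hists.temperatures, dtype=float)
    m_k = np.asarray(hists.m_k, dtype=float)

    tot = counts.sum(axis=0)
    occ = tot > 0
    e = centers[occ]
    ln_num = np.log(tot[occ])
    ln_m = np.log(m_k)
    # exponent matrix -beta_k * E, shape (K, nbins_occ)
    neg_be = -np.outer(beta_k, e)

    ln_z = np.zeros(beta_k.size)
    ln_g = ln_num + e * beta_k[0]  # start from the coldest single-histogram guess
    ln_g -= ln_g.max()
    converged = False
    for _ in range(max_iter):
        ln_z_new = logsumexp(ln_g[None, :] + neg_be, axis=1)
        ln_g = ln_num - logsumexp(ln_m[:, None] - ln_z_new[:, None] + neg_be, axis=0)
        ln_g -= ln_g.max()
        if np.max(np.abs(ln_z_new - ln_z)) < tol:
            ln_z = ln_z_new
            converged = True
            break
        ln_z = ln_z_new
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {np.max(np.abs(ln_z_new - ln_z)):.2e})",
            RuntimeWarning,
        )

    obs = None
    if hists.rg2_sums is not None:
        obs = hists.observable_means()[occ]
    return DensityOfStates(
        e, ln_g, obs_means=obs,
        meta={"ln_z": ln_z, "temperatures": np.asarray(hists.temperatures, float)},
    )


# ---------------------------------------------------------------------------
# canonical observables from the density of states
# ---------------------------------------------------------------------------


def _boltzmann_logweights(dos: DensityOfStates, beta: float) -> np.ndarray:
    return dos.ln_g - beta * dos.energies


def canonical_mean_energy(dos: DensityOfStates, beta) -> np.ndarray:
    """<E>(beta) = sum E g exp(-beta E) / sum g exp(-beta E), log-sum-exp stable."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    out = np.empty(beta.size)
    for i, b in enumerate(beta):
        lw = _boltzmann_logweights(dos, b)
        lw -= lw.max()
        w = np.exp(lw)
        out[i] = np.sum(w * dos.energies) / np.sum(w)
    return out if out.size > 1 else out[0]


def heat_capacity(dos: DensityOfStates, beta) -> np.ndarray:
    """C_V(beta) = beta^2 (<E^2> - <E>^2); nonnegative by construction."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    out = np.empty(beta.size)
    for i, b in enumerate(beta):
        lw = _boltzmann_logweights(dos, b)
        lw -= lw.max()
        w = np.exp(lw)
        w /= w.sum()
        e1 = np.sum(w * dos.energies)
        var = np.sum(w * (dos.energies - e1) ** 2)
        out[i] = b * b * var
    return out if out.size > 1 else out[0]


def canonical_observable(dos: DensityOfStates, obs_bins: np.ndarray, beta):
    """Reweighted <O>(beta) and its temperature derivative d<O>/dT_can.

    ``obs_bins`` holds the conditional mean O(E) on every occupied bin of the
    density of states; the derivative uses the covariance identity
    d<O>/dT = beta^2 (<O E> - <O><E>).
    """
    obs_bins = np.asarray(obs_bins, dtype=float)
    if obs_bins.shape != dos.energies.shape:
        raise ValueError("obs_bins must match the DoS support")
    if np.any(~np.isfinite(obs_bins)):
        raise ValueError("obs_bins contains NaN/inf on occupied bins")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    mean = np.empty(beta.size)
    deriv = np.empty(beta.size)
    for i, b in enumerate(beta):
        lw = _boltzmann_logweights(dos, b)
        lw -= lw.max()
        w = np.exp(lw)
        w /= w.sum()
        o = np.sum(w * obs_bins)
        e1 = np.sum(w * dos.energies)
        cov = np.sum(w * (obs_bins - o) * (dos.energies - e1))
        mean[i] = o
        deriv[i] = b * b * cov
    if beta.size == 1:
        return mean[0], deriv[0]
    return mean, deriv


def canonical_curves(dos: DensityOfStates, beta_grid: np.ndarray) -> CanonicalCurves:
    """Convenience bundle of all canonical curves on a beta grid."""
    beta_grid = np.asarray(beta_grid, dtype=float)
    e_mean = np.atleast_1d(canonical_mean_energy(dos, beta_grid))
    cv = np.atleast_1d(heat_capacity(dos, beta_grid))
    rg2 = drg2 = None
    if dos.obs_means is not None and np.all(np.isfinite(dos.obs_means)):
        rg2, drg2 = canonical_observable(dos, dos.obs_means, beta_grid)
        rg2, drg2 = np.atleast_1d(rg2), np.atleast_1d(drg2)
    return CanonicalCurves(beta_grid, e_mean, cv, rg2, drg2)
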