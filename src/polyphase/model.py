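"""Coarse-grained bead-spring energy model for flexible and semiflexible polymers.

The chain is a sequence of N identical monomers.  Non-bonded monomer pairs
interact through a 12-6 Lennard-Jones potential, truncated at ``r_cut`` and
shifted so the potential is continuous there.  Consecutive monomers are bound
by a FENE (finitely extensible nonlinear elastic) spring combined with the
same shifted Lennard-Jones term, which confines bond lengths to the open
interval ``(r0 - R_fene, r0 + R_fene)``.  Semiflexibility enters through a
bending penalty ``kappa * (1 - cos(theta - theta0))`` on each interior bond
angle, with ``theta = 0`` for a straight chain.  Reduced units are used
throughout: ``k_B = 1``, ``epsilon_LJ = 1``, ``r0 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "Conformation",
    "EnergyBreakdown",
    "lj_potential",
    "nonbonded_potential",
    "bond_potential",
    "bend_potential",
    "total_energy",
    "energy_delta",
    "energy_and_grad",
]


@dataclass(frozen=True)
class ModelParams:
    """All constants of the energy function.

    Only ``epsilon_lj``, ``r0``, ``kappa`` and ``theta0`` are free; the van der
    Waals length, cutoff, shift and FENE constants are derived from them and
    exposed as read-only properties.
    """

    epsilon_lj: float = 1.0
    r0: float = 1.0
    kappa: float = 0.0
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon_lj <= 0 or self.r0 <= 0:
            raise ValueError("epsilon_lj and r0 must be positive")
        if self.kappa < 0:
            raise ValueError("bending stiffness kappa must be >= 0")

    @property
    def sigma(self) -> float:
        """van der Waals length; LJ minimum sits at r0 = 2^(1/6) sigma."""
        return 2.0 ** (-1.0 / 6.0) * self.r0

    @property
    def r_cut(self) -> float:
        return 2.5 * self.sigma

    @property
    def v_shift(self) -> float:
        """Unshifted LJ potential evaluated at the cutoff."""
        sr6 = (self.sigma / self.r_cut) ** 6
        return 4.0 * self.epsilon_lj * (sr6 * sr6 - sr6)

    @property
    def r_fene(self) -> float:
        """FENE range R: bond lengths live in (r0 - R, r0 + R)."""
        return (3.0 / 7.0) * self.r0

    @property
    def k_fene(self) -> float:
        return (98.0 / 5.0) * self.epsilon_lj / self.r0**2


@dataclass
class EnergyBreakdown:
    """Total energy split into its three contributions."""

    nonbonded: float
    bonded: float
    bending: float

    @property
    def total(self) -> float:
        return self.nonbonded + self.bonded + self.bending


class Conformation:
    """Ordered 3D positions of the N monomers of one chain."""

    __slots__ = ("positions", "energy_cache")

    def __init__(self, positions: Iterable[Sequence[float]], energy: float | None = None):
        pos = np.asarray(positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if pos.shape[0] < 2:
            raise ValueError("a chain needs at least two monomers")
        self.positions = pos
        self.energy_cache = energy

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def is_valid(self, params: ModelParams) -> bool:
        """True if every bond length is strictly inside the FENE interval."""
        b = self.bond_lengths()
        return bool(np.all(np.abs(b - params.r0) < params.r_fene))

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.energy_cache)


def lj_potential(r, params: ModelParams = ModelParams()):
    """Plain 12-6 Lennard-Jones potential, 4 eps [(sigma/r)^12 - (sigma/r)^6]."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("lj_potential requires r > 0")
    sr6 = (params.sigma / r) ** 6
    return 4.0 * params.epsilon_lj * (sr6 * sr6 - sr6)


def nonbonded_potential(r, params: ModelParams = ModelParams()):
    """Truncated-and-shifted LJ: V_LJ(r) - V_shift below r_cut, exactly 0 above."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("nonbonded_potential requires r > 0")
    v = lj_potential(r, params) - params.v_shift
    return np.where(r < params.r_cut, v, 0.0)


def bond_potential(r, params: ModelParams = ModelParams()):
    """FENE + shifted-LJ bond potential; +inf outside the FENE interval.

    The FENE log-term diverges as r approaches r0 +/- R_fene; the bond can
    never leave the interval, which a Metropolis sampler enforces by
    rejecting any move that would take it there.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond_potential requires r > 0")
    u = (r - params.r0) / params.r_fene
    inside = np.abs(u) < 1.0
    usq = np.where(inside, u * u, 0.0)
    fene = -0.5 * params.k_fene * params.r_fene**2 * np.log1p(-usq)
    v = fene + lj_potential(np.where(r > 0, r, 1.0), params) - params.v_shift
    return np.where(inside, v, np.inf)


def bend_potential(theta, params: ModelParams = ModelParams()):
    """Bending penalty kappa * (1 - cos(theta - theta0)); zero for straight chains."""
    theta = np.asarray(theta, dtype=float)
    return params.kappa * (1.0 - np.cos(theta - params.theta0))


def _bond_angles(pos: np.ndarray) -> np.ndarray:
    """Angles between successive bond vectors (0 for a straight chain)."""
    bonds = np.diff(pos, axis=0)
    b1 = bonds[:-1]
    b2 = bonds[1:]
    cosang = np.einsum("ij,ij->i", b1, b2)
    cosang /= np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def total_energy(conf: Conformation | np.ndarray, params: ModelParams) -> EnergyBreakdown:
    """Exact total energy of a conformation, split into its three terms.

    The non-bonded sum runs over pairs (i, j) with i > j + 1, so bonded
    neighbours are excluded but next-nearest pairs (i, i+2) are included.
    Raises ``ValueError`` if any bond length lies outside the FENE interval.
    """
    pos = conf.positions if isinstance(conf, Conformation) else np.asarray(conf, dtype=float)
    n = pos.shape[0]

    bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if np.any(np.abs(bonds - params.r0) >= params.r_fene):
        raise ValueError("bond length outside the FENE interval")
    e_bond = float(np.sum(bond_potential(bonds, params)))

    e_nb = 0.0
    if n > 2:
        iu, ju = np.triu_indices(n, k=2)
        rij = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        e_nb = float(np.sum(nonbonded_potential(rij, params)))

    e_bend = 0.0
    if n > 2 and params.kappa != 0.0:
        e_bend = float(np.sum(bend_potential(_bond_angles(pos), params)))

    out = EnergyBreakdown(nonbonded=e_nb, bonded=e_bond, bending=e_bend)
    if isinstance(conf, Conformation):
        conf.energy_cache = out.total
    return out


def _local_terms(pos: np.ndarray, moved: np.ndarray, params: ModelParams) -> float:
    """Sum of all energy terms that involve at least one moved monomer.

    Returns +inf if an involved bond leaves the FENE interval.
    """
    n = pos.shape[0]
    moved_mask = np.zeros(n, dtype=bool)
    moved_mask[moved] = True

    # bonds (i, i+1) touching a moved monomer
    bond_touch = moved_mask[:-1] | moved_mask[1:]
    e = 0.0
    if np.any(bond_touch):
        i = np.nonzero(bond_touch)[0]
        r = np.linalg.norm(pos[i + 1] - pos[i], axis=1)
        if np.any(np.abs(r - params.r0) >= params.r_fene):
            return np.inf
        e += float(np.sum(bond_potential(r, params)))

    # non-bonded pairs i > j + 1 with an endpoint moved
    if n > 2:
        iu, ju = np.triu_indices(n, k=2)
        sel = moved_mask[iu] | moved_mask[ju]
        if np.any(sel):
            rij = np.linalg.norm(pos[iu[sel]] - pos[ju[sel]], axis=1)
            e += float(np.sum(nonbonded_potential(rij, params)))

    # bond angles centred at l involve monomers l-1, l, l+1
    if n > 2 and params.kappa != 0.0:
        centers = np.arange(1, n - 1)
        sel = moved_mask[centers - 1] | moved_mask[centers] | moved_mask[centers + 1]
        if np.any(sel):
            angles = _bond_angles(pos)  # angles[l-1] is centred at monomer l
            e += float(np.sum(bend_potential(angles[sel], params)))
    return e


def energy_delta(
    conf: Conformation,
    new_positions: np.ndarray,
    moved: Sequence[int],
    params: ModelParams,
) -> float:
    """E(new) - E(old) re-evaluating only interactions that touch moved monomers.

    ``new_positions`` is the full (N, 3) proposed coordinate array; ``moved``
    lists the indices whose coordinates changed.  Returns ``+inf`` when the
    proposal drives a bond outside the FENE interval (the caller must reject).
    """
    moved = np.asarray(moved, dtype=int)
    if moved.size == 0:
        return 0.0
    e_new = _local_terms(np.asarray(new_positions, dtype=float), moved, params)
    if not np.isfinite(e_new):
        return np.inf
    e_old = _local_terms(conf.positions, moved, params)
    return e_new - e_old


# ---------------------------------------------------------------------------
# smooth energy + gradient for deterministic minimisation
# ---------------------------------------------------------------------------

_FENE_EDGE = 1.0 - 1e-6  # |u| beyond which the log barrier is extended quadratically


def energy_and_grad(x: np.ndarray, params: ModelParams) -> tuple[float, np.ndarray]:
    """Energy and analytic gradient for gradient-based minimisers.

    Identical to :func:`total_energy` on the physical domain except that the
    FENE log barrier is continued by a matched quadratic beyond
    ``|r - r0| >= R_fene * (1 - 1e-6)``, so line searches never encounter an
    infinite value.  Minima are far from the edge, where the two agree exactly.
    """
    pos = np.asarray(x, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    grad = np.zeros_like(pos)
    energy = 0.0

    # bonds
    dvec = np.diff(pos, axis=0)
    r = np.linalg.norm(dvec, axis=1)
    u = (r - params.r0) / params.r_fene
    kr2 = params.k_fene * params.r_fene**2
    au = np.clip(u, -_FENE_EDGE, _FENE_EDGE)
    v_in = -0.5 * kr2 * np.log1p(-au * au)
    dv_in = params.k_fene * (au * params.r_fene) / (1.0 - au * au)  # dV/dr at clipped u
    # quadratic continuation beyond the clip point
    d2v = params.k_fene * (1.0 + au * au) / (1.0 - au * au) ** 2
    excess = (u - au) * params.r_fene
    v_fene = v_in + dv_in * excess + 0.5 * d2v * excess**2
    dv_fene = dv_in + d2v * excess

    sr6 = (params.sigma / r) ** 6
    v_lj = 4.0 * params.epsilon_lj * (sr6 * sr6 - sr6) - params.v_shift
    dv_lj = 4.0 * params.epsilon_lj * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    energy += float(np.sum(v_fene + v_lj))
    f = ((dv_fene + dv_lj) / r)[:, None] * dvec
    np.add.at(grad, np.arange(n - 1), -f)
    np.add.at(grad, np.arange(1, n), f)

    # non-bonded
    if n > 2:
        iu, ju = np.triu_indices(n, k=2)
        dv_ij = pos[iu] - pos[ju]
        rij = np.linalg.norm(dv_ij, axis=1)
        inside = rij < params.r_cut
        if np.any(inside):
            rin = rij[inside]
            sr6 = (params.sigma / rin) ** 6
            energy += float(
                np.sum(4.0 * params.epsilon_lj * (sr6 * sr6 - sr6) - params.v_shift)
            )
            dv = 4.0 * params.epsilon_lj * (-12.0 * sr6 * sr6 + 6.0 * sr6) / rin
            f = (dv / rin)[:, None] * dv_ij[inside]
            np.add.at(grad, iu[inside], f)
            np.add.at(grad, ju[inside], -f)

    # bending
    if n > 2 and params.kappa != 0.0:
        b1 = dvec[:-1]
        b2 = dvec[1:]
        n1 = np.linalg.norm(b1, axis=1)
        n2 = np.linalg.norm(b2, axis=1)
        dot = np.einsum("ij,ij->i", b1, b2)
        cosang = np.clip(dot / (n1 * n2), -1.0, 1.0)
        theta = np.arccos(cosang)
        energy += float(np.sum(params.kappa * (1.0 - np.cos(theta - params.theta0))))
        # dV/d(cos theta): V = kappa (1 - cos(theta - theta0))
        sin_t = np.sqrt(np.maximum(1.0 - cosang**2, 1e-24))
        dv_dtheta = params.kappa * np.sin(theta - params.theta0)
        dv_dcos = -dv_dtheta / sin_t
        dcos_db1 = (b2 / (n1 * n2)[:, None]) - (cosang / n1**2)[:, None] * b1
        dcos_db2 = (b1 / (n1 * n2)[:, None]) - (cosang / n2**2)[:, None] * b2
        g1 = dv_dcos[:, None] * dcos_db1
        g2 = dv_dcos[:, None] * dcos_db2
        idx = np.arange(n - 2)
        np.add.at(grad, idx, -g1)
        np.add.at(grad, idx + 1, g1 - g2)
        np.add.at(grad, idx + 2, g2)

    return energy, grad.ravel()
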