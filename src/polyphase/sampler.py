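"""Replica-exchange Metropolis Monte Carlo for the bead-spring chain.

Each temperature thread runs local single-monomer displacement updates (cubic
proposal box, edge tuned to ~50% acceptance before measurements start) and
global pivot rotations of the chain tail.  Neighbouring threads exchange
conformations at a fixed period.  Canonical energy histograms, per-bin
accumulators of the squared radius of gyration, and the lowest-energy
conformation seen are collected for the downstream multi-histogram analysis.
A simulated-annealing driver reuses the same move set for ground-state search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels
from .model import (
    Conformation,
    ModelParams,
    energy_and_grad,
    energy_delta,
    total_energy,
)

__all__ = [
    "TemperatureLadder",
    "RunConfig",
    "HistogramSet",
    "Proposal",
    "metropolis_accept",
    "replica_swap",
    "displacement_move",
    "pivot_move",
    "adapt_step_size",
    "straight_chain",
    "sample_chain",
    "run_remc",
    "simulated_annealing",
]

logger = logging.getLogger(__name__)

FULL_RECOMPUTE_PERIOD = 10_000  # sweeps between full energy resyncs (drift control)


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly increasing list of simulation temperatures."""

    temperatures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", t)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("need at least one temperature")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be positive and strictly increasing")

    @property
    def count(self) -> int:
        return self.temperatures.size

    @classmethod
    def geometric(cls, t_min: float = 0.1, t_max: float = 5.0, count: int = 40) -> "TemperatureLadder":
        """Geometrically spaced ladder, the default production layout."""
        return cls(np.geomspace(t_min, t_max, count))


@dataclass
class RunConfig:
    """Everything one replica-exchange run needs besides the energy model."""

    n_monomers: int
    ladder: TemperatureLadder
    sweeps: int = 50_000              # measurement sweeps per thread (M_k)
    equilibration: int = 5_000
    tuning_blocks: int = 60
    tuning_block_sweeps: int = 50
    exchange_period: int = 1_500      # sweeps between neighbour-swap events
    pivot_interval_min: int = 20      # displacement sweeps per pivot sweep, hottest thread
    pivot_interval_max: int = 70      # and coldest thread (linear in thread index)
    bin_width: float = 0.5
    seed: int = 0
    measure_every: int = 1

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("n_monomers must be >= 2")
        for name in ("sweeps", "exchange_period", "measure_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")

    def pivot_intervals(self) -> np.ndarray:
        """Pivot cadence per thread: cold threads pivot rarely, hot ones often."""
        k = self.ladder.count
        if k == 1:
            return np.array([self.pivot_interval_max])
        frac = np.arange(k) / (k - 1)
        return np.rint(
            self.pivot_interval_max - frac * (self.pivot_interval_max - self.pivot_interval_min)
        ).astype(int)


@dataclass
class HistogramSet:
    """Canonical energy histograms of one run, shared bin edges across threads."""

    bin_edges: np.ndarray             # (nbins+1,)
    counts: np.ndarray                # (K, nbins) integer counts
    m_k: np.ndarray                   # (K,) measurements per thread
    temperatures: np.ndarray          # (K,)
    rg2_sums: np.ndarray | None = None        # (K, nbins) accumulated R^2_gyr
    acceptance: np.ndarray | None = None      # (K,) displacement acceptance rates
    swap_rates: np.ndarray | None = None      # (K-1,)
    min_energy: float = np.inf
    min_conformation: np.ndarray | None = None
    step_sizes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be nonnegative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_threads(self) -> int:
        return self.counts.shape[0]

    def observable_means(self) -> np.ndarray:
        """Per-bin conditional mean of R^2_gyr, pooled over threads (NaN where empty)."""
        if self.rg2_sums is None:
            raise ValueError("no observable accumulators in this histogram set")
        tot = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.rg2_sums.sum(axis=0) / tot, np.nan)

    def to_frame(self):
        import pandas as pd

        data = {"bin_center": self.bin_centers}
        for k in range(self.n_threads):
            data[f"count_thread_{k + 1}"] = self.counts[k]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("bin_edges", "counts", "m_k", "temperatures"):
                f.create_dataset(name, data=getattr(self, name))
            for name in ("rg2_sums", "acceptance", "swap_rates", "step_sizes", "min_conformation"):
                val = getattr(self, name)
                if val is not None:
                    f.create_dataset(name, data=val)
            f.attrs["min_energy"] = self.min_energy
            for key, val in self.meta.items():
                f.attrs[f"meta_{key}"] = val

    @classmethod
    def from_hdf5(cls, path) -> "HistogramSet":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {name: f[name][()] for name in f.keys()}
            meta = {
                key[5:]: val for key, val in f.attrs.items() if key.startswith("meta_")
            }
            return cls(min_energy=float(f.attrs["min_energy"]), meta=meta, **kw)


# ---------------------------------------------------------------------------
# elementary moves and acceptance rules
# ---------------------------------------------------------------------------


def metropolis_accept(e_current: float, e_proposed: float, temperature: float, u: float) -> bool:
    """Metropolis rule: accept iff u < min{exp(-(E' - E)/k_B T), 1}."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not np.isfinite(e_proposed):
        return False
    de = e_proposed - e_current
    return de <= 0 or u < np.exp(-de / temperature)


def replica_swap(e_k: float, e_k1: float, t_k: float, t_k1: float, u: float) -> bool:
    """Neighbour-swap rule: accept iff u < min{exp[(E_k - E_k1)(1/T_k - 1/T_k1)], 1}."""
    arg = (e_k - e_k1) * (1.0 / t_k - 1.0 / t_k1)
    return arg >= 0 or u < np.exp(arg)


@dataclass
class Proposal:
    """A proposed coordinate update: full new positions plus bookkeeping."""

    positions: np.ndarray
    moved: np.ndarray
    auto_reject: bool = False


def displacement_move(
    conf: Conformation,
    i: int,
    r_d: float,
    rng: np.random.Generator,
    params: ModelParams | None = None,
) -> Proposal:
    """Shift monomer i by a uniform random vector in a cube of edge r_d.

    If ``params`` is given, proposals that push a bond outside the FENE
    interval come back flagged ``auto_reject`` (their energy is infinite).
    """
    if not 0 <= i < conf.n_monomers:
        raise IndexError("monomer index out of range")
    if r_d < 0:
        raise ValueError("box edge must be nonnegative")
    shift = rng.uniform(-0.5 * r_d, 0.5 * r_d, size=3)
    new = conf.positions.copy()
    new[i] += shift
    reject = False
    if params is not None:
        for j in (i - 1, i):
            if 0 <= j < conf.n_monomers - 1:
                r = np.linalg.norm(new[j + 1] - new[j])
                if abs(r - params.r0) >= params.r_fene:
                    reject = True
    return Proposal(positions=new, moved=np.array([i]), auto_reject=reject)


def pivot_move(conf: Conformation, i: int, rng: np.random.Generator) -> Proposal:
    """Rigidly rotate monomers i+1..N-1 about a random axis through monomer i.

    The axis is uniform on the unit sphere (normalised Gaussian triple) and the
    angle uniform in [0, 2 pi).  Bond (i, i+1) and all tail-internal distances
    are preserved exactly.
    """
    if not 0 <= i < conf.n_monomers - 1:
        raise IndexError("pivot index must leave a nonempty tail")
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    rot = Rotation.from_rotvec(angle * axis)
    new = conf.positions.copy()
    pivot = new[i]
    new[i + 1 :] = rot.apply(new[i + 1 :] - pivot) + pivot
    return Proposal(positions=new, moved=np.arange(i + 1, conf.n_monomers))


def adapt_step_size(acceptance: float, r_d: float, gain: float = 0.1) -> float:
    """Multiplicative feedback r_d <- r_d * exp(gain * (acceptance - 0.5)).

    Drives the displacement-box edge toward the ~50% Metropolis acceptance
    target; applied once per tuning block and frozen before measurements.
    """
    return r_d * np.exp(gain * (acceptance - 0.5))


def reptation_move(conf: Conformation, rng: np.random.Generator,
                   bond_window: tuple[float, float] = (0.95, 1.05)) -> Proposal:
    """Slithering-snake update: move one end monomer to the opposite end.

    The chosen end monomer is deleted and re-attached beyond the other end at
    a random direction and a bond length drawn from ``bond_window``; all
    other monomers keep their positions but shift chain index by one.  This
    rethreads the chain through a compact cluster without disturbing the
    packing, which single-monomer and pivot moves cannot do at low
    temperature.  Used by the annealing ground-state search.
    """
    pos = conf.positions
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    r = rng.uniform(*bond_window)
    if rng.random() < 0.5:  # head -> tail
        new = np.vstack([pos[1:], pos[-1] + r * direction])
    else:
        new = np.vstack([pos[0] + r * direction, pos[:-1]])
    return Proposal(positions=new, moved=np.arange(conf.n_monomers))


def straight_chain(n: int, bond: float = 1.0) -> Conformation:
    pos = np.zeros((n, 3))
    pos[:, 0] = bond * np.arange(n)
    return Conformation(pos)


# ---------------------------------------------------------------------------
# single-temperature walker
# ---------------------------------------------------------------------------


class _Walker:
    """One Metropolis walker: a conformation, its temperature and step size."""

    def __init__(self, params: ModelParams, conf: Conformation, temperature: float,
                 r_d: float, rng: np.random.Generator):
        self.params = params
        self.conf = conf
        self.t = temperature
        self.r_d = r_d
        self.rng = rng
        self.energy = total_energy(conf, params).total
        self._pt = (params.sigma, params.epsilon_lj, params.v_shift, params.r_cut,
                    params.r0, params.r_fene, params.k_fene, params.kappa, params.theta0)
        self.accepted = 0
        self.attempted = 0

    def sweep(self) -> None:
        """N single-monomer displacement attempts."""
        n = self.conf.n_monomers
        pos = self.conf.positions
        idx = self.rng.integers(0, n, size=n)
        shifts = self.rng.uniform(-0.5 * self.r_d, 0.5 * self.r_d, size=(n, 3))
        us = self.rng.random(n)
        if _kernels.HAVE_NUMBA:
            de, acc = _kernels.displacement_sweep(
                pos, idx, shifts, us, 1.0 / self.t, *self._pt,
            )
            self.energy += de
            self.accepted += int(acc)
            self.attempted += n
            return
        for m in range(n):
            i = idx[m]
            old = pos[i].copy()
            pos[i] = old + shifts[m]
            de = _displacement_delta(pos, old, i, self.params)
            self.attempted += 1
            if np.isfinite(de) and (de <= 0 or us[m] < np.exp(-de / self.t)):
                self.energy += de
                self.accepted += 1
            else:
                pos[i] = old

    def pivot_sweep(self) -> None:
        n = self.conf.n_monomers
        for _ in range(n - 1):
            i = int(self.rng.integers(0, n - 1))
            prop = pivot_move(self.conf, i, self.rng)
            de = energy_delta(self.conf, prop.positions, prop.moved, self.params)
            if np.isfinite(de) and metropolis_accept(0.0, de, self.t, self.rng.random()):
                self.conf.positions = prop.positions
                self.energy += de

    def resync(self) -> None:
        self.energy = total_energy(self.conf, self.params).total

    def acceptance_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0

    def reset_counters(self) -> None:
        self.accepted = 0
        self.attempted = 0


def _displacement_delta(pos: np.ndarray, old_i: np.ndarray, i: int, params: ModelParams) -> float:
    """Energy change of moving monomer i from old_i to pos[i] (pos already updated)."""
    n = pos.shape[0]
    # bonds touching i
    de = 0.0
    for j in (i - 1, i + 1):
        if 0 <= j < n:
            r_new = np.linalg.norm(pos[j] - pos[i])
            u = (r_new - params.r0) / params.r_fene
            if abs(u) >= 1.0:
                return np.inf
            r_old = np.linalg.norm(pos[j] - old_i)
            de += _bond_e(r_new, params) - _bond_e(r_old, params)
    # non-bonded partners |i - j| > 1
    if n > 2:
        mask = np.ones(n, dtype=bool)
        mask[max(i - 1, 0) : min(i + 2, n)] = False
        others = pos[mask]
        rn = np.linalg.norm(others - pos[i], axis=1)
        ro = np.linalg.norm(others - old_i, axis=1)
        de += _nb_sum(rn, params) - _nb_sum(ro, params)
    # bond angles centred at i-1, i, i+1
    if n > 2 and params.kappa != 0.0:
        de += _angle_e_around(pos, i, params)
        saved = pos[i].copy()
        pos[i] = old_i
        de -= _angle_e_around(pos, i, params)
        pos[i] = saved
    return de


def _bond_e(r: float, params: ModelParams) -> float:
    u = (r - params.r0) / params.r_fene
    sr6 = (params.sigma / r) ** 6
    return (
        -0.5 * params.k_fene * params.r_fene**2 * np.log1p(-u * u)
        + 4.0 * params.epsilon_lj * (sr6 * sr6 - sr6)
        - params.v_shift
    )


def _nb_sum(r: np.ndarray, params: ModelParams) -> float:
    inside = r < params.r_cut
    if not np.any(inside):
        return 0.0
    sr6 = (params.sigma / r[inside]) ** 6
    return float(np.sum(4.0 * params.epsilon_lj * (sr6 * sr6 - sr6) - params.v_shift))


def _angle_e_around(pos: np.ndarray, i: int, params: ModelParams) -> float:
    n = pos.shape[0]
    lo = max(i - 1, 1)
    hi = min(i + 1, n - 2)
    e = 0.0
    for c in range(lo, hi + 1):
        b1 = pos[c] - pos[c - 1]
        b2 = pos[c + 1] - pos[c]
        cosang = np.dot(b1, b2) / (np.linalg.norm(b1) * np.linalg.norm(b2))
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        e += params.kappa * (1.0 - np.cos(theta - params.theta0))
    return e


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _tune_walker(w: _Walker, blocks: int, block_sweeps: int, gain: float = 0.1) -> None:
    for _ in range(blocks):
        w.reset_counters()
        for _ in range(block_sweeps):
            w.sweep()
        w.r_d = adapt_step_size(w.acceptance_rate(), w.r_d, gain)
    if not 0.40 <= w.acceptance_rate() <= 0.60:
        logger.warning(
            "step-size tuning at T=%.3f ended at acceptance %.2f (target 0.5); "
            "using r_d=%.3g anyway", w.t, w.acceptance_rate(), w.r_d,
        )
    w.reset_counters()


def sample_chain(
    params: ModelParams,
    n_monomers: int,
    temperature: float,
    sweeps: int,
    seed: int = 0,
    r_d: float = 0.5,
    tuning_blocks: int = 60,
    tuning_block_sweeps: int = 50,
    equilibration: int = 500,
    measure_every: int = 1,
    pivot_interval: int = 20,
    observable: Callable[[np.ndarray], float] | None = None,
    initial: Conformation | None = None,
) -> SimpleNamespace:
    """Plain single-temperature Metropolis run with tuned step size.

    Returns measured energies, optional per-measurement observable values, the
    post-tuning displacement acceptance rate and the frozen step size.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    conf = initial.copy() if initial is not None else straight_chain(n_monomers)
    w = _Walker(params, conf, temperature, r_d, rng)
    # equilibrate the conformation first: the optimal step size depends on
    # the typical state (collapsed vs extended), so tuning runs afterwards
    for s in range(equilibration):
        w.sweep()
        if pivot_interval and (s + 1) % pivot_interval == 0 and n_monomers > 2:
            w.pivot_sweep()
    _tune_walker(w, tuning_blocks, tuning_block_sweeps)
    w.reset_counters()
    energies, obs = [], []
    for s in range(sweeps):
        w.sweep()
        if pivot_interval and (s + 1) % pivot_interval == 0 and n_monomers > 2:
            w.pivot_sweep()
        if (s + 1) % FULL_RECOMPUTE_PERIOD == 0:
            w.resync()
        if (s + 1) % measure_every == 0:
            energies.append(w.energy)
            if observable is not None:
                obs.append(observable(w.conf.positions))
    return SimpleNamespace(
        energies=np.array(energies),
        observables=np.array(obs) if observable is not None else None,
        acceptance=w.acceptance_rate(),
        r_d=w.r_d,
        conformation=w.conf,
    )


def _rg2(pos: np.ndarray) -> float:
    c = pos - pos.mean(axis=0)
    return float(np.mean(np.sum(c * c, axis=1)))


def run_remc(config: RunConfig, params: ModelParams) -> HistogramSet:
    """Replica-exchange run: tune, equilibrate, measure; returns the histograms.

    Per sweep each thread attempts N displacement moves; every 20-70
    displacement sweeps (thread-dependent) a sweep of pivot rotations; every
    ``exchange_period`` sweeps neighbouring threads attempt to swap
    conformations, alternating even/odd pairings.  Fully reproducible from
    ``config.seed``.
    """
    ladder = config.ladder
    k_threads = ladder.count
    seeds = np.random.SeedSequence(config.seed).spawn(k_threads + 1)
    swap_rng = np.random.default_rng(seeds[-1])
    walkers = [
        _Walker(params, straight_chain(config.n_monomers), float(t), 0.5,
                np.random.default_rng(seeds[k]))
        for k, t in enumerate(ladder.temperatures)
    ]

    pivot_iv = config.pivot_intervals()
    swap_attempts = np.zeros(max(k_threads - 1, 1))
    swap_accepts = np.zeros(max(k_threads - 1, 1))
    swap_parity = 0

    def maybe_exchange() -> None:
        nonlocal swap_parity
        if k_threads < 2:
            return
        for lo in range(swap_parity, k_threads - 1, 2):
            a, b = walkers[lo], walkers[lo + 1]
            swap_attempts[lo] += 1
            if replica_swap(a.energy, b.energy, a.t, b.t, swap_rng.random()):
                a.conf, b.conf = b.conf, a.conf
                a.energy, b.energy = b.energy, a.energy
                swap_accepts[lo] += 1
        swap_parity ^= 1

    sweep_count = 0

    def advance(n_sweeps: int, record: bool) -> None:
        nonlocal sweep_count
        for _ in range(n_sweeps):
            sweep_count += 1
            for k, w in enumerate(walkers):
                w.sweep()
                if sweep_count % pivot_iv[k] == 0 and config.n_monomers > 2:
                    w.pivot_sweep()
            if sweep_count % FULL_RECOMPUTE_PERIOD == 0:
                for w in walkers:
                    w.resync()
            if sweep_count % config.exchange_period == 0:
                maybe_exchange()
            if record and sweep_count % config.measure_every == 0:
                for k, w in enumerate(walkers):
                    energies[k].append(w.energy)
                    rg2s[k].append(_rg2(w.conf.positions))
                    if w.energy < best["e"]:
                        best["e"] = w.energy
                        best["x"] = w.conf.positions.copy()

    energies: list[list[float]] = [[] for _ in range(k_threads)]
    rg2s: list[list[float]] = [[] for _ in range(k_threads)]
    best: dict = {"e": np.inf, "x": None}

    # equilibrate with the initial step size, then freeze a tuned one per
    # thread before any measurement (the 50% target refers to the
    # equilibrated state)
    advance(config.equilibration, record=False)
    for w in walkers:
        _tune_walker(w, config.tuning_blocks, config.tuning_block_sweeps)
        w.reset_counters()
    advance(config.sweeps, record=True)

    e_all = [np.asarray(e) for e in energies]
    lo = min(e.min() for e in e_all)
    hi = max(e.max() for e in e_all)
    bw = config.bin_width
    edges = np.arange(np.floor(lo / bw) * bw, np.ceil(hi / bw) * bw + 1.5 * bw, bw)
    counts = np.zeros((k_threads, edges.size - 1), dtype=int)
    rg2_sums = np.zeros_like(counts, dtype=float)
    for k in range(k_threads):
        counts[k], _ = np.histogram(e_all[k], bins=edges)
        rg2_sums[k], _ = np.histogram(e_all[k], bins=edges, weights=np.asarray(rg2s[k]))

    occupied = counts.sum(axis=0) > 0
    gaps = _interior_gaps(occupied)
    if gaps:
        warnings.warn(
            f"unvisited energy gaps between thread histograms at bins {gaps[:5]}; "
            "multi-histogram reweighting may be ill-conditioned",
            RuntimeWarning,
        )

    with np.errstate(invalid="ignore"):
        rates = np.divide(swap_accepts, swap_attempts, out=np.zeros_like(swap_accepts),
                          where=swap_attempts > 0)
    return HistogramSet(
        bin_edges=edges,
        counts=counts,
        m_k=np.array([len(e) for e in e_all]),
        temperatures=ladder.temperatures.copy(),
        rg2_sums=rg2_sums,
        acceptance=np.array([w.acceptance_rate() for w in walkers]),
        swap_rates=rates if k_threads > 1 else None,
        min_energy=float(best["e"]),
        min_conformation=best["x"],
        step_sizes=np.array([w.r_d for w in walkers]),
        meta={"n_monomers": config.n_monomers, "kappa": params.kappa, "seed": config.seed},
    )


def _interior_gaps(occupied: np.ndarray) -> list[int]:
    idx = np.nonzero(occupied)[0]
    if idx.size == 0:
        return []
    interior = np.arange(idx[0], idx[-1] + 1)
    return [int(i) for i in interior if not occupied[i]]


def simulated_annealing(
    params: ModelParams,
    n_monomers: int,
    schedule: np.ndarray | None = None,
    restarts: int = 4,
    sweeps_per_temperature: int = 200,
    seed: int = 0,
    initial: Conformation | None = None,
    polish: bool = True,
    refine_steps: int = 1500,
) -> Conformation:
    """Ground-state search: cooled Metropolis runs plus a gradient polish.

    Each restart cools a walker through ``schedule`` (default: geometric from
    T=2 to T=0.01), mixing displacement sweeps with occasional pivot sweeps;
    the best conformation over all restarts is locally minimised with L-BFGS
    on the smooth energy.  If ``initial`` is given, it seeds the first restart
    and the returned energy is never worse than its energy.
    """
    if schedule is None:
        schedule = np.geomspace(2.0, 0.01, 50)
    if np.any(np.diff(schedule) >= 0):
        raise ValueError("annealing schedule must be strictly decreasing")

    candidates: list[tuple[float, np.ndarray]] = []
    if initial is not None:
        candidates.append((total_energy(initial, params).total, initial.positions.copy()))

    seeds = np.random.SeedSequence(seed).spawn(restarts)
    for r in range(restarts):
        rng = np.random.default_rng(seeds[r])
        if r == 0 and initial is not None:
            conf = initial.copy()
        else:
            conf = _random_coil(n_monomers, rng)
        w = _Walker(params, conf, float(schedule[0]), 0.3, rng)
        run_best = (np.inf, None)
        for t in schedule:
            w.t = float(t)
            w.r_d = 0.02 + 0.3 * np.sqrt(t)
            for s in range(sweeps_per_temperature):
                w.sweep()
                if (s + 1) % 10 == 0 and n_monomers > 2:
                    w.pivot_sweep()
                if (s + 1) % 5 == 0 and n_monomers > 2:
                    prop = reptation_move(w.conf, rng)
                    try:
                        e_new = total_energy(prop.positions, params).total
                    except ValueError:
                        e_new = np.inf
                    if np.isfinite(e_new) and metropolis_accept(w.energy, e_new, w.t, rng.random()):
                        w.conf.positions = prop.positions
                        w.energy = e_new
            w.resync()
            if w.energy < run_best[0]:
                run_best = (w.energy, w.conf.positions.copy())
        candidates.append(run_best)

    if polish:
        polished = []
        for e, x in candidates:
            if x is None:
                continue
            polished.append(_local_minimize(x, params))
        candidates.extend(polished)
        # refine the chain threading of the best packing: near-degenerate
        # threadings of the same cluster differ only in which monomer sits
        # where along the chain, and only reptation can move between them
        best = min(candidates, key=lambda c: c[0])
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
        candidates.append(_threading_refine(best[1], params, rng, steps=refine_steps))

    best_e, best_x = min(candidates, key=lambda c: c[0])
    out = Conformation(best_x)
    out.energy_cache = best_e
    return out


def _local_minimize(x: np.ndarray, params: ModelParams) -> tuple[float, np.ndarray]:
    from scipy.optimize import minimize

    res = minimize(
        energy_and_grad, np.asarray(x, dtype=float).ravel(), args=(params,), jac=True,
        method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    cand = Conformation(res.x.reshape(-1, 3))
    if cand.is_valid(params):
        return total_energy(cand, params).total, cand.positions
    return np.inf, cand.positions


def _threading_refine(
    x: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    steps: int = 1500,
    temperature: float = 0.01,
) -> tuple[float, np.ndarray]:
    """Low-temperature Metropolis walk in threading space.

    Alternates reptation proposals with full local minimisation; the tiny
    temperature accepts the near-degenerate rethreadings but rejects real
    uphill moves, letting the chain end slither to its optimal position
    (e.g. into the center of an icosahedral cluster) without disturbing the
    packing.  Returns the best state visited.
    """
    cur_e, cur_x = _local_minimize(x, params)
    best_e, best_x = cur_e, cur_x
    for _ in range(steps):
        prop = reptation_move(Conformation(cur_x), rng)
        e, px = _local_minimize(prop.positions, params)
        if np.isfinite(e) and metropolis_accept(cur_e, e, temperature, rng.random()):
            cur_e, cur_x = e, px
            if e < best_e:
                best_e, best_x = e, px
    return best_e, best_x


def _random_coil(n: int, rng: np.random.Generator) -> Conformation:
    """Self-avoiding-ish random walk at bond length r0 = 1."""
    pos = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            step = rng.standard_normal(3)
            step /= np.linalg.norm(step)
            cand = pos[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) > 0.9:
                break
        pos[i] = cand
    return Conformation(pos)
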