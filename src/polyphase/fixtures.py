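"""Synthetic fixtures with exact ground truth for every analysis stage.

Analytic density-of-states families plant least-sensitive inflection points
of known order and character, so the detector and classifier can be tested
without simulating a polymer; canonical histograms are drawn i.i.d. from the
analytic Boltzmann distribution, so the reweighting error bands are exactly
interpretable (no Markov-chain autocorrelation); and deterministic chain
geometries (hairpin, helix, icosahedral cluster, ...) exercise the structural
observables.

All families keep beta(E) = S'(E) > 0 on their energy window, matching the
physical sign condition of the classification rules; constructors raise on
parameter choices that violate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .model import Conformation
from .reweighting import DensityOfStates
from .sampler import HistogramSet, TemperatureLadder

__all__ = [
    "AnalyticDoS",
    "PlantedTransition",
    "make_toy_dos",
    "sample_histograms",
    "make_conformation_fixture",
    "TOY_FAMILIES",
]


@dataclass(frozen=True)
class PlantedTransition:
    order: int
    character: str
    e_tr: float
    beta_tr: float


@dataclass
class AnalyticDoS:
    """Closed-form ln g(E) with exact derivative callables and planted truth."""

    family: str
    window: tuple[float, float]
    ln_g: Callable[[np.ndarray], np.ndarray]
    beta: Callable[[np.ndarray], np.ndarray]
    gamma: Callable[[np.ndarray], np.ndarray]
    delta: Callable[[np.ndarray], np.ndarray]
    planted: list[PlantedTransition] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.linspace(*self.window, 512)
        if np.any(self.beta(e) <= 0):
            raise ValueError(
                f"{self.family}: beta(E) must stay positive on the window "
                "(unphysical fixture)"
            )

    def tabulate(self, n_bins: int = 241) -> DensityOfStates:
        """Exact ln g on a uniform grid, normalised to max 0."""
        e = np.linspace(*self.window, n_bins)
        lg = self.ln_g(e)
        return DensityOfStates(e, lg - lg.max(), meta={"family": self.family})


def _gaussian(s: float = 10.0, window=None, **_) -> AnalyticDoS:
    if window is None:
        window = (-26.0 * s, -1.0 * s)
    return AnalyticDoS(
        family="gaussian", window=tuple(window),
        ln_g=lambda e: -np.asarray(e) ** 2 / (2 * s * s),
        beta=lambda e: -np.asarray(e) / (s * s),
        gamma=lambda e: np.full_like(np.asarray(e, dtype=float), -1.0 / (s * s)),
        delta=lambda e: np.zeros_like(np.asarray(e, dtype=float)),
        params={"s": s},
    )


def _first_order(b0: float = 3.0, c: float = 1e-3, e_t: float = 50.0,
                 half_width: float = 30.0, **_) -> AnalyticDoS:
    """beta(E) = b0 + c (E - E_t)^2: backbending with a positive minimum at E_t."""
    def u(e):
        return np.asarray(e, dtype=float) - e_t

    return AnalyticDoS(
        family="first_order_toy", window=(e_t - half_width, e_t + half_width),
        ln_g=lambda e: b0 * u(e) + c * u(e) ** 3 / 3.0,
        beta=lambda e: b0 + c * u(e) ** 2,
        gamma=lambda e: 2.0 * c * u(e),
        delta=lambda e: np.full_like(u(e), 2.0 * c),
        planted=[PlantedTransition(1, "independent", e_t, b0)],
        params={"b0": b0, "c": c, "e_t": e_t, "half_width": half_width},
    )


def _second_order(gamma0: float = -0.05, a: float = 0.04, w: float = 5.0,
                  beta_c: float = 3.0, e_t: float = 50.0,
                  half_width: float = 30.0, **_) -> AnalyticDoS:
    """gamma(E) has a negative-valued Lorentzian peak at E_t."""
    if gamma0 + a >= 0:
        raise ValueError("peak value gamma0 + a must stay negative")

    def u(e):
        return np.asarray(e, dtype=float) - e_t

    def s_fun(e):
        v = u(e)
        return (beta_c * v + 0.5 * gamma0 * v**2
                + a * w * (v * np.arctan(v / w) - 0.5 * w * np.log1p(v**2 / w**2)))

    dos = AnalyticDoS(
        family="second_order_toy", window=(e_t - half_width, e_t + half_width),
        ln_g=s_fun,
        beta=lambda e: beta_c + gamma0 * u(e) + a * w * np.arctan(u(e) / w),
        gamma=lambda e: gamma0 + a * w * w / (w * w + u(e) ** 2),
        delta=lambda e: -2.0 * a * w * w * u(e) / (w * w + u(e) ** 2) ** 2,
        planted=[PlantedTransition(2, "independent", e_t, beta_c)],
        params={"gamma0": gamma0, "a": a, "w": w, "beta_c": beta_c, "e_t": e_t},
    )
    return dos


def _third_order(d0: float = 0.02, c: float = 2e-4, g_edge: float = -0.3,
                 beta_margin: float = 1.0, e_t: float = 50.0,
                 half_width: float = 30.0, **_) -> AnalyticDoS:
    """delta(E) = d0 + c (E - E_t)^2: a positive-valued minimum at E_t.

    gamma stays negative (g_edge < 0 is its value at the upper window edge)
    and beta positive, so no lower-order signal is planted.
    """
    length = half_width
    g0 = g_edge - (d0 * length + c * length**3 / 3.0)
    beta_c = beta_margin - (g0 * length + 0.5 * d0 * length**2 + c * length**4 / 12.0)

    def u(e):
        return np.asarray(e, dtype=float) - e_t

    return AnalyticDoS(
        family="third_order_toy", window=(e_t - half_width, e_t + half_width),
        ln_g=lambda e: (beta_c * u(e) + 0.5 * g0 * u(e) ** 2 + d0 * u(e) ** 3 / 6.0
                        + c * u(e) ** 5 / 60.0),
        beta=lambda e: beta_c + g0 * u(e) + 0.5 * d0 * u(e) ** 2 + c * u(e) ** 4 / 12.0,
        gamma=lambda e: g0 + d0 * u(e) + c * u(e) ** 3 / 3.0,
        delta=lambda e: d0 + c * u(e) ** 2,
        planted=[PlantedTransition(3, "independent", e_t,
                                   beta_c)],
        params={"d0": d0, "c": c, "g_edge": g_edge, "e_t": e_t},
    )


def _composite(b0: float = 3.0, k: float = 1e-3, a: float = 5.0, b: float = 12.0,
               e_1: float = 40.0, below: float = 6.0, above: float = 6.0,
               **_) -> AnalyticDoS:
    """Independent first-order at E_1 plus a dependent second-order above it.

    Built from delta(E) = k (v - a)(v - b) with v = E - E_1 and b/3 < a < b:
    beta has a positive minimum b0 at E_1 and gamma a positive-valued local
    minimum at E_1 + b, inside the convex (backbending) region.
    """
    if not (b / 3.0 < a < b):
        raise ValueError("need b/3 < a < b for a positive gamma minimum")

    def v(e):
        return np.asarray(e, dtype=float) - e_1

    def gamma_f(e):
        x = v(e)
        return k * (x**3 / 3.0 - 0.5 * (a + b) * x**2 + a * b * x)

    def beta_f(e):
        x = v(e)
        return b0 + k * (x**4 / 12.0 - (a + b) * x**3 / 6.0 + 0.5 * a * b * x**2)

    def s_f(e):
        x = v(e)
        return b0 * x + k * (x**5 / 60.0 - (a + b) * x**4 / 24.0 + a * b * x**3 / 6.0)

    beta_tr2 = float(beta_f(e_1 + b))
    return AnalyticDoS(
        family="composite", window=(e_1 - below, e_1 + b + above),
        ln_g=s_f, beta=beta_f, gamma=gamma_f,
        delta=lambda e: k * (v(e) - a) * (v(e) - b),
        planted=[
            PlantedTransition(1, "independent", e_1, b0),
            PlantedTransition(2, "dependent", e_1 + b, beta_tr2),
        ],
        params={"b0": b0, "k": k, "a": a, "b": b, "e_1": e_1},
    )


TOY_FAMILIES = {
    "gaussian": _gaussian,
    "first_order_toy": _first_order,
    "second_order_toy": _second_order,
    "third_order_toy": _third_order,
    "composite": _composite,
}

# parameter ranges used when a seed requests a random parameterization
_RANDOM_RANGES = {
    "gaussian": {"s": (8.0, 14.0)},
    "first_order_toy": {"b0": (1.5, 5.0), "c": (5e-4, 2e-3), "e_t": (35.0, 65.0)},
    "second_order_toy": {"gamma0": (-0.08, -0.03), "w": (3.0, 8.0),
                         "beta_c": (2.0, 4.0), "e_t": (35.0, 65.0)},
    "third_order_toy": {"d0": (0.01, 0.04), "e_t": (35.0, 65.0)},
    "composite": {"b0": (2.0, 4.0), "k": (8e-4, 2e-3), "b": (9.0, 15.0),
                  "e_1": (30.0, 50.0)},
}


def make_toy_dos(family: str, params: dict | None = None,
                 seed: int | None = None) -> AnalyticDoS:
    """Build an analytic DoS fixture.

    ``params`` overrides family defaults.  With a ``seed``, the remaining free
    parameters are drawn uniformly from documented well-conditioned ranges,
    giving an endless supply of distinct planted-truth fixtures.
    """
    if family not in TOY_FAMILIES:
        raise ValueError(f"unknown fixture family {family!r}; "
                         f"choose from {sorted(TOY_FAMILIES)}")
    kwargs = dict(params or {})
    if seed is not None:
        rng = np.random.default_rng(seed)
        for name, (lo, hi) in _RANDOM_RANGES[family].items():
            kwargs.setdefault(name, float(rng.uniform(lo, hi)))
        if family == "second_order_toy":
            # peak value gamma0 + a must stay strictly negative
            kwargs.setdefault("a", float(rng.uniform(0.3, 0.7)) * abs(kwargs["gamma0"]))
        if family == "third_order_toy":
            # keep the delta parabola sharp relative to its floor, so the
            # planted minimum stays put under smoothing
            kwargs.setdefault("c", kwargs["d0"] / float(rng.uniform(50.0, 180.0)))
        if family == "composite":
            # a well inside (b/3, 0.55 b): clear contrast between the gamma
            # maximum at a and the planted positive minimum at b; window
            # margins scale with the feature so the polynomial tails stay tame
            b = kwargs["b"]
            kwargs.setdefault("a", float(rng.uniform(b / 3.0 + 0.3, 0.55 * b)))
            kwargs.setdefault("below", float(rng.uniform(0.45, 0.6)) * b)
            kwargs.setdefault("above", float(rng.uniform(0.45, 0.6)) * b)
    return TOY_FAMILIES[family](**kwargs)


def sample_histograms(
    dos: AnalyticDoS | DensityOfStates,
    ladder: TemperatureLadder | Sequence[float],
    m_per_thread: int = 100_000,
    bin_width: float = 0.5,
    seed: int = 0,
) -> HistogramSet:
    """Draw i.i.d. canonical energy histograms from an analytic DoS.

    Each thread k receives a multinomial sample of size M from the
    discretised distribution p(E) ~ g(E) exp(-E / k_B T_k) on a shared bin
    grid spanning the fixture window.
    """
    temps = ladder.temperatures if isinstance(ladder, TemperatureLadder) else np.asarray(ladder, float)
    if isinstance(dos, AnalyticDoS):
        lo, hi = dos.window
        edges = np.arange(lo, hi + bin_width, bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ln_g = dos.ln_g(centers)
    else:
        centers = dos.energies
        step = float(np.min(np.diff(centers))) if centers.size > 1 else 1.0
        edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
        ln_g = dos.ln_g
    rng = np.random.default_rng(seed)
    counts = np.zeros((temps.size, centers.size), dtype=int)
    for kk, t in enumerate(temps):
        lp = ln_g - centers / t
        lz = logsumexp(lp)
        if not np.isfinite(lz):
            raise ValueError(f"canonical distribution not normalizable at T={t}")
        counts[kk] = rng.multinomial(m_per_thread, np.exp(lp - lz))
    return HistogramSet(
        bin_edges=edges, counts=counts,
        m_k=np.full(temps.size, m_per_thread),
        temperatures=np.asarray(temps, dtype=float),
        meta={"synthetic": True,
              "family": dos.family if isinstance(dos, AnalyticDoS) else "tabulated"},
    )


# ---------------------------------------------------------------------------
# deterministic chain geometries
# ---------------------------------------------------------------------------


def _icosahedron_13() -> np.ndarray:
    """Centered icosahedral cluster: 12 vertices at edge length 1 plus center.

    The chain visits the center first, then a Hamiltonian path over the
    vertex-adjacency graph, so every bond has length ~0.951 (center-vertex)
    or 1 (edge), both inside the FENE interval.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    raw = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            raw.append((0.0, s1 * 1.0, s2 * phi))
            raw.append((s1 * 1.0, s2 * phi, 0.0))
            raw.append((s1 * phi, 0.0, s2 * 1.0))
    v = np.array(raw) / 2.0  # edge length 1 after scaling (raw edge = 2)
    # adjacency at edge length 1
    d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
    adj = (d > 0.5) & (d < 1.1)

    path = None

    def extend(p: list) -> list | None:
        if len(p) == 12:
            return p
        for nxt in np.nonzero(adj[p[-1]])[0]:
            if nxt not in p:
                r = extend(p + [int(nxt)])
                if r is not None:
                    return r
        return None

    path = extend([0])
    return np.vstack([np.zeros(3), v[path]])


def make_conformation_fixture(kind: str, **kwargs) -> Conformation:
    """Deterministic chain geometries for structural and sampler tests.

    Kinds: ``straight_chain(n)``, ``dimer(bond)``, ``triangle``,
    ``hairpin(length, spacing)``, ``helix(n)``, ``icosahedron_13``.
    """
    if kind == "straight_chain":
        n = kwargs.get("n", 3)
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n, dtype=float)
    elif kind == "dimer":
        pos = np.array([[0.0, 0, 0], [kwargs.get("bond", 1.0), 0, 0]])
    elif kind == "triangle":
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    elif kind == "hairpin":
        length = kwargs.get("length", 5)
        spacing = kwargs.get("spacing", 1.0)
        down = [(float(i), 0.0, 0.0) for i in range(length)]
        back = [(float(length - 1 - j), spacing, 0.0) for j in range(length)]
        pos = np.array(down + back)
    elif kind == "helix":
        n = kwargs.get("n", 20)
        per_turn = 6
        omega = 2.0 * np.pi / per_turn
        rise = 1.0 / per_turn  # one turn stacks at distance 1
        radius = np.sqrt(1.0 - rise**2) / (2.0 * np.sin(omega / 2.0))
        i = np.arange(n)
        pos = np.column_stack(
            [radius * np.cos(omega * i), radius * np.sin(omega * i), rise * i]
        )
    elif kind == "icosahedron_13":
        pos = _icosahedron_13()
    else:
        raise ValueError(f"unknown conformation fixture {kind!r}")
    return Conformation(pos)
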