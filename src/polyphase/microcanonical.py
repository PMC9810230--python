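"""Generalized microcanonical inflection-point analysis.

The microcanonical entropy S(E) = k_B ln g(E) and its derivatives

    beta(E)  = dS/dE     (inverse microcanonical temperature)
    gamma(E) = dbeta/dE
    delta(E) = dgamma/dE

carry the transition signals of systems of any size.  A phase transition
shows up as a *least-sensitive inflection point*: an inflection of a curve at
which the magnitude of its slope is locally minimal.  The classification
rules implemented here:

* first order (independent): positive-valued local minimum of beta(E)
  (backbending / convex intruder in S);
* second order, independent: negative-valued local maximum ("peak") of gamma;
* second order, dependent: positive-valued local minimum of gamma at an
  energy above an identified first-order transition;
* third order, independent: positive-valued local minimum of delta;
* third order, dependent: negative-valued local extremum of delta above an
  independent lower-order transition.

Curves are smoothed with a single high-degree Bernstein-Bezier curve whose
control polygon is the data itself; derivatives come from the hodograph, so
no finite differencing of noisy data is ever needed.  Uncertainty bands are
leave-one-out jackknife estimates over independent simulation runs, and an
extremum only counts as a transition when it is significant against its band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.special import gammaln

from .reweighting import DensityOfStates

__all__ = [
    "BezierCurve",
    "MicrocanonicalCurves",
    "TransitionRecord",
    "InflectionCandidate",
    "entropy_from_dos",
    "bezier_smooth",
    "curves_from_dos",
    "find_least_sensitive_inflections",
    "classify_transitions",
    "jackknife_uncertainties",
    "MicrocanonicalAnalysis",
    "MicrocanonicalResults",
]

K_B = 1.0  # reduced units


def entropy_from_dos(dos: DensityOfStates) -> tuple[np.ndarray, np.ndarray]:
    """S(E) = k_B ln g(E) on the occupied bins (additive constant from the DoS)."""
    if dos.energies.size == 0:
        raise ValueError("empty density of states")
    return dos.energies.copy(), K_B * dos.ln_g.copy()


# ---------------------------------------------------------------------------
# Bernstein-Bezier smoothing
# ---------------------------------------------------------------------------


def _bernstein_matrix(t: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix B[j, i] = C(n,i) t_j^i (1-t_j)^(n-i), log-domain for stability."""
    i = np.arange(degree + 1)
    ln_c = gammaln(degree + 1) - gammaln(i + 1) - gammaln(degree - i + 1)
    t = np.asarray(t, dtype=float)
    interior = (t > 0) & (t < 1)
    out = np.zeros((t.size, degree + 1))
    if np.any(interior):
        ti = t[interior, None]
        out[interior] = np.exp(ln_c[None, :] + i[None, :] * np.log(ti)
                               + (degree - i)[None, :] * np.log1p(-ti))
    out[t <= 0, 0] = 1.0
    out[t >= 1, degree] = 1.0
    return out


class BezierCurve:
    """Parametric Bezier curve (x(t), y(t)) with the data as control points.

    Degree equals the number of points minus one; the curve interpolates the
    endpoints and smooths everything in between (Bernstein operators preserve
    monotonicity and convexity of the control polygon, so no artificial
    backbending is ever created).  Values and the first three derivatives
    with respect to x are available anywhere on [x_0, x_n].
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 4:
            raise ValueError("need at least 4 points for third derivatives")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        self.cx = x
        self.cy = y
        self.degree = x.size - 1
        self._dense: dict | None = None

    def evaluate(self, num: int | None = None):
        """Tabulate the curve and its x-derivatives on a uniform t grid.

        Returns a dict with keys ``x, value, d1, d2, d3``.
        """
        n = self.degree
        if num is None:
            num = max(4 * (n + 1) + 1, 401)
        t = np.linspace(0.0, 1.0, num)

        def hodo(c, order):
            d = np.diff(c, n=order)
            fac = np.prod(np.arange(n, n - order, -1, dtype=float)) if order else 1.0
            return fac * (_bernstein_matrix(t, n - order) @ d if order else _bernstein_matrix(t, n) @ c)

        x = hodo(self.cx, 0)
        xp = hodo(self.cx, 1)
        xpp = hodo(self.cx, 2)
        xppp = hodo(self.cx, 3)
        y = hodo(self.cy, 0)
        yp = hodo(self.cy, 1)
        ypp = hodo(self.cy, 2)
        yppp = hodo(self.cy, 3)

        f1 = yp / xp
        f2 = (ypp * xp - yp * xpp) / xp**3
        f3 = (yppp * xp - yp * xppp) / xp**4 - 3.0 * xpp * (ypp * xp - yp * xpp) / xp**5
        return {"t": t, "x": x, "value": y, "d1": f1, "d2": f2, "d3": f3}

    def _cached(self):
        if self._dense is None:
            self._dense = self.evaluate()
        return self._dense

    def __call__(self, x, deriv: int = 0):
        """Evaluate value (deriv=0) or d^k/dx^k (k<=3) at arbitrary x."""
        key = {0: "value", 1: "d1", 2: "d2", 3: "d3"}[deriv]
        d = self._cached()
        return np.interp(np.asarray(x, dtype=float), d["x"], d[key])


def _control_grid(x: np.ndarray, y: np.ndarray, max_points: int | None):
    """Resample onto an exactly uniform control grid of at most max_points.

    Uniform control abscissae make x(t) affine in the curve parameter, so the
    chain-rule derivative formulas stay free of spacing-induced wobble; for
    histogram-binned data (already uniform) this is plain decimation up to a
    negligible interpolation correction.
    """
    if max_points is None or x.size <= max_points:
        return x, y
    n = x.size
    h = np.diff(x)
    if np.allclose(h, h[0], rtol=1e-9):
        # uniform data: integer-stride subsample (no interpolation error),
        # trimming the remainder symmetrically from the ends
        s = int(np.ceil((n - 1) / (max_points - 1)))
        count = (n - 1) // s + 1
        offset = (n - 1 - s * (count - 1)) // 2
        idx = offset + s * np.arange(count)
        return x[idx], y[idx]
    xu = np.linspace(x[0], x[-1], max_points)
    return xu, np.interp(xu, x, y)


def bezier_smooth(x: np.ndarray, y: np.ndarray, max_points: int | None = None) -> BezierCurve:
    """Bezier-smooth (x, y) samples, optionally decimating dense data first.

    Smoothing strength grows as the control polygon gets denser, so noisy
    high-resolution data should be decimated (``max_points``) before fitting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return BezierCurve(*_control_grid(x, y, max_points))


# ---------------------------------------------------------------------------
# curves container
# ---------------------------------------------------------------------------


@dataclass
class MicrocanonicalCurves:
    """Entropy and its first three derivatives on one energy grid."""

    energies: np.ndarray
    entropy: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    se_entropy: np.ndarray | None = None
    se_beta: np.ndarray | None = None
    se_gamma: np.ndarray | None = None
    se_delta: np.ndarray | None = None
    e_min: float | None = None        # putative ground-state energy for the dE shift
    spacing: float = np.nan           # spacing of the smoothing control grid
    meta: dict = field(default_factory=dict)

    @property
    def has_bands(self) -> bool:
        return self.se_beta is not None

    @property
    def delta_e(self) -> np.ndarray:
        ref = self.e_min if self.e_min is not None else self.energies[0]
        return self.energies - ref

    def to_frame(self):
        import pandas as pd

        data = {
            "E": self.energies, "dE": self.delta_e, "S": self.entropy,
            "beta": self.beta, "gamma": self.gamma, "delta": self.delta,
        }
        for name in ("entropy", "beta", "gamma", "delta"):
            se = getattr(self, f"se_{name}")
            if se is not None:
                data[f"se_{'S' if name == 'entropy' else name}"] = se
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, axes=None):
        """Four stacked panels: S, beta, gamma, delta against dE."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(4, 1, sharex=True, figsize=(6, 10))
        labels = ["S", r"$\beta$", r"$\gamma$", r"$\delta$"]
        curves = [self.entropy, self.beta, self.gamma, self.delta]
        ses = [self.se_entropy, self.se_beta, self.se_gamma, self.se_delta]
        for ax, y, se, lab in zip(axes, curves, ses, labels):
            ax.plot(self.delta_e, y, lw=1)
            if se is not None:
                ax.fill_between(self.delta_e, y - se, y + se, alpha=0.3)
            ax.set_ylabel(lab)
        axes[-1].set_xlabel(r"$\Delta E$")
        return axes


def curves_from_dos(
    dos: DensityOfStates,
    decimate: int = 100,
    n_eval: int = 801,
    e_min: float | None = None,
) -> MicrocanonicalCurves:
    """Smooth one run's entropy and tabulate S, beta, gamma, delta."""
    e, s = entropy_from_dos(dos)
    xc, yc = _control_grid(e, s, decimate)
    curve = BezierCurve(xc, yc)
    grid = np.linspace(e[0], e[-1], n_eval)
    return MicrocanonicalCurves(
        energies=grid,
        entropy=curve(grid, 0),
        beta=curve(grid, 1),
        gamma=curve(grid, 2),
        delta=curve(grid, 3),
        e_min=e_min,
        spacing=float((xc[-1] - xc[0]) / (xc.size - 1)),
    )


def jackknife_uncertainties(
    runs: Sequence[DensityOfStates],
    decimate: int = 100,
    n_eval: int = 801,
    e_min: float | None = None,
) -> MicrocanonicalCurves:
    """Jackknife mean and standard error of S, beta, gamma, delta over runs.

    Each run is smoothed identically; curves are tabulated on the energy
    window where at least two runs have support (histogram edges are noisy,
    so the detection window stays away from them).  With a single run the
    curves are returned without bands.
    """
    runs = list(runs)
    if len(runs) == 0:
        raise ValueError("need at least one run")
    if len(runs) == 1:
        return curves_from_dos(runs[0], decimate, n_eval, e_min)

    los = sorted(r.energies[0] for r in runs)
    his = sorted(r.energies[-1] for r in runs)
    lo, hi = los[1], his[-2]  # >= 2 runs have support inside [lo, hi]
    if hi <= lo:
        raise ValueError("runs do not share an energy window")
    grid = np.linspace(lo, hi, n_eval)

    tabs = {name: [] for name in ("entropy", "beta", "gamma", "delta")}
    spacing = np.nan
    for r in runs:
        e, s = entropy_from_dos(r)
        sel = (e >= lo - 1e-12) & (e <= hi + 1e-12)
        if sel.sum() < 4:
            continue
        xc, yc = _control_grid(e[sel], s[sel], decimate)
        curve = BezierCurve(xc, yc)
        spacing = float((xc[-1] - xc[0]) / (xc.size - 1))
        g = np.clip(grid, e[sel][0], e[sel][-1])
        for name, d in zip(("entropy", "beta", "gamma", "delta"), (0, 1, 2, 3)):
            tabs[name].append(curve(g, d))

    arrays = {name: np.array(v) for name, v in tabs.items()}
    r_eff = arrays["beta"].shape[0]
    out = {}
    for name, a in arrays.items():
        mean = a.mean(axis=0)
        loo = (a.sum(axis=0)[None, :] - a) / (r_eff - 1)
        se = np.sqrt((r_eff - 1) / r_eff * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
        out[name] = mean
        out[f"se_{name}"] = se
    return MicrocanonicalCurves(
        energies=grid, e_min=e_min, spacing=spacing,
        meta={"n_runs": r_eff}, **out,
    )


# ---------------------------------------------------------------------------
# detection and classification
# ---------------------------------------------------------------------------


@dataclass
class InflectionCandidate:
    """A sign-conditioned extremum of one entropy derivative."""

    energy: float
    value: float               # extremal value of the scanned derivative
    kind: str                  # "min" | "max"
    derivative: str            # "beta" | "gamma" | "delta"
    index: int


@dataclass
class TransitionRecord:
    """One classified transition (a row of the study's summary table)."""

    e_tr: float
    beta_tr: float
    order: int
    character: str                      # "independent" | "dependent"
    signal: float = np.nan              # extremal derivative value at E_tr
    signal_se: float = np.nan
    delta_e: float = np.nan             # E_tr - E_min^(kappa), filled by the pipeline
    borderline: bool = False
    validated: bool = True              # False when no uncertainty bands existed
    parent_e_tr: float | None = None    # independent partner of a dependent record

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError("order must be 1, 2 or 3")
        if not self.beta_tr > 0:
            raise ValueError("transition requires a positive inverse temperature")
        if self.character == "dependent":
            if self.parent_e_tr is None or not self.parent_e_tr < self.e_tr:
                raise ValueError("dependent record needs an independent partner at lower E_tr")

    @property
    def strength(self) -> float:
        return abs(self.signal)


def _extrema(y: np.ndarray, kind: str, prominence_rtol: float = 1e-8) -> np.ndarray:
    """Indices of strict interior extrema, ignoring float-noise wiggles."""
    scale = np.max(np.abs(y)) if y.size else 0.0
    prom = prominence_rtol * (scale + 1e-300)
    sgn = -1.0 if kind == "min" else 1.0
    idx, _ = find_peaks(sgn * y, prominence=prom)
    return idx


def find_least_sensitive_inflections(
    curves: MicrocanonicalCurves,
    scan: str,
    prominence_rtol: float = 1e-8,
) -> list[InflectionCandidate]:
    """Candidate least-sensitive inflection points of one curve.

    ``scan`` names the curve being scanned ("S", "beta" or "gamma"); a
    least-sensitive inflection of that curve is an extremum of its derivative,
    so the next-higher derivative is searched for sign-conditioned extrema:
    S -> minima of beta, beta -> extrema of gamma, gamma -> extrema of delta.
    """
    table = {"S": ("beta", ("min",)), "beta": ("gamma", ("min", "max")),
             "gamma": ("delta", ("min", "max"))}
    if scan not in table:
        raise ValueError("scan must be one of 'S', 'beta', 'gamma'")
    deriv, kinds = table[scan]
    y = getattr(curves, deriv)
    out = []
    for kind in kinds:
        for i in _extrema(y, kind, prominence_rtol):
            out.append(InflectionCandidate(
                energy=float(curves.energies[i]), value=float(y[i]),
                kind=kind, derivative=deriv, index=int(i),
            ))
    return sorted(out, key=lambda c: c.energy)


def _se_at(curves: MicrocanonicalCurves, name: str, i: int) -> float:
    se = getattr(curves, f"se_{name}")
    return float(se[i]) if se is not None else np.nan


def classify_transitions(
    curves: MicrocanonicalCurves,
    significance: float = 1.0,
    prominence_rtol: float = 1e-8,
) -> list[TransitionRecord]:
    """Apply the inflection-point rules, in order, and return all records.

    A signal only counts when its extremal value differs from zero by more
    than ``significance`` jackknife standard errors; without bands the
    records are returned flagged ``validated=False``.  All qualifying extrema
    are reported, ranked by signal strength within each order.
    """
    has_bands = curves.has_bands
    records: list[TransitionRecord] = []

    beta_c = find_least_sensitive_inflections(curves, "S", prominence_rtol)
    gamma_c = find_least_sensitive_inflections(curves, "beta", prominence_rtol)
    delta_c = find_least_sensitive_inflections(curves, "gamma", prominence_rtol)

    # (1) first order: positive-valued minimum of beta
    gamma_maxima = [c for c in gamma_c if c.kind == "max"]
    for c in beta_c:
        if c.value <= 0:
            continue
        se_b = _se_at(curves, "beta", c.index)
        if has_bands and not c.value > significance * se_b:
            continue
        # borderline first/second order: the gamma peak in the backbending
        # region above E_tr straddling zero within 1 SE
        borderline = False
        peaks_above = [g for g in gamma_maxima if g.energy > c.energy]
        if peaks_above:
            g = min(peaks_above, key=lambda p: p.energy)
            se_g = _se_at(curves, "gamma", g.index)
            if has_bands and abs(g.value) <= significance * se_g:
                borderline = True
        records.append(TransitionRecord(
            e_tr=c.energy, beta_tr=c.value, order=1, character="independent",
            signal=c.value, signal_se=se_b, borderline=borderline,
            validated=has_bands,
        ))

    first_order_es = sorted(r.e_tr for r in records)

    # (2) independent second order: negative-valued peak of gamma
    for c in gamma_c:
        if c.kind != "max" or c.value >= 0:
            continue
        se_g = _se_at(curves, "gamma", c.index)
        if has_bands and not abs(c.value) > significance * se_g:
            continue
        b_tr = float(np.interp(c.energy, curves.energies, curves.beta))
        if b_tr <= 0:
            continue
        records.append(TransitionRecord(
            e_tr=c.energy, beta_tr=b_tr,
            order=2, character="independent", signal=c.value, signal_se=se_g,
            validated=has_bands,
        ))

    # (3) dependent second order: positive-valued minimum of gamma above a
    # first-order transition
    for c in gamma_c:
        if c.kind != "min" or c.value <= 0:
            continue
        parents = [e for e in first_order_es if e < c.energy]
        if not parents:
            continue
        se_g = _se_at(curves, "gamma", c.index)
        if has_bands and not c.value > significance * se_g:
            continue
        b_tr = float(np.interp(c.energy, curves.energies, curves.beta))
        if b_tr <= 0:
            continue
        records.append(TransitionRecord(
            e_tr=c.energy, beta_tr=b_tr,
            order=2, character="dependent", signal=c.value, signal_se=se_g,
            validated=has_bands, parent_e_tr=max(parents),
        ))

    independent_es = sorted(r.e_tr for r in records if r.character == "independent")

    # (4) independent third order: positive-valued minimum of delta
    for c in delta_c:
        if c.kind != "min" or c.value <= 0:
            continue
        se_d = _se_at(curves, "delta", c.index)
        if has_bands and not c.value > significance * se_d:
            continue
        b_tr = float(np.interp(c.energy, curves.energies, curves.beta))
        if b_tr <= 0:
            continue
        records.append(TransitionRecord(
            e_tr=c.energy, beta_tr=b_tr,
            order=3, character="independent", signal=c.value, signal_se=se_d,
            validated=has_bands,
        ))

    # (5) dependent third order: negative-valued extremum of delta above an
    # independent lower-order transition
    for c in delta_c:
        if c.value >= 0:
            continue
        parents = [e for e in independent_es if e < c.energy]
        if not parents:
            continue
        se_d = _se_at(curves, "delta", c.index)
        if has_bands and not abs(c.value) > significance * se_d:
            continue
        b_tr = float(np.interp(c.energy, curves.energies, curves.beta))
        if b_tr <= 0:
            continue
        records.append(TransitionRecord(
            e_tr=c.energy, beta_tr=b_tr,
            order=3, character="dependent", signal=c.value, signal_se=se_d,
            validated=has_bands, parent_e_tr=max(parents),
        ))

    records.sort(key=lambda r: (r.order, -r.strength))
    if curves.e_min is not None:
        for r in records:
            r.delta_e = r.e_tr - curves.e_min
    return records


# ---------------------------------------------------------------------------
# model / results front end
# ---------------------------------------------------------------------------


class MicrocanonicalAnalysis:
    """Microcanonical transition analysis of one system.

    Built from one or more independent density-of-states estimates (or
    directly from histogram sets, which are first pushed through WHAM);
    ``fit()`` smooths, differentiates, jackknifes and classifies, returning a
    :class:`MicrocanonicalResults`.
    """

    def __init__(
        self,
        dos_runs: Sequence[DensityOfStates] | DensityOfStates,
        e_min: float | None = None,
        decimate: int = 100,
        n_eval: int = 801,
        significance: float = 1.0,
    ):
        if isinstance(dos_runs, DensityOfStates):
            dos_runs = [dos_runs]
        self.dos_runs = list(dos_runs)
        if not self.dos_runs:
            raise ValueError("need at least one density-of-states estimate")
        self.e_min = e_min
        self.decimate = decimate
        self.n_eval = n_eval
        self.significance = significance

    @classmethod
    def from_histograms(cls, hist_sets, e_min: float | None = None, **kwargs):
        from .reweighting import wham_iterate

        hist_sets = list(hist_sets)
        runs = [wham_iterate(h) for h in hist_sets]
        if e_min is None:
            seen = [h.min_energy for h in hist_sets if np.isfinite(h.min_energy)]
            e_min = min(seen) if seen else None
        return cls(runs, e_min=e_min, **kwargs)

    def fit(self) -> "MicrocanonicalResults":
        curves = jackknife_uncertainties(
            self.dos_runs, decimate=self.decimate, n_eval=self.n_eval, e_min=self.e_min,
        )
        transitions = classify_transitions(curves, significance=self.significance)
        return MicrocanonicalResults(self, curves, transitions)


class MicrocanonicalResults:
    """Fitted curves, classified transitions and their uncertainties."""

    def __init__(self, model: MicrocanonicalAnalysis, curves: MicrocanonicalCurves,
                 transitions: list[TransitionRecord]):
        self.model = model
        self.curves = curves
        self.transitions = transitions

    @property
    def e_min(self) -> float | None:
        return self.model.e_min

    def transitions_frame(self):
        import pandas as pd

        rows = [
            {
                "E_tr": r.e_tr, "dE": r.delta_e, "beta_tr": r.beta_tr,
                "order": r.order, "character": r.character,
                "signal": r.signal, "signal_se": r.signal_se,
                "borderline": r.borderline, "validated": r.validated,
            }
            for r in sorted(self.transitions, key=lambda r: r.e_tr)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Microcanonical inflection-point analysis",
            "=" * 72,
            f"runs: {len(self.model.dos_runs)}    "
            f"energy window: [{self.curves.energies[0]:.3f}, {self.curves.energies[-1]:.3f}]",
            f"E_min (shift reference): "
            + (f"{self.e_min:.4f}" if self.e_min is not None else "lowest occupied bin"),
            f"significance rule: |signal| > {self.model.significance:g} SE",
            "-" * 72,
            f"{'E_tr':>10} {'dE':>9} {'beta_tr':>9} {'order':>6} {'character':>12} "
            f"{'signal':>10} {'flags':>10}",
        ]
        for r in sorted(self.transitions, key=lambda r: r.e_tr):
            flags = ",".join(
                f for f, on in (("borderline", r.borderline), ("unvalidated", not r.validated)) if on
            ) or "-"
            de = f"{r.delta_e:9.2f}" if np.isfinite(r.delta_e) else "        -"
            lines.append(
                f"{r.e_tr:10.3f} {de} {r.beta_tr:9.3f} {r.order:6d} "
                f"{r.character:>12} {r.signal:10.3g} {flags:>10}"
            )
        if not self.transitions:
            lines.append("  (no transitions detected)")
        lines.append("=" * 72)
        return "\n".join(lines)

    def plot(self, axes=None):
        axes = self.curves.plot(axes)
        for r in self.transitions:
            for ax in axes:
                ax.axvline(r.e_tr - (self.curves.e_min or self.curves.energies[0]),
                           color="k", ls=":", lw=0.8)
        return axes
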