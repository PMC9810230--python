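"""Structural observables of chain conformations.

Radius of gyration, the discretised pair distribution function P(r), contact
maps of non-bonded monomer pairs, and a streak summary of the contact map
that quantifies hairpin-like (anti-diagonal) and helix-like (parallel to the
diagonal) secondary arrangements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Conformation

__all__ = [
    "PairDistribution",
    "ContactMap",
    "radius_of_gyration_sq",
    "pair_distribution",
    "contact_map",
    "secondary_motif_summary",
]


def _positions(conf) -> np.ndarray:
    return conf.positions if isinstance(conf, Conformation) else np.asarray(conf, dtype=float)


def radius_of_gyration_sq(conf) -> float:
    """Mean squared monomer distance from the centroid."""
    pos = _positions(conf)
    c = pos - pos.mean(axis=0)
    return float(np.mean(np.sum(c * c, axis=1)))


@dataclass
class PairDistribution:
    """Histogram of all pairwise distances on a grid of spacing 2 r_t.

    Grid cell m covers [2 m r_t, 2 (m+1) r_t), i.e. distances within r_t of
    the cell centre (2m + 1) r_t; every pair lands in exactly one cell, so the
    counts always sum to N (N - 1) / 2.
    """

    r: np.ndarray            # cell centres
    counts: np.ndarray       # integer counts per cell
    r_t: float

    def peak_count(self, near: float, window: float = 0.1) -> int:
        """Largest single-cell count with |r - near| <= window."""
        sel = np.abs(self.r - near) <= window
        return int(self.counts[sel].max()) if np.any(sel) else 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r": self.r, "count": self.counts})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pair_distribution(conf, r_t: float = 0.01, r_max: float | None = None) -> PairDistribution:
    """Count pairs i < j whose distance falls within r_t of each grid value."""
    if r_t <= 0:
        raise ValueError("threshold r_t must be positive")
    pos = _positions(conf)
    n = pos.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    rij = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    if r_max is None:
        r_max = rij.max() + 2 * r_t
    elif rij.max() >= r_max:
        warnings.warn("pair distance exceeds r_max; extending the grid", RuntimeWarning)
        r_max = rij.max() + 2 * r_t
    n_cells = int(np.ceil(r_max / (2 * r_t)))
    counts = np.bincount((rij // (2 * r_t)).astype(int), minlength=n_cells)
    centers = (2 * np.arange(counts.size) + 1) * r_t
    return PairDistribution(r=centers, counts=counts, r_t=r_t)


@dataclass
class ContactMap:
    """Non-bonded monomer pairs closer than the cutoff (default 1.2 r0)."""

    pairs: set = field(default_factory=set)   # {(i, j)} with i < j - 1, 0-based
    n_monomers: int = 0
    cutoff: float = 1.2

    def __contains__(self, pair) -> bool:
        i, j = sorted(pair)
        return (i, j) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def as_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_monomers, self.n_monomers), dtype=bool)
        for i, j in self.pairs:
            m[i, j] = m[j, i] = True
        return m

    def to_frame(self, conf=None):
        """Sparse pair list, 1-based labels; distances included when conf given."""
        import pandas as pd

        rows = sorted(self.pairs)
        data = {"i": [i + 1 for i, _ in rows], "j": [j + 1 for _, j in rows]}
        if conf is not None:
            pos = _positions(conf)
            data["r_ij"] = [float(np.linalg.norm(pos[i] - pos[j])) for i, j in rows]
        return pd.DataFrame(data)

    def to_csv(self, path, conf=None) -> None:
        self.to_frame(conf).to_csv(path, index=False)


def contact_map(conf, cutoff: float = 1.2) -> ContactMap:
    """All pairs i < j - 1 with r_ij < cutoff (bonded pairs excluded)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = _positions(conf)
    n = pos.shape[0]
    iu, ju = np.triu_indices(n, k=2)
    rij = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    sel = rij < cutoff
    return ContactMap(
        pairs={(int(i), int(j)) for i, j in zip(iu[sel], ju[sel])},
        n_monomers=n, cutoff=cutoff,
    )


def secondary_motif_summary(cmap: ContactMap, min_length: int = 3) -> dict:
    """Count anti-diagonal (hairpin-like) and parallel (helix-like) streaks.

    A streak is a maximal run of at least ``min_length`` contacts chained by
    (i+1, j-1) adjacency (anti-diagonal: two strands running opposite ways)
    or (i+1, j+1) adjacency (parallel to the diagonal: helical alignment).
    Returns counts and the length list of each streak type.
    """
    out = {}
    for name, step in (("antidiagonal", (1, -1)), ("parallel", (1, 1))):
        starts = [
            p for p in cmap.pairs
            if (p[0] - step[0], p[1] - step[1]) not in cmap.pairs
        ]
        lengths = []
        for i, j in starts:
            length = 1
            while (i + step[0], j + step[1]) in cmap.pairs:
                i, j = i + step[0], j + step[1]
                length += 1
            if length >= min_length:
                lengths.append(length)
        out[f"{name}_streaks"] = len(lengths)
        out[f"{name}_lengths"] = sorted(lengths)
    return out
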