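"""File I/O: conformations as XYZ/PDB, configs as YAML, tables as CSV.

Coordinates are stored in units of the equilibrium bond length r0; every
monomer is tagged as a carbon atom so that standard molecular viewers can
display the chains.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .model import Conformation

__all__ = ["write_xyz", "read_xyz", "write_pdb", "load_config", "save_config"]


def _mda_universe(conf: Conformation):
    import MDAnalysis as mda

    n = conf.n_monomers
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", ["C"] * n)
    u.add_TopologyAttr("elements", ["C"] * n)
    u.atoms.positions = conf.positions.astype(np.float32)
    return u


def write_xyz(conf: Conformation, path) -> None:
    """One-frame XYZ file, element tag C per monomer, coordinates in r0 units."""
    u = _mda_universe(conf)
    u.atoms.write(str(path))


def read_xyz(path) -> Conformation:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    return Conformation(u.atoms.positions.astype(float))


def write_pdb(conf: Conformation, path) -> None:
    u = _mda_universe(conf)
    u.add_TopologyAttr("resnames", ["POL"])
    u.atoms.write(str(path))


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
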