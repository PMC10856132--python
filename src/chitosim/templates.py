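"""Rigid residue templates for chain construction.

Each monomer kind (GlcN, GlcNAc) has an idealized chair-like template with
the conventional atom names (C1..C6, C7, C8, O3, O4, O5, O6, O7, N and
hydrogens). Templates live in a JSON data file so alternative geometries can
be swapped in without code changes. Local frame: +z is the chain axis, the
ring centroid (C1, C2, C3, C4, C5, O5) sits exactly at the origin, and the
amine/acetyl arm points toward +y.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

RING_ATOMS = ("C1", "C2", "C3", "C4", "C5", "O5")

_cache: dict = {}


def load_templates(path: str | None = None) -> dict:
    """Load residue templates; default is the bundled data file.

    Returns a dict with keys ``residues`` (kind -> {atom name: (3,) array}),
    ``terminal`` (cap atoms: HO4 for the free O4 of residue 1, O1/HO1 for the
    free anomeric carbon of residue DP), ``rise_per_monomer`` and
    ``heavy_bonds``.
    """
    key = path or "__default__"
    if key in _cache:
        return _cache[key]
    if path is None:
        raw = (resources.files("chitosim") / "data" / "residue_templates.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    data = json.loads(raw)
    out = {
        "rise_per_monomer": float(data["rise_per_monomer"]),
        "residues": {
            kind: {name: np.asarray(xyz, float) for name, xyz in atoms.items()}
            for kind, atoms in data["residues"].items()
        },
        "terminal": {name: np.asarray(xyz, float)
                     for name, xyz in data["terminal"].items()},
        "heavy_bonds": {kind: [tuple(b) for b in bonds]
                        for kind, bonds in data["heavy_bonds"].items()},
    }
    _cache[key] = out
    return out


def template_atom_count(kind: str) -> int:
    return len(load_templates()["residues"][kind])


def chain_atom_count(kinds) -> int:
    """Atom count of a built chain: residue templates + 3 terminal cap atoms."""
    return sum(template_atom_count(k) for k in kinds) + 3


def ring_centroid(coords: dict) -> np.ndarray:
    return np.mean([coords[a] for a in RING_ATOMS], axis=0)
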