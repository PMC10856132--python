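"""Core structural containers: atoms, frames, trajectories.

Coordinates are in angstroms throughout. Frames hold column arrays
(struct-of-arrays) for speed; :class:`AtomRecord` is a per-atom view used at
API boundaries. Boxes are orthorhombic; when a box is present, distance-based
analyses apply the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

# residue kind <-> PDB residue name
KIND_TO_RESNAME = {"GlcN": "GCS", "GlcNAc": "NAG", "water": "HOH"}
RESNAME_TO_KIND = {v: k for k, v in KIND_TO_RESNAME.items()}
WATER_RESNAME = "HOH"

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: Bondi-style van der Waals radii (angstrom) used for SASA.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.65, "O": 1.60}


def wrap_coords(coords, box) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis (safe at the upper edge)."""
    box = np.asarray(box, float)
    w = np.mod(np.asarray(coords, float), box)
    return np.where(w >= box, 0.0, w)


def element_from_name(name: str) -> str:
    """Infer the element from a PDB-style atom name (H/C/N/O only)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with its labels and position."""

    name: str
    element: str
    residue_kind: str  # GlcN | GlcNAc | water
    residue_index: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        if self.residue_kind not in KIND_TO_RESNAME:
            raise ValueError(f"unknown residue kind {self.residue_kind!r}")


class Frame:
    """One configuration: atom labels, coordinates and an optional box.

    Parameters
    ----------
    names, resnames, resids, chains : array-like of per-atom labels
        ``resnames`` use PDB conventions (GCS = glucosamine,
        NAG = N-acetylglucosamine, HOH = water).
    coords : (n_atoms, 3) float array, angstrom
    box : optional length-3 float array of orthorhombic edge lengths
    """

    def __init__(self, names, resnames, resids, chains, coords,
                 elements=None, box=None, frame_index: int = 0):
        self.names = np.asarray(names, dtype="U4")
        self.resnames = np.asarray(resnames, dtype="U4")
        self.resids = np.asarray(resids, dtype=np.int64)
        self.chains = np.asarray(chains, dtype="U2")
        self.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if elements is None:
            elements = [element_from_name(n) for n in self.names]
        self.elements = np.asarray(elements, dtype="U2")
        n = len(self.names)
        for arr, label in ((self.resnames, "resnames"), (self.resids, "resids"),
                           (self.chains, "chains"), (self.elements, "elements")):
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != n_atoms {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.box = None if box is None else np.asarray(box, dtype=np.float64).reshape(3)
        self.frame_index = int(frame_index)

    # -- basic views ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    @property
    def is_water(self) -> np.ndarray:
        return self.resnames == WATER_RESNAME

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"

    def chain_ids(self) -> list[str]:
        """Unique chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(c, None)
        return list(seen)

    def solute_chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, w in zip(self.chains, self.is_water):
            if not w:
                seen.setdefault(c, None)
        return list(seen)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_kind=RESNAME_TO_KIND[str(self.resnames[i])],
            residue_index=int(self.resids[i]),
            chain_id=str(self.chains[i]),
            position=self.coords[i].copy(),
        )

    def __iter__(self) -> Iterator[AtomRecord]:
        return (self.atom(i) for i in range(self.n_atoms))

    # -- manipulation -----------------------------------------------------
    def subset(self, indices) -> "Frame":
        """New Frame containing the given atoms (file order preserved)."""
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Frame(self.names[idx], self.resnames[idx], self.resids[idx],
                     self.chains[idx], self.coords[idx],
                     elements=self.elements[idx], box=None if self.box is None
                     else self.box.copy(), frame_index=self.frame_index)

    def copy(self) -> "Frame":
        return self.subset(np.arange(self.n_atoms))

    def select(self, expression: str) -> np.ndarray:
        """Indices of atoms matching a selection expression (see selections)."""
        from .selections import select
        return select(self, expression)

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image displacement(s) b - a under the frame's box."""
        d = np.asarray(b, float) - np.asarray(a, float)
        if self.box is not None:
            d = d - self.box * np.round(d / self.box)
        return d

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.displacement(self.coords[i], self.coords[j])))

    def same_topology(self, other: "Frame") -> bool:
        return (self.n_atoms == other.n_atoms
                and np.array_equal(self.names, other.names)
                and np.array_equal(self.resnames, other.resnames)
                and np.array_equal(self.resids, other.resids)
                and np.array_equal(self.chains, other.chains))


def concatenate(frames: Sequence[Frame], box=None, frame_index: int = 0) -> Frame:
    """Merge frames atom-wise into one frame (labels kept as-is)."""
    return Frame(
        np.concatenate([f.names for f in frames]),
        np.concatenate([f.resnames for f in frames]),
        np.concatenate([f.resids for f in frames]),
        np.concatenate([f.chains for f in frames]),
        np.vstack([f.coords for f in frames]),
        elements=np.concatenate([f.elements for f in frames]),
        box=box, frame_index=frame_index,
    )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, plus builder metadata."""

    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, f in enumerate(self.frames[1:], start=1):
            if not self.frames[0].same_topology(f):
                raise ValueError(f"frame {k} topology differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)
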