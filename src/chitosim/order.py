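"""Chain orientation and order metrics.

The orientation of a chain is the unit vector from the ring centroid of its
second residue to that of its ninth (equal-weight centroid over the six ring
atoms C1, C2, C3, C4, C5, O5). The degree of alignment of a set of chains is

    p2 = (1/N) sum_i (v_i . d)^2

where the director d is the dominant common orientation of the unsigned
chain vectors, computed as the principal eigenvector of the second-moment
matrix (1/N) sum v v^T. This mean-squared-projection form is the primary
order parameter here; it equals 1 for perfect (parallel or antiparallel)
alignment and tends to 1/3 for isotropic orientations as N grows. The
conventional second-Legendre form is recovered as
``p2_conventional = (3*p2 - 1) / 2`` and is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import Frame, wrap_coords
from .templates import RING_ATOMS

DEFAULT_ADJACENCY_CUTOFF = 4.5  # heavy-atom contact distance, A
ANTIPARALLEL_THRESHOLD = 90.0   # pair angle above this counts as antiparallel

_VECTOR_RESIDUES = (2, 9)


@dataclass(frozen=True)
class ChainVector:
    chain_id: str
    v: np.ndarray  # unit vector


@dataclass
class OrderReport:
    """Per-frame orientation summary."""

    frame_index: int
    chain_vectors: list[ChainVector]
    director: np.ndarray
    p2: float
    p2_conventional: float
    pair_angles: list[tuple[str, str, float]] = field(default_factory=list)
    antiparallel_fraction: float = float("nan")


def _ring_centroid(frame: Frame, chain_id: str, resid: int) -> np.ndarray:
    mask = (frame.chains == chain_id) & (frame.resids == resid) \
        & np.isin(frame.names, RING_ATOMS)
    if mask.sum() != len(RING_ATOMS):
        raise ValueError(
            f"chain {chain_id} residue {resid}: expected the {len(RING_ATOMS)} "
            f"ring atoms, found {int(mask.sum())}")
    return frame.coords[mask].mean(axis=0)


def chain_vector(frame: Frame, chain_id: str) -> ChainVector:
    """Unit vector from the ring centroid of residue 2 to that of residue 9."""
    resids = frame.resids[frame.chains == chain_id]
    if len(resids) == 0:
        raise ValueError(f"no atoms with chain id {chain_id!r}")
    if resids.max() < max(_VECTOR_RESIDUES):
        raise ValueError(
            f"chain {chain_id} has only {int(resids.max())} residues; the chain "
            f"vector needs residues {_VECTOR_RESIDUES[0]} and {_VECTOR_RESIDUES[1]}")
    a = _ring_centroid(frame, chain_id, _VECTOR_RESIDUES[0])
    b = _ring_centroid(frame, chain_id, _VECTOR_RESIDUES[1])
    v = frame.displacement(a, b)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError(f"degenerate chain vector for chain {chain_id}")
    return ChainVector(chain_id, v / n)


def director_and_p2(vectors: np.ndarray) -> tuple[float, np.ndarray]:
    """(p2, director) for an (N, 3) array of unit chain vectors.

    The director is the principal eigenvector of the second-moment matrix,
    which depends only on the unsigned orientations; its sign and any
    eigenvalue tie are resolved deterministically (lexicographically smallest
    non-negative representative).
    """
    v = np.asarray(vectors, float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need at least two chain vectors")
    m = v.T @ v / len(v)
    w, e = np.linalg.eigh(m)
    d = e[:, np.argmax(w)]
    # deterministic sign: first nonzero component positive
    nz = np.flatnonzero(np.abs(d) > 1e-12)
    if len(nz) and d[nz[0]] < 0:
        d = -d
    p2 = float(np.mean((v @ d) ** 2))
    return p2, d


def p2_order(frame: Frame, chain_subset=None) -> tuple[float, np.ndarray]:
    """P2 order parameter and director over the frame's (solute) chains."""
    ids = chain_subset if chain_subset is not None else frame.solute_chain_ids()
    vs = np.array([chain_vector(frame, c).v for c in ids])
    return director_and_p2(vs)


def _chain_min_distances(frame: Frame, cutoff: float):
    """Pairs of solute chain ids whose minimum heavy-atom distance <= cutoff."""
    ids = frame.solute_chain_ids()
    heavy = frame.is_heavy & ~frame.is_water
    idx = {c: np.flatnonzero(heavy & (frame.chains == c)) for c in ids}
    box = frame.box
    if box is not None:
        coords = wrap_coords(frame.coords, box)
        tree = {c: cKDTree(coords[idx[c]], boxsize=box) for c in ids}
    else:
        coords = frame.coords
        tree = {c: cKDTree(coords[idx[c]]) for c in ids}
    pairs = []
    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            hits = tree[ci].query_ball_tree(tree[cj], cutoff)
            if any(hits):
                pairs.append((ci, cj))
    return ids, pairs


def pair_angles(frame: Frame, adjacency_cutoff: float = DEFAULT_ADJACENCY_CUTOFF
                ) -> list[tuple[str, str, float]]:
    """Angles between chain vectors of adjacent chains, in degrees [0, 180].

    Two chains are adjacent when their minimum heavy-atom distance is at most
    ``adjacency_cutoff``. Angles near 0 deg indicate parallel alignment,
    near 180 deg antiparallel alignment.
    """
    ids, pairs = _chain_min_distances(frame, adjacency_cutoff)
    vecs = {c: chain_vector(frame, c).v for c in ids}
    out = []
    for ci, cj in pairs:
        cosang = float(np.clip(np.dot(vecs[ci], vecs[cj]), -1.0, 1.0))
        out.append((ci, cj, float(np.degrees(np.arccos(cosang)))))
    return out


def antiparallel_fraction(angles: list[tuple[str, str, float]],
                          threshold: float = ANTIPARALLEL_THRESHOLD) -> float:
    """Fraction of adjacent-pair angles above the antiparallel threshold."""
    if not angles:
        return float("nan")
    return float(np.mean([a > threshold for _, _, a in angles]))


def order_report(frame: Frame,
                 adjacency_cutoff: float = DEFAULT_ADJACENCY_CUTOFF) -> OrderReport:
    ids = frame.solute_chain_ids()
    cvs = [chain_vector(frame, c) for c in ids]
    p2, d = director_and_p2(np.array([cv.v for cv in cvs]))
    angles = pair_angles(frame, adjacency_cutoff)
    return OrderReport(frame_index=frame.frame_index, chain_vectors=cvs,
                       director=d, p2=p2, p2_conventional=(3 * p2 - 1) / 2,
                       pair_angles=angles,
                       antiparallel_fraction=antiparallel_fraction(angles))


def end_to_end(frame: Frame, chain_id: str) -> float:
    """Distance between the mass-weighted centers of residues 2 and 9 (A)."""
    out = []
    for resid in _VECTOR_RESIDUES:
        mask = (frame.chains == chain_id) & (frame.resids == resid)
        if not mask.any():
            raise ValueError(f"chain {chain_id} has no residue {resid}")
        m = frame.masses[mask]
        out.append((frame.coords[mask] * m[:, None]).sum(axis=0) / m.sum())
    return float(np.linalg.norm(frame.displacement(out[0], out[1])))


def radius_of_gyration(frame: Frame, selection=None) -> float:
    """Mass-weighted radius of gyration of a selection (default: all atoms)."""
    if selection is None:
        idx = np.arange(frame.n_atoms)
    elif isinstance(selection, str):
        idx = frame.select(selection)
    else:
        idx = np.asarray(selection)
    if len(idx) == 0:
        raise ValueError("empty selection for radius of gyration")
    m = frame.masses[idx]
    x = frame.coords[idx]
    com = (x * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def find_assemblies(frame: Frame,
                    contact_cutoff: float = DEFAULT_ADJACENCY_CUTOFF
                    ) -> list[list[str]]:
    """Partition solute chains into connected assemblies.

    Edges join chain pairs whose minimum heavy-atom distance is at most
    ``contact_cutoff``; assemblies are the connected components, sorted
    largest-first (ties by first chain id). Components of size one are
    chains in solution.
    """
    ids, pairs = _chain_min_distances(frame, contact_cutoff)
    if not ids:
        return []
    pos = {c: k for k, c in enumerate(ids)}
    n = len(ids)
    if pairs:
        rows = [pos[a] for a, b in pairs] + [pos[b] for a, b in pairs]
        cols = [pos[b] for a, b in pairs] + [pos[a] for a, b in pairs]
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    comps = [[] for _ in range(n_comp)]
    for c, lab in zip(ids, labels):
        comps[lab].append(c)
    return sorted(comps, key=lambda c: (-len(c), c[0]))
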