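"""Solvent-accessible surface area and percent solvent exposure.

Two SASA backends are provided:

* :func:`sasa_shrake_rupley` — numerical quadrature: a deterministic
  golden-spiral point set on each atom's probe-expanded sphere, points
  occluded by any neighboring expanded sphere are removed. This is the
  reference method; accuracy improves with the point count.
* :func:`sasa_lcpo` — the analytical linear-combination-of-pairwise-overlaps
  approximation, a weighted sum of an atom's isolated-sphere area, its
  pairwise overlap areas with neighbors, the overlaps among those neighbors,
  and a mixed term, with published per-type weights (bundled data table
  keyed by element, bonded-heavy-atom count and hybridization). Hydrogens
  carry zero area; heavy-atom radii absorb them implicitly.

Percent solvent exposure of a chain is 100 x SASA(chain, computed in the
full solute context) / SASA(same chain extracted alone, same conformation).
Waters are excluded from all contexts by default, and SASA is computed
without periodic images (a fibril is treated as a cluster in open solvent).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, VDW_RADII

DEFAULT_PROBE = 1.4
DEFAULT_SPHERE_POINTS = 960

#: atom names treated as sp2 for LCPO typing (carbonyl group)
SP2_NAMES = frozenset({"C7", "O7"})
#: heavy-heavy distance below which two atoms count as covalently bonded
BOND_CUTOFF = 1.8


@dataclass(frozen=True)
class RadiiSet:
    """Van der Waals radii (A) by element plus the probe radius."""

    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    probe_radius: float = DEFAULT_PROBE

    def radius(self, element: str) -> float:
        try:
            r = self.radii[element]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {element!r}")
        if r <= 0:
            raise ValueError(f"non-positive radius for element {element!r}")
        return r


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa_shrake_rupley(frame: Frame, radii: RadiiSet = RadiiSet(),
                       n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                       include_hydrogens: bool = True) -> np.ndarray:
    """Per-atom accessible areas (A^2) by spherical quadrature.

    Each atom's sphere of radius r_i + probe carries ``n_sphere_points`` test
    points; the accessible fraction times the sphere area is the atom's SASA.
    With ``include_hydrogens=False`` hydrogens neither carry nor occlude
    area (the convention used by the analytical method).
    """
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60")
    if include_hydrogens:
        idx = np.arange(frame.n_atoms)
    else:
        idx = np.flatnonzero(frame.is_heavy)
    areas = np.zeros(frame.n_atoms)
    if not len(idx):
        return areas
    coords = frame.coords[idx]
    expanded = np.array([radii.radius(e) for e in frame.elements[idx]]) \
        + radii.probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    rmax = expanded.max()
    for a in range(len(idx)):
        neighbors = tree.query_ball_point(coords[a], expanded[a] + rmax)
        neighbors = [b for b in neighbors if b != a
                     and np.linalg.norm(coords[b] - coords[a])
                     < expanded[a] + expanded[b]]
        pts = coords[a] + expanded[a] * unit
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[idx[a]] = frac * 4.0 * np.pi * expanded[a] ** 2
    return areas


def _heavy_neighbor_counts(frame: Frame, heavy_idx: np.ndarray) -> np.ndarray:
    """Number of covalently bonded heavy atoms per heavy atom (distance rule)."""
    tree = cKDTree(frame.coords[heavy_idx])
    counts = np.zeros(len(heavy_idx), dtype=int)
    for i, j in tree.query_pairs(BOND_CUTOFF):
        counts[i] += 1
        counts[j] += 1
    return counts


def _load_lcpo_table() -> dict:
    raw = (resources.files("chitosim") / "data" / "lcpo_params.csv").read_text()
    table = {}
    for row in csv.DictReader(r for r in raw.splitlines() if not r.startswith("#")):
        key = (row["element"], int(row["n_heavy"]), row["hybrid"])
        table[key] = (float(row["radius"]),
                      tuple(float(row[f"P{k}"]) for k in range(1, 5)))
    return table


_lcpo_cache: dict = {}


def lcpo_parameters() -> dict:
    if "table" not in _lcpo_cache:
        _lcpo_cache["table"] = _load_lcpo_table()
    return _lcpo_cache["table"]


def _pair_overlap(ri: float, rj: float, d: float) -> float:
    """Area of sphere i buried inside sphere j (both probe-expanded)."""
    return 2.0 * np.pi * ri * (ri - d / 2.0 - (ri * ri - rj * rj) / (2.0 * d))


def sasa_lcpo(frame: Frame, probe_radius: float = DEFAULT_PROBE) -> np.ndarray:
    """Per-atom accessible areas (A^2) by the pairwise-overlap approximation.

    Heavy atoms only; hydrogens are assigned zero area. Atom types (and thus
    the P1..P4 weights and radius) derive from the element, the number of
    bonded heavy atoms, and carbonyl (sp2) flags on C7/O7.
    """
    params = lcpo_parameters()
    heavy_idx = np.flatnonzero(frame.is_heavy)
    areas = np.zeros(frame.n_atoms)
    if not len(heavy_idx):
        return areas
    counts = _heavy_neighbor_counts(frame, heavy_idx)
    radii = np.empty(len(heavy_idx))
    pvals = np.empty((len(heavy_idx), 4))
    for k, (gi, nb) in enumerate(zip(heavy_idx, counts)):
        name = str(frame.names[gi])
        hyb = "sp2" if name in SP2_NAMES else "sp3"
        key = (str(frame.elements[gi]), int(nb), hyb)
        if key not in params:
            raise KeyError(
                f"no LCPO parameters for atom {name} ({key[0]}, {key[1]} bonded "
                f"heavy neighbors, {hyb})")
        radii[k], pvals[k] = params[key][0] + probe_radius, params[key][1]
    coords = frame.coords[heavy_idx]
    tree = cKDTree(coords)
    neighbor_lists: list[np.ndarray] = []
    for i in range(len(heavy_idx)):
        nb = tree.query_ball_point(coords[i], radii[i] + radii.max())
        nb = np.array([j for j in nb if j != i
                       and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]],
                      dtype=int)
        neighbor_lists.append(nb)

    def aij(i: int, j: int) -> float:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        return _pair_overlap(radii[i], radii[j], d)

    for i in range(len(heavy_idx)):
        p1, p2, p3, p4 = pvals[i]
        s1 = 4.0 * np.pi * radii[i] ** 2
        nb_i = neighbor_lists[i]
        sum_aij = 0.0
        sum_ajk = 0.0
        sum_mixed = 0.0
        set_i = set(nb_i.tolist())
        for j in nb_i:
            a_ij = aij(i, j)
            sum_aij += a_ij
            shared = [k for k in neighbor_lists[j] if k in set_i]
            s_jk = sum(aij(j, k) for k in shared)
            sum_ajk += s_jk
            sum_mixed += a_ij * s_jk
        areas[heavy_idx[i]] = max(0.0, p1 * s1 + p2 * sum_aij
                                  + p3 * sum_ajk + p4 * sum_mixed)
    return areas


def chain_sasa(frame: Frame, chain_id: str, method: str = "shrake_rupley",
               radii: RadiiSet = RadiiSet(),
               n_sphere_points: int = DEFAULT_SPHERE_POINTS,
               include_waters: bool = False, in_context: bool = True) -> float:
    """Total SASA (A^2) of one chain, in context or extracted alone."""
    keep = np.ones(frame.n_atoms, bool) if include_waters else ~frame.is_water
    context = frame.subset(keep) if not keep.all() else frame
    if not in_context:
        context = context.subset(context.chains == chain_id)
    if method == "shrake_rupley":
        areas = sasa_shrake_rupley(context, radii, n_sphere_points)
    elif method == "lcpo":
        areas = sasa_lcpo(context, probe_radius=radii.probe_radius)
    else:
        raise ValueError(f"unknown SASA method {method!r}")
    mask = context.chains == chain_id
    if not mask.any():
        raise ValueError(f"chain {chain_id!r} not present")
    return float(areas[mask].sum())


def per_chain_exposure(frame: Frame, method: str = "shrake_rupley",
                       radii: RadiiSet = RadiiSet(),
                       n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                       include_waters: bool = False) -> dict[str, float]:
    """Percent solvent exposure for every solute chain of a frame.

    Equivalent to calling :func:`percent_exposure` per chain but the full
    solute context is evaluated only once.
    """
    keep = np.ones(frame.n_atoms, bool) if include_waters else ~frame.is_water
    context = frame.subset(keep) if not keep.all() else frame
    if method == "shrake_rupley":
        areas = sasa_shrake_rupley(context, radii, n_sphere_points)
    elif method == "lcpo":
        areas = sasa_lcpo(context, probe_radius=radii.probe_radius)
    else:
        raise ValueError(f"unknown SASA method {method!r}")
    out = {}
    for cid in context.chain_ids():
        mask = context.chains == cid
        alone = context.subset(mask)
        if method == "shrake_rupley":
            ref = sasa_shrake_rupley(alone, radii, n_sphere_points).sum()
        else:
            ref = sasa_lcpo(alone, probe_radius=radii.probe_radius).sum()
        out[cid] = 100.0 * float(areas[mask].sum()) / float(ref)
    return out


def percent_exposure(frame: Frame, chain_id: str,
                     method: str = "shrake_rupley",
                     radii: RadiiSet = RadiiSet(),
                     n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                     include_waters: bool = False) -> float:
    """Percent solvent exposure of a chain relative to its fully solvated self.

    100 x SASA(chain atoms within the full solute context) / SASA(the same
    chain extracted alone in the same conformation). An isolated chain scores
    exactly 100; burial in an assembly lowers the value.
    """
    in_ctx = chain_sasa(frame, chain_id, method, radii, n_sphere_points,
                        include_waters, in_context=True)
    alone = chain_sasa(frame, chain_id, method, radii, n_sphere_points,
                       include_waters, in_context=False)
    return 100.0 * in_ctx / alone
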