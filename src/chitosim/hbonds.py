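"""Geometric hydrogen-bond detection, classification and occupancy.

A hydrogen bond is recorded when a donor heavy atom D (N or O carrying at
least one bonded hydrogen) and an acceptor A (any O, or a free-amine N with
two or more bonded hydrogens; amide nitrogens do not accept) satisfy

    |D - A| <= heavy_distance_cutoff   and   angle(D-H...A) >= dha_angle_min

with minimum-image distances when the frame has a box. Donor and acceptor in
the same residue are never paired. Hydrogens are assigned to the nearest
heavy atom within 1.2 A.

Events are classified three ways:

* ``type_label`` from the donor-heavy and acceptor atom names, e.g.
  ``"O6H-O7"``, ``"NH-O6"``, ``"O3H-O7"``; water donors give
  ``"water-<acceptor>"`` and water acceptors ``"<donor>H-water"``.
* ``pair_class`` from the two residues' acetylation: ``NAc-NAc``, ``NAc-N``,
  ``N-N`` (NAc = N-acetylglucosamine, N = glucosamine), or ``water-solute``.
* ``scope``: ``intrachain``, ``interchain`` or ``chain-water``.

Occupancies follow the convention of averaging the per-frame event count
over all solute monomers (10 monomers x 24 chains = 240 by default) and
then over frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Frame, Trajectory, wrap_coords

H_BOND_TO_HEAVY = 1.2  # hydrogen-to-parent assignment radius, A


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: heavy-atom D..A cutoff (A) and minimum D-H..A angle
    (degrees). Defaults follow common trajectory-analysis practice."""

    heavy_distance_cutoff: float = 3.0
    dha_angle_min: float = 135.0

    def __post_init__(self):
        if self.heavy_distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.dha_angle_min <= 180.0:
            raise ValueError("angle minimum must be in (0, 180]")


@dataclass(frozen=True)
class HBondEvent:
    donor: int      # atom indices into the frame
    hydrogen: int
    acceptor: int
    type_label: str
    pair_class: str
    scope: str


def assign_hydrogens(frame: Frame) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of its bonded hydrogens.

    A hydrogen bonds to the nearest heavy atom within 1.2 A; hydrogens with
    no heavy atom in range are ignored.
    """
    heavy_idx = np.flatnonzero(frame.is_heavy)
    h_idx = np.flatnonzero(~frame.is_heavy)
    out: dict[int, list[int]] = {}
    if not len(h_idx) or not len(heavy_idx):
        return out
    if frame.box is not None:
        tree = cKDTree(wrap_coords(frame.coords[heavy_idx], frame.box),
                       boxsize=frame.box)
        d, j = tree.query(wrap_coords(frame.coords[h_idx], frame.box), k=1)
    else:
        tree = cKDTree(frame.coords[heavy_idx])
        d, j = tree.query(frame.coords[h_idx], k=1)
    for h, dist, jj in zip(h_idx, d, j):
        if dist <= H_BOND_TO_HEAVY:
            out.setdefault(int(heavy_idx[jj]), []).append(int(h))
    return out


def _label_parts(frame: Frame, donor: int, acceptor: int):
    d_water = bool(frame.is_water[donor])
    a_water = bool(frame.is_water[acceptor])
    dname, aname = str(frame.names[donor]), str(frame.names[acceptor])
    if d_water and a_water:
        type_label = "water-water"
    elif d_water:
        type_label = f"water-{aname}"
    elif a_water:
        type_label = f"{dname}H-water"
    else:
        type_label = f"{dname}H-{aname}"
    if d_water or a_water:
        pair_class = "water-water" if (d_water and a_water) else "water-solute"
        scope = "water-water" if (d_water and a_water) else "chain-water"
    else:
        kinds = {"NAG": "NAc", "GCS": "N"}
        ka = kinds.get(str(frame.resnames[donor]), "other")
        kb = kinds.get(str(frame.resnames[acceptor]), "other")
        pair_class = "-".join(sorted((ka, kb), reverse=True))  # NAc before N
        scope = ("intrachain" if frame.chains[donor] == frame.chains[acceptor]
                 else "interchain")
    return type_label, pair_class, scope


def classify(frame: Frame, donor: int, hydrogen: int, acceptor: int) -> HBondEvent:
    """Build a classified event from donor/hydrogen/acceptor atom indices."""
    type_label, pair_class, scope = _label_parts(frame, donor, acceptor)
    return HBondEvent(donor, hydrogen, acceptor, type_label, pair_class, scope)


def detect_hbonds(frame: Frame, criteria: HBondCriteria = HBondCriteria(),
                  donor_selection: str | None = None,
                  acceptor_selection: str | None = None) -> list[HBondEvent]:
    """All hydrogen bonds in a frame under the given geometric criteria.

    Donors default to every N/O with a bonded hydrogen; acceptors to every
    N/O. Selections restrict the candidate heavy atoms.
    """
    h_map = assign_hydrogens(frame)
    no_mask = np.isin(frame.elements, ("N", "O"))
    don_mask = no_mask.copy()
    # acceptors: any O, and N only as a free amine (>= 2 bonded hydrogens);
    # an amide nitrogen's lone pair is delocalized and does not accept
    acc_mask = frame.elements == "O"
    for i in np.flatnonzero(frame.elements == "N"):
        if len(h_map.get(int(i), ())) >= 2:
            acc_mask[i] = True
    if donor_selection is not None:
        m = np.zeros(frame.n_atoms, bool)
        m[frame.select(donor_selection)] = True
        don_mask &= m
    if acceptor_selection is not None:
        m = np.zeros(frame.n_atoms, bool)
        m[frame.select(acceptor_selection)] = True
        acc_mask &= m
    donors = np.array([i for i in np.flatnonzero(don_mask) if i in h_map],
                      dtype=int)
    acceptors = np.flatnonzero(acc_mask)
    if not len(donors) or not len(acceptors):
        return []
    box = frame.box
    if box is not None:
        dtree = cKDTree(wrap_coords(frame.coords[donors], box), boxsize=box)
        atree = cKDTree(wrap_coords(frame.coords[acceptors], box), boxsize=box)
    else:
        dtree = cKDTree(frame.coords[donors])
        atree = cKDTree(frame.coords[acceptors])
    hits = dtree.query_ball_tree(atree, criteria.heavy_distance_cutoff)
    cos_min = np.cos(np.deg2rad(criteria.dha_angle_min))
    events: list[HBondEvent] = []
    for di, acc_list in zip(donors, hits):
        if not acc_list:
            continue
        for aj in acc_list:
            ai = int(acceptors[aj])
            if ai == di:
                continue
            if (frame.chains[di] == frame.chains[ai]
                    and frame.resids[di] == frame.resids[ai]):
                continue  # same residue
            for h in h_map[int(di)]:
                u = frame.displacement(frame.coords[h], frame.coords[di])
                v = frame.displacement(frame.coords[h], frame.coords[ai])
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                # D-H...A angle >= minimum <=> cos(angle) <= cos(minimum)
                if cosang <= cos_min + 1e-12:
                    events.append(classify(frame, int(di), int(h), ai))
    return events


def interchain_hbonds_per_monomer(frame: Frame,
                                  criteria: HBondCriteria = HBondCriteria(),
                                  n_monomers: int | None = None) -> float:
    """Interchain hydrogen bonds divided by the solute monomer count."""
    if n_monomers is None:
        n_monomers = count_solute_monomers(frame)
    if n_monomers == 0:
        return 0.0
    events = detect_hbonds(frame, criteria)
    n = sum(e.scope == "interchain" for e in events)
    return n / n_monomers


def count_solute_monomers(frame: Frame) -> int:
    solute = ~frame.is_water
    pairs = {(c, r) for c, r in zip(frame.chains[solute], frame.resids[solute])}
    return len(pairs)


def bridging_waters(frame: Frame,
                    criteria: HBondCriteria = HBondCriteria()) -> int:
    """Waters hydrogen-bonded (either direction) to two or more chains.

    Operationalizes water-mediated sheet-sheet interactions: a water counts
    when it donates to or accepts from solute atoms of at least two distinct
    chains in the same frame.
    """
    events = detect_hbonds(frame, criteria)
    partners: dict[tuple[str, int], set[str]] = {}
    for e in events:
        dw, aw = frame.is_water[e.donor], frame.is_water[e.acceptor]
        if dw and not aw:
            key = (str(frame.chains[e.donor]), int(frame.resids[e.donor]))
            partners.setdefault(key, set()).add(str(frame.chains[e.acceptor]))
        elif aw and not dw:
            key = (str(frame.chains[e.acceptor]), int(frame.resids[e.acceptor]))
            partners.setdefault(key, set()).add(str(frame.chains[e.donor]))
    return sum(len(chains) >= 2 for chains in partners.values())


@dataclass
class OccupancyTable:
    """Mean per-monomer occupancy by (type_label, pair_class, scope)."""

    table: pd.DataFrame  # columns: type_label, pair_class, scope, occupancy, n_events
    n_frames: int
    n_monomers: int

    def pair_class_percentages(self, type_label: str,
                               scope: str = "interchain") -> pd.Series:
        """Percentage of events of one h-bond type per acetylation pair class.

        Mirrors the breakdown of an h-bond type into NAc-NAc / NAc-N / N-N
        contributions; percentages sum to 100 when any events exist.
        """
        t = self.table
        sel = t[(t.type_label == type_label) & (t.scope == scope)]
        total = sel.n_events.sum()
        if total == 0:
            return pd.Series(dtype=float)
        return (sel.set_index("pair_class").n_events / total * 100.0)

    def to_csv(self, path: str) -> None:
        out = self.table.copy()
        out["n_frames"] = self.n_frames
        out.to_csv(path, index=False)


def occupancy_table(traj: Trajectory, criteria: HBondCriteria = HBondCriteria(),
                    last_n_frames: int | None = None,
                    n_monomers: int | None = None) -> OccupancyTable:
    """Aggregate per-monomer h-bond occupancies over (the last n) frames.

    For each frame, events of each (type_label, pair_class, scope) are
    counted and divided by the solute monomer count; occupancies are the
    average of this per-frame quantity over frames.
    """
    if last_n_frames is None:
        last_n_frames = len(traj)
    if last_n_frames < 1 or last_n_frames > len(traj):
        raise ValueError(f"last_n_frames must be in [1, {len(traj)}]")
    frames = traj.frames[-last_n_frames:]
    if n_monomers is None:
        n_monomers = count_solute_monomers(frames[0])
    counts: dict[tuple[str, str, str], int] = {}
    for frame in frames:
        for e in detect_hbonds(frame, criteria):
            key = (e.type_label, e.pair_class, e.scope)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"type_label": k[0], "pair_class": k[1], "scope": k[2],
         "occupancy": n / n_monomers / len(frames), "n_events": n}
        for k, n in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["type_label", "pair_class", "scope",
                                        "occupancy", "n_events"])
    return OccupancyTable(table, n_frames=len(frames), n_monomers=n_monomers)
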