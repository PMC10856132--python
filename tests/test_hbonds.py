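"""Hydrogen-bond detection vs brute force, classification, occupancies."""

import numpy as np
import pytest

from chitosim import Frame, Trajectory, build_chain, make_sequence
from chitosim.core import concatenate
from chitosim.hbonds import (HBondCriteria, bridging_waters, detect_hbonds,
                             interchain_hbonds_per_monomer, occupancy_table)

from conftest import random_no_frame


def brute_force_hbonds(frame, criteria):
    """O(n^2) reference detector: all donor/H/acceptor triples checked
    directly against the distance and angle criteria."""
    events = set()
    n = frame.n_atoms
    heavies = [i for i in range(n) if frame.elements[i] != "H"]
    # hydrogen -> nearest heavy within 1.2 A
    h_parent = {}
    for h in range(n):
        if frame.elements[h] != "H":
            continue
        best, bd = None, 1.2
        for j in heavies:
            d = frame.distance(h, j)
            if d <= bd:
                best, bd = j, d
        if best is not None:
            h_parent[h] = best
    n_h_on = {}
    for h, par in h_parent.items():
        n_h_on[par] = n_h_on.get(par, 0) + 1
    def accepts(a):
        return frame.elements[a] == "O" or (frame.elements[a] == "N"
                                            and n_h_on.get(a, 0) >= 2)
    cos_min = np.cos(np.deg2rad(criteria.dha_angle_min))
    for h, d_heavy in h_parent.items():
        if frame.elements[d_heavy] not in ("N", "O"):
            continue
        for a in range(n):
            if not accepts(a) or a == d_heavy:
                continue
            if (frame.chains[a] == frame.chains[d_heavy]
                    and frame.resids[a] == frame.resids[d_heavy]):
                continue
            if frame.distance(d_heavy, a) > criteria.heavy_distance_cutoff:
                continue
            u = frame.displacement(frame.coords[h], frame.coords[d_heavy])
            v = frame.displacement(frame.coords[h], frame.coords[a])
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            if cosang <= cos_min + 1e-12:
                events.add((d_heavy, h, a))
    return events


def constructed_pair(d_da=2.8, angle_deg=170.0):
    """One O6-H donor aimed at an O7 acceptor with prescribed geometry."""
    o6 = np.array([0.0, 0.0, 0.0])
    h = np.array([0.96, 0.0, 0.0])
    # acceptor placed so that the D-H...A angle is angle_deg at distance d_da
    theta = np.deg2rad(180.0 - angle_deg)
    # direction from H making (180 - angle) with the H->D vector
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # find acceptor along `direction` from H at donor-acceptor distance d_da
    t = np.roots([1.0, 2 * np.dot(h - o6, direction),
                  np.dot(h - o6, h - o6) - d_da ** 2])
    acc = h + max(t.real) * direction
    names = ["O6", "HO6", "O7"]
    return Frame(names, ["GCS", "GCS", "NAG"], [1, 1, 2], ["A", "A", "B"],
                 np.array([o6, h, acc]), elements=["O", "H", "O"])


class TestDetection:
    def test_constructed_geometry_detected(self):
        f = constructed_pair(2.8, 170.0)
        events = detect_hbonds(f)
        assert len(events) == 1
        e = events[0]
        assert e.type_label == "O6H-O7"
        assert e.pair_class == "NAc-N"
        assert e.scope == "interchain"

    def test_outside_distance_cutoff(self):
        assert detect_hbonds(constructed_pair(3.6, 170.0)) == []

    def test_outside_angle_cutoff(self):
        assert detect_hbonds(constructed_pair(2.8, 110.0)) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_random_frames(self, seed):
        f = random_no_frame(60, seed)
        crit = HBondCriteria()
        fast = {(e.donor, e.hydrogen, e.acceptor) for e in detect_hbonds(f, crit)}
        assert fast == brute_force_hbonds(f, crit)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_brute_force_periodic(self, seed):
        f = random_no_frame(50, seed, box=(13.0, 13.0, 13.0), spread=13.0)
        crit = HBondCriteria(3.2, 120.0)
        fast = {(e.donor, e.hydrogen, e.acceptor) for e in detect_hbonds(f, crit)}
        assert fast == brute_force_hbonds(f, crit)

    @pytest.mark.parametrize("seed", range(4))
    def test_tightening_criteria_monotone(self, seed):
        f = random_no_frame(80, seed)
        loose = detect_hbonds(f, HBondCriteria(3.5, 120.0))
        tight_d = detect_hbonds(f, HBondCriteria(3.0, 120.0))
        tight_a = detect_hbonds(f, HBondCriteria(3.5, 150.0))
        assert len(tight_d) <= len(loose)
        assert len(tight_a) <= len(loose)
        keys = lambda evs: {(e.donor, e.hydrogen, e.acceptor) for e in evs}
        assert keys(tight_d) <= keys(loose)
        assert keys(tight_a) <= keys(loose)

    def test_rigid_motion_invariance(self, antiparallel_fibril):
        from scipy.spatial.transform import Rotation
        f = antiparallel_fibril
        g = f.copy()
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        g.coords = f.coords @ rot.T + np.array([11.0, -3.0, 7.0])
        n_f = interchain_hbonds_per_monomer(f)
        n_g = interchain_hbonds_per_monomer(g)
        assert n_f == pytest.approx(n_g)
        assert n_f > 0

    def test_atom_order_permutation_invariance(self, block_seq):
        f = concatenate([build_chain(block_seq, chain_id="A"),
                         build_chain(block_seq, origin=(0, 9.0, 1.9),
                                     flip=True, chain_id="B")])
        rng = np.random.default_rng(0)
        perm = rng.permutation(f.n_atoms)
        g = f.subset(perm)
        tab_f = occupancy_table(Trajectory([f]))
        tab_g = occupancy_table(Trajectory([g]))
        assert tab_f.table.equals(tab_g.table)


class TestClassification:
    def test_water_donating_to_amine_nitrogen(self):
        # water O-H aimed at a free amine (NH2) nitrogen of GlcN
        coords = np.array([
            [0.0, 0.0, 0.0],     # water O
            [0.96, 0.0, 0.0],    # water H1
            [-0.24, 0.93, 0.0],  # water H2
            [2.85, 0.0, 0.0],    # N acceptor (amine)
            [3.35, 0.87, 0.0],   # HN1
            [3.35, -0.87, 0.0],  # HN2
        ])
        f = Frame(["O", "H1", "H2", "N", "HN1", "HN2"],
                  ["HOH", "HOH", "HOH", "GCS", "GCS", "GCS"],
                  [1, 1, 1, 2, 2, 2], ["W", "W", "W", "A", "A", "A"], coords,
                  elements=["O", "H", "H", "N", "H", "H"])
        events = [e for e in detect_hbonds(f) if e.type_label == "water-N"]
        assert len(events) == 1
        assert events[0].pair_class == "water-solute"
        assert events[0].scope == "chain-water"

    def test_amide_nitrogen_does_not_accept(self):
        # same geometry but the nitrogen bears a single hydrogen (amide-like):
        # it must not be reported as an acceptor
        coords = np.array([
            [0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0],
            [2.85, 0.0, 0.0], [3.35, 0.87, 0.0],
        ])
        f = Frame(["O", "H1", "H2", "N", "HN1"],
                  ["HOH", "HOH", "HOH", "NAG", "NAG"],
                  [1, 1, 1, 2, 2], ["W", "W", "W", "A", "A"], coords,
                  elements=["O", "H", "H", "N", "H"])
        assert [e for e in detect_hbonds(f) if e.type_label == "water-N"] == []

    def test_intrachain_scope(self):
        f = constructed_pair(2.8, 170.0)
        g = Frame(f.names, f.resnames, f.resids, ["A", "A", "A"], f.coords,
                  elements=f.elements)
        assert detect_hbonds(g)[0].scope == "intrachain"

    def test_nn_pair_class(self):
        f = constructed_pair(2.8, 170.0)
        g = Frame(f.names, ["GCS"] * 3, f.resids, f.chains, f.coords,
                  elements=f.elements)
        assert detect_hbonds(g)[0].pair_class == "N-N"


class TestOccupancy:
    def test_known_event_count_bookkeeping(self, block_seq):
        # two-chain frame with a known interchain h-bond count, replicated
        f = concatenate([build_chain(block_seq, chain_id="A"),
                         build_chain(block_seq, origin=(0, 9.0, 1.9),
                                     flip=True, chain_id="B")])
        n_events = len([e for e in detect_hbonds(f) if e.scope == "interchain"])
        assert n_events > 0
        traj = Trajectory([f.copy() for _ in range(4)])
        table = occupancy_table(traj)
        inter = table.table[table.table.scope == "interchain"]
        # 20 monomers; occupancy sums to n_events / 20, exactly, every frame
        assert inter.occupancy.sum() == pytest.approx(n_events / 20.0)
        assert table.n_frames == 4

    def test_hand_counted_fixture(self):
        # one O6H-O7 pair per frame over 3 frames, 2 monomers total
        f = constructed_pair(2.8, 170.0)
        table = occupancy_table(Trajectory([f.copy() for _ in range(3)]))
        assert len(table.table) == 1
        assert table.table.occupancy.iloc[0] == pytest.approx(1 / 2.0)

    def test_no_events_gives_empty_table(self):
        f = constructed_pair(3.6, 170.0)
        table = occupancy_table(Trajectory([f]))
        assert len(table.table) == 0
        assert table.pair_class_percentages("O6H-O7").empty

    def test_pair_class_percentages_sum_to_100(self, antiparallel_fibril):
        table = occupancy_table(Trajectory([antiparallel_fibril]))
        pct = table.pair_class_percentages("O3H-O6")
        assert pct.sum() == pytest.approx(100.0)

    def test_last_n_frames_selects_tail(self, block_seq):
        quiet = build_chain(block_seq)  # single chain: no interchain events
        busy = concatenate([build_chain(block_seq, chain_id="A"),
                            build_chain(block_seq, origin=(0, 9.0, 1.9),
                                        flip=True, chain_id="B")])
        quiet2 = concatenate([build_chain(block_seq, chain_id="A"),
                              build_chain(block_seq, origin=(0, 40.0, 0),
                                          chain_id="B")])
        traj = Trajectory([quiet2, busy])
        full = occupancy_table(traj)
        tail = occupancy_table(traj, last_n_frames=1)
        inter_full = full.table[full.table.scope == "interchain"]
        inter_tail = tail.table[tail.table.scope == "interchain"]
        assert inter_tail.occupancy.sum() == pytest.approx(
            2 * inter_full.occupancy.sum())


class TestDerivedMeasures:
    def test_dispersed_frame_has_zero(self, dispersed_frame):
        assert interchain_hbonds_per_monomer(dispersed_frame) == 0.0

    def test_hand_built_ratio(self):
        # single interchain bond, 2 monomers -> 0.5 per monomer
        f = constructed_pair(2.8, 170.0)
        assert interchain_hbonds_per_monomer(f) == pytest.approx(0.5)

    def test_bridging_water_counted(self):
        # one water donating to chain A and accepting from chain B
        coords = np.array([
            [0.0, 0.0, 0.0],      # water O
            [0.96, 0.0, 0.0],     # water H1 -> toward O3 of chain A
            [-0.24, 0.93, 0.0],   # water H2
            [2.85, 0.0, 0.0],     # O3 chain A (acceptor)
            [-2.80, 0.0, 0.0],    # O6 chain B (donor)
            [-1.84, 0.0, 0.0],    # HO6 chain B aimed at water O
        ])
        f = Frame(["O", "H1", "H2", "O3", "O6", "HO6"],
                  ["HOH", "HOH", "HOH", "GCS", "GCS", "GCS"],
                  [1, 1, 1, 2, 3, 3], ["W", "W", "W", "A", "B", "B"],
                  coords, elements=["O", "H", "H", "O", "O", "H"])
        assert bridging_waters(f) == 1
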