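"""Order metrics: chain vectors, P2, pair angles, Rg, assemblies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chitosim import Frame, build_chain, build_fibril, make_sequence
from chitosim.core import concatenate
from chitosim.order import (antiparallel_fraction, chain_vector,
                            director_and_p2, end_to_end, find_assemblies,
                            p2_order, pair_angles, radius_of_gyration)


class TestChainVector:
    def test_straight_chain_along_z(self, single_chain):
        v = chain_vector(single_chain, "A").v
        assert np.allclose(v, [0, 0, 1], atol=1e-12)

    def test_flipped_chain(self, block_seq):
        f = build_chain(block_seq, flip=True)
        assert np.allclose(chain_vector(f, "A").v, [0, 0, -1], atol=1e-12)

    def test_noisy_chain_within_two_degrees(self, block_seq):
        rng = np.random.default_rng(3)
        f = build_chain(block_seq)
        f.coords = f.coords + rng.normal(0, 0.1, f.coords.shape)
        v = chain_vector(f, "A").v
        angle = np.degrees(np.arccos(np.clip(v @ [0, 0, 1], -1, 1)))
        assert angle < 2.0

    def test_short_chain_rejected(self):
        seq = make_sequence(6, 0.5, "block")
        f = build_chain(seq)
        with pytest.raises(ValueError, match="chain A"):
            chain_vector(f, "A")


class TestP2:
    def test_aligned_is_exactly_one(self, antiparallel_fibril, parallel_fibril):
        for frame in (antiparallel_fibril, parallel_fibril):
            p2, d = p2_order(frame)
            assert p2 == pytest.approx(1.0, abs=1e-12)
            assert abs(d @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_limit_and_mc_oracle(self):
        rng = np.random.default_rng(12345)
        v = rng.normal(size=(10_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        p2, d = director_and_p2(v)
        # oracle: direct Monte-Carlo average of (v.d)^2 with the same director
        assert p2 == pytest.approx(float(np.mean((v @ d) ** 2)), abs=1e-12)
        # unbiased fixed-axis projection hits 1/3 within 3 standard errors
        se = np.sqrt((1 / 5 - 1 / 9) / len(v))
        fixed = float(np.mean((v @ [0, 0, 1.0]) ** 2))
        assert abs(fixed - 1 / 3) < 3 * se
        # fitted director adds an O(N^-1/2) selection bias: allow twice that
        assert abs(p2 - 1 / 3) < 6 * se

    def test_unsigned_orientation_invariance(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(40, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        p2, _ = director_and_p2(v)
        flips = np.where(rng.random(40) < 0.5, -1.0, 1.0)[:, None]
        p2_flipped, _ = director_and_p2(v * flips)
        assert p2 == pytest.approx(p2_flipped, abs=1e-12)
        rot = Rotation.from_euler("zyx", [10, 70, -30], degrees=True).as_matrix()
        p2_rot, _ = director_and_p2(v @ rot.T)
        assert p2 == pytest.approx(p2_rot, abs=1e-10)
        perm = rng.permutation(40)
        p2_perm, _ = director_and_p2(v[perm])
        assert p2 == pytest.approx(p2_perm, abs=1e-12)


class TestPairAngles:
    def test_antiparallel_fibril(self, antiparallel_fibril):
        angles = pair_angles(antiparallel_fibril)
        assert len(angles) > 0
        assert all(a == pytest.approx(180.0, abs=1e-6) for _, _, a in angles)
        assert antiparallel_fraction(angles) == 1.0

    def test_parallel_fibril(self, parallel_fibril):
        angles = pair_angles(parallel_fibril)
        assert all(a == pytest.approx(0.0, abs=1e-6) for _, _, a in angles)
        assert antiparallel_fraction(angles) == 0.0

    def test_dispersed_frame_empty(self, dispersed_frame):
        assert pair_angles(dispersed_frame, 4.5) == []
        assert np.isnan(antiparallel_fraction([]))

    def test_fraction_partition(self, block_seq):
        # mixed fibril: one parallel pair, one antiparallel pair
        a = build_chain(block_seq, chain_id="A")
        b = build_chain(block_seq, origin=(0, 9.0, 0), chain_id="B")
        c = build_chain(block_seq, origin=(0, 18.0, 1.9), flip=True,
                        chain_id="C")
        angles = pair_angles(concatenate([a, b, c]))
        frac = antiparallel_fraction(angles)
        parallel_frac = np.mean([ang <= 90 for _, _, ang in angles])
        assert frac + parallel_frac == pytest.approx(1.0)


class TestDistances:
    def test_end_to_end_straight(self, single_chain):
        # residues 2 and 9 are 7 rises apart; substituent asymmetry between
        # GlcN and GlcNAc halves shifts the mass-weighted COMs slightly
        assert end_to_end(single_chain, "A") == pytest.approx(7 * 5.2, abs=1.0)

    def test_bent_chain_shorter(self, block_seq, single_chain):
        f = single_chain.copy()
        straight = end_to_end(f, "A")
        upper = f.resids > 5  # bend 90 deg at residue 5
        rot = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        pivot = np.array([0, 0, 5 * 5.2])
        f.coords[upper] = (f.coords[upper] - pivot) @ rot.T + pivot
        assert end_to_end(f, "A") < straight

    def test_rigid_motion_invariance(self, single_chain):
        f = single_chain.copy()
        rot = Rotation.from_euler("zxz", [12, 34, 56], degrees=True).as_matrix()
        f.coords = f.coords @ rot.T + np.array([3.0, -8.0, 2.0])
        assert end_to_end(f, "A") == pytest.approx(
            end_to_end(single_chain, "A"), abs=1e-9)


class TestRadiusOfGyration:
    def test_cube_corners_closed_form(self):
        # 8 unit-mass points at the corners of an edge-2 cube: Rg = sqrt(3)
        corners = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1)
                            for z in (-1, 1)], float)
        f = Frame(["H1"] * 8, ["HOH"] * 8, [1] * 8, ["W"] * 8, corners,
                  elements=["H"] * 8)
        assert radius_of_gyration(f) == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_single_atom_zero(self):
        f = Frame(["O"], ["HOH"], [1], ["W"], [[1.0, 2.0, 3.0]],
                  elements=["O"])
        assert radius_of_gyration(f) == 0.0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(5)
        n = 100
        f = Frame([f"C{i%9}" for i in range(n)], ["GCS"] * n, [1] * n,
                  ["A"] * n, rng.normal(size=(n, 3)) * 5,
                  elements=["C"] * n)
        m = f.masses
        com = (f.coords * m[:, None]).sum(0) / m.sum()
        rg = np.sqrt((m * ((f.coords - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(f) == pytest.approx(rg, abs=1e-10)


class TestAssemblies:
    def test_fibril_plus_two_solution_chains(self, block_seq):
        fib = build_fibril(block_seq, 2, 4)
        far1 = build_chain(block_seq, origin=(60.0, 0, 0), chain_id="X")
        far2 = build_chain(block_seq, origin=(0, 90.0, 0), chain_id="Y")
        frame = concatenate([fib, far1, far2])
        comps = find_assemblies(frame, 4.5)
        assert sorted(len(c) for c in comps) == [1, 1, 8]

    def test_fully_dispersed_singletons(self, dispersed_frame):
        comps = find_assemblies(dispersed_frame, 4.5)
        assert len(comps) == 24
        assert all(len(c) == 1 for c in comps)

    def test_true_partition_and_brute_force(self, block_seq):
        rng = np.random.default_rng(2)
        chains = [build_chain(block_seq, origin=o, chain_id=c)
                  for c, o in zip("ABCDE", rng.uniform(0, 40, (5, 3)))]
        frame = concatenate(chains)
        cutoff = 6.0
        comps = find_assemblies(frame, cutoff)
        ids = sorted(x for comp in comps for x in comp)
        assert ids == ["A", "B", "C", "D", "E"]  # disjoint cover
        # brute-force adjacency -> components via repeated expansion
        heavy = {c: frame.coords[(frame.chains == c) & frame.is_heavy]
                 for c in "ABCDE"}
        adj = {c: set() for c in "ABCDE"}
        for i, ci in enumerate("ABCDE"):
            for cj in "ABCDE"[i + 1:]:
                d = np.linalg.norm(heavy[ci][:, None] - heavy[cj][None], axis=-1)
                if d.min() <= cutoff:
                    adj[ci].add(cj)
                    adj[cj].add(ci)
        seen, expected = set(), []
        for c in "ABCDE":
            if c in seen:
                continue
            stack, comp = [c], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            expected.append(sorted(comp))
        assert sorted(sorted(c) for c in comps) == sorted(expected)
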