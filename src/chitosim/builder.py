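"""Synthetic all-atom configuration builder.

Generates single chitosan chains, ordered nanofibrils (sheets of parallel or
antiparallel chains, optionally off-register), randomly dispersed solution
states, lattice solvation, and interpolated assembly trajectories. These
idealized configurations stand in for molecular-dynamics snapshots: they span
the same order/disorder regimes (fully dispersed through fully fibrillar)
with controllable order, register, arrangement and positional noise, but
carry no energies or dynamics.

Geometry: chains are rigid stacks of residue templates with a two-fold screw
(successive residues rotated 180 deg about the chain axis) and a default rise
of 5.2 A per monomer. Default fibril spacings are chosen so that the
idealized sheets realize interchain hydrogen-bond geometries (donor-acceptor
heavy-atom distances near 2.8-3.0 A); they are template properties, not
measured lattice constants, and are fully configurable.
"""

from __future__ import annotations

import string
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import Frame, KIND_TO_RESNAME, Trajectory, concatenate, wrap_coords
from .sequence import ChitosanSequence
from .templates import load_templates, ring_centroid

DEFAULT_RISE = 5.2
#: lateral spacing between chain axes within a sheet (A); see module docstring
DEFAULT_INTRA_SHEET = 9.0
#: spacing between sheets (ring-stacking direction, A)
DEFAULT_INTER_SHEET = 5.0
#: axial shift of every second chain within a sheet (A); by default chosen
#: per arrangement so facing hydroxyls realize interchain h-bond geometry
REGISTER_BY_ARRANGEMENT = {"parallel": 0.0, "antiparallel": 1.9}

STERIC_MIN_DISTANCE = 1.0

_TWO_FOLD = Rotation.from_euler("z", 180, degrees=True).as_matrix()
_FLIP_Y = Rotation.from_euler("y", 180, degrees=True).as_matrix()


def chain_label(i: int) -> str:
    """Chain id for chain index i: A..Z, then two-character AA, AB, ..."""
    letters = string.ascii_uppercase
    if i < 26:
        return letters[i]
    i -= 26
    if i < 26 * 26:
        return letters[i // 26] + letters[i % 26]
    raise ValueError("more chains than supported chain ids")


def _axis_basis(axis) -> np.ndarray:
    """Deterministic rotation matrix whose third column is the given axis."""
    a = np.asarray(axis, float)
    norm = np.linalg.norm(a)
    if norm < 1e-12:
        raise ValueError("chain axis must be a nonzero vector")
    a = a / norm
    helper = np.array([1.0, 0, 0]) if abs(a[0]) < 0.9 else np.array([0, 1.0, 0])
    u1 = helper - np.dot(helper, a) * a
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(a, u1)
    return np.column_stack([u1, u2, a])


def build_chain(seq: ChitosanSequence, rise_per_monomer: float = DEFAULT_RISE,
                axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0),
                flip: bool = False, chain_id: str = "A",
                template_path: str | None = None) -> Frame:
    """Build one rigid chain from residue templates.

    Residue i's ring centroid lies at ``origin + (i-1)*rise*axis``; with
    ``flip=True`` the chain is rotated 180 deg about an axis perpendicular to
    its own, so residue i's centroid moves to position DP-i while the chain
    direction reverses. Terminal caps (HO4 on residue 1; O1/HO1 on residue
    DP) close the free valences.
    """
    if rise_per_monomer <= 0:
        raise ValueError("rise_per_monomer must be positive")
    tpl = load_templates(template_path)
    names, resnames, resids, coords = [], [], [], []
    dp = seq.dp
    for i, unit in enumerate(seq.units, start=1):
        res = tpl["residues"][unit.kind]
        rot = _TWO_FOLD if (i - 1) % 2 else np.eye(3)
        shift = np.array([0.0, 0.0, (i - 1) * rise_per_monomer])
        entries = dict(res)
        if i == 1:
            entries["HO4"] = tpl["terminal"]["HO4"]
        if i == dp:
            entries["O1"] = tpl["terminal"]["O1"]
            entries["HO1"] = tpl["terminal"]["HO1"]
        for name, xyz in entries.items():
            names.append(name)
            resnames.append(KIND_TO_RESNAME[unit.kind])
            resids.append(i)
            coords.append(rot @ xyz + shift)
    coords = np.asarray(coords)
    if flip:
        center = np.array([0.0, 0.0, (dp - 1) * rise_per_monomer / 2.0])
        coords = (coords - center) @ _FLIP_Y.T + center
    basis = _axis_basis(axis)
    coords = coords @ basis.T + np.asarray(origin, float)
    return Frame(names, resnames, resids, [chain_id] * len(names), coords)


def _min_cross_distance(a: np.ndarray, b: np.ndarray, box=None) -> float:
    """Minimum distance between two coordinate sets (minimum image if box)."""
    if box is not None:
        box = np.asarray(box, float)
        tree = cKDTree(wrap_coords(b, box), boxsize=box)
        d, _ = tree.query(wrap_coords(a, box), k=1)
    else:
        tree = cKDTree(b)
        d, _ = tree.query(a, k=1)
    return float(np.min(d))


def _steric_check(frame: Frame) -> None:
    tree = cKDTree(frame.coords)
    pairs = tree.query_pairs(STERIC_MIN_DISTANCE, output_type="ndarray")
    # only distinct chains count as steric failure (intra-chain geometry is
    # the template's business)
    for i, j in pairs:
        if frame.chains[i] != frame.chains[j]:
            raise ValueError(
                f"steric failure: atoms {frame.names[i]}/{frame.chains[i]} and "
                f"{frame.names[j]}/{frame.chains[j]} closer than "
                f"{STERIC_MIN_DISTANCE} A at zero noise")


def build_fibril(seq: ChitosanSequence, n_sheets: int, chains_per_sheet: int,
                 arrangement: str = "antiparallel",
                 intra_sheet_spacing: float = DEFAULT_INTRA_SHEET,
                 inter_sheet_spacing: float = DEFAULT_INTER_SHEET,
                 register_offset: float | None = None,
                 noise_sigma: float = 0.0, seed: int | None = None,
                 rise_per_monomer: float = DEFAULT_RISE, box=None,
                 center=None) -> Frame:
    """Build an idealized nanofibril of n_sheets x chains_per_sheet chains.

    Chains run along +z; chains within a sheet are stacked along +y
    (``intra_sheet_spacing`` apart) and sheets along +x
    (``inter_sheet_spacing``). In the antiparallel arrangement adjacent
    chains within a sheet alternate direction; ``register_offset``
    translates every second chain of a sheet along the chain axis. Gaussian
    positional noise of ``noise_sigma`` (A) is added atom-wise using
    ``seed``.
    """
    if arrangement not in ("parallel", "antiparallel"):
        raise ValueError(f"arrangement must be parallel|antiparallel, got {arrangement!r}")
    if intra_sheet_spacing <= 0 or inter_sheet_spacing <= 0:
        raise ValueError("spacings must be positive")
    if register_offset is None:
        register_offset = REGISTER_BY_ARRANGEMENT[arrangement]
    chains = []
    idx = 0
    for s in range(n_sheets):
        for c in range(chains_per_sheet):
            # checkerboard: alternates within a sheet and across sheets, so
            # every adjacent pair (lateral and stacking) is antiparallel
            flip = arrangement == "antiparallel" and (s + c) % 2 == 1
            # the axial register shift rides on the flipped sublattice so all
            # sheets repeat the same lateral pair geometry
            shifted = flip if arrangement == "antiparallel" else c % 2 == 1
            origin = np.array([s * inter_sheet_spacing, c * intra_sheet_spacing,
                               register_offset if shifted else 0.0])
            chains.append(build_chain(seq, rise_per_monomer, (0, 0, 1), origin,
                                      flip=flip, chain_id=chain_label(idx)))
            idx += 1
    frame = concatenate(chains, box=box)
    if center is not None:
        frame.coords += np.asarray(center, float) - frame.coords.mean(axis=0)
    if box is not None:
        extent = frame.coords.max(axis=0) - frame.coords.min(axis=0)
        if np.any(extent + 2.0 > np.asarray(box, float)):
            warnings.warn(
                f"fibril extent {np.round(extent, 1)} A approaches or exceeds "
                f"the box {box}; periodic images will touch", stacklevel=2)
    _steric_check(frame)
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("noise_sigma > 0 requires a seed")
        rng = np.random.default_rng(seed)
        frame.coords = frame.coords + rng.normal(0.0, noise_sigma, frame.coords.shape)
    return frame


def random_solution_frame(seq: ChitosanSequence, n_chains: int, box,
                          min_separation: float = 3.0, seed: int = 0,
                          max_attempts: int = 2000,
                          rise_per_monomer: float = DEFAULT_RISE) -> Frame:
    """Randomly place rigid chains in an orthorhombic box (dispersed state).

    Orientations are uniform over rotations; positions uniform in the box.
    Each placement is rejected until its minimum heavy-atom distance to all
    previously placed chains (minimum image) is >= ``min_separation``.
    """
    box = np.asarray(box, float).reshape(3)
    rng = np.random.default_rng(seed)
    base = build_chain(seq, rise_per_monomer)
    base_coords = base.coords - base.coords.mean(axis=0)
    heavy = base.is_heavy
    placed: list[Frame] = []
    placed_heavy: list[np.ndarray] = []
    for k in range(n_chains):
        ok = False
        for _ in range(max_attempts):
            rot = Rotation.random(rng=rng).as_matrix()
            origin = rng.uniform(0.0, box)
            coords = base_coords @ rot.T + origin
            if all(_min_cross_distance(coords[heavy], other, box) >= min_separation
                   for other in placed_heavy):
                ok = True
                break
        if not ok:
            density = (k + 1) / float(np.prod(box))
            raise RuntimeError(
                f"failed to place chain {k + 1}/{n_chains} after {max_attempts} "
                f"attempts (number density {density:.2e} chains/A^3 too high for "
                f"min_separation {min_separation} A)")
        f = base.copy()
        f.coords = coords
        f.chains = np.full(f.n_atoms, chain_label(k), dtype="U2")
        placed.append(f)
        placed_heavy.append(coords[heavy])
    return concatenate(placed, box=box)


# rigid TIP3P-like water geometry: O-H 0.9572 A, H-O-H 104.52 deg
_WATER_OH = 0.9572
_WATER_ANGLE = np.deg2rad(104.52)
_WATER_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [_WATER_OH * np.sin(_WATER_ANGLE / 2), _WATER_OH * np.cos(_WATER_ANGLE / 2), 0.0],
    [-_WATER_OH * np.sin(_WATER_ANGLE / 2), _WATER_OH * np.cos(_WATER_ANGLE / 2), 0.0],
])


def solvate_lattice(frame: Frame, water_spacing: float,
                    exclusion_radius: float) -> Frame:
    """Add rigid 3-site waters on a cubic lattice inside the frame's box.

    Lattice sites within ``exclusion_radius`` of any solute heavy atom
    (minimum image) are removed. Waters get chain id ``W`` and residue
    numbering continuing after the solute.
    """
    if water_spacing <= 0:
        raise ValueError("water_spacing must be positive")
    if frame.box is None:
        raise ValueError("solvation requires a box")
    box = np.asarray(frame.box, float).reshape(3)
    n = np.floor(box / water_spacing).astype(int)
    axes = [water_spacing / 2 + water_spacing * np.arange(n[d]) for d in range(3)]
    sites = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    heavy = frame.is_heavy & ~frame.is_water
    if heavy.any() and len(sites):
        solute = wrap_coords(frame.coords[heavy], box)
        tree = cKDTree(solute, boxsize=box)
        d, _ = tree.query(wrap_coords(sites, box), k=1)
        sites = sites[d >= exclusion_radius]
    n_w = len(sites)
    if n_w == 0:
        return frame.copy()
    coords = (sites[:, None, :] + _WATER_TEMPLATE[None, :, :]).reshape(-1, 3)
    next_resid = int(frame.resids.max()) + 1 if frame.n_atoms else 1
    water = Frame(
        np.tile(["O", "H1", "H2"], n_w),
        np.full(3 * n_w, "HOH"),
        np.repeat(next_resid + np.arange(n_w), 3),
        np.full(3 * n_w, "W"),
        coords,
        elements=np.tile(["O", "H", "H"], n_w),
    )
    return concatenate([frame, water], box=box, frame_index=frame.frame_index)


def _kabsch(moving: np.ndarray, target: np.ndarray):
    """Rigid transform (R, t) minimizing ||R @ moving + t - target||."""
    cm, ct = moving.mean(axis=0), target.mean(axis=0)
    h = (moving - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, ct - r @ cm


def make_assembly_trajectory(seq: ChitosanSequence, n_chains: int,
                             n_frames: int, schedule=None, seed: int = 0,
                             box=(85.0, 85.0, 85.0), min_separation: float = 3.0,
                             arrangement: str = "antiparallel",
                             n_sheets: int | None = None,
                             intra_sheet_spacing: float = DEFAULT_INTRA_SHEET,
                             inter_sheet_spacing: float = DEFAULT_INTER_SHEET,
                             register_offset: float | None = None,
                             noise_sigma: float = 0.0) -> Trajectory:
    """Synthetic self-assembly pathway: dispersed state -> ordered fibril.

    Frame k places each chain by rigid-body interpolation between its pose in
    a random solution frame (mixing coefficient 0) and its pose in an
    idealized fibril (coefficient 1): rotations via spherical interpolation,
    translations linearly. A monotone non-decreasing ``schedule`` of mixing
    coefficients emulates progressive ordering; a non-monotone schedule is
    allowed (with a warning) for disassembly scenarios.
    """
    box = np.asarray(box, float).reshape(3)
    if schedule is None:
        schedule = np.linspace(0.0, 1.0, n_frames)
    schedule = np.asarray(schedule, float)
    if len(schedule) != n_frames:
        raise ValueError("schedule length must equal n_frames")
    if np.any(schedule < 0) or np.any(schedule > 1):
        raise ValueError("mixing coefficients must lie in [0, 1]")
    if np.any(np.diff(schedule) < 0):
        warnings.warn("assembly schedule is not monotone non-decreasing",
                      stacklevel=2)
    if n_sheets is None:
        # aim for sheets of ~8 chains (e.g. 24 chains -> 3 sheets of 8),
        # keeping the sheet width well inside an 85 A box
        divisors = [d for d in range(1, n_chains + 1) if n_chains % d == 0]
        n_sheets = min(divisors, key=lambda d: abs(d - n_chains / 8.0))
    if n_chains % n_sheets:
        raise ValueError(f"n_chains={n_chains} not divisible by n_sheets={n_sheets}")
    dispersed = random_solution_frame(seq, n_chains, box, min_separation, seed)
    fibril = build_fibril(seq, n_sheets, n_chains // n_sheets, arrangement,
                          intra_sheet_spacing, inter_sheet_spacing,
                          register_offset, box=box, center=box / 2)
    rng = np.random.default_rng(seed)
    transforms = []
    for cid in dispersed.chain_ids():
        sel = dispersed.chains == cid
        r, t = _kabsch(dispersed.coords[sel], fibril.coords[fibril.chains == cid])
        transforms.append((sel, Rotation.from_matrix(r),
                           dispersed.coords[sel].mean(axis=0), t))
    frames = []
    for k, lam in enumerate(schedule):
        coords = dispersed.coords.copy()
        for sel, rot, center_a, t in transforms:
            rk = Rotation.from_rotvec(lam * rot.as_rotvec()).as_matrix()
            full_t = rot.as_matrix() @ center_a + t  # target centroid
            ck = (1 - lam) * center_a + lam * full_t
            coords[sel] = (dispersed.coords[sel] - center_a) @ rk.T + ck
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        f = dispersed.copy()
        f.coords = coords
        f.frame_index = k
        frames.append(f)
    meta = dict(seed=seed, n_chains=n_chains, n_frames=n_frames,
                schedule=list(map(float, schedule)), box=list(map(float, box)),
                arrangement=arrangement, n_sheets=n_sheets,
                intra_sheet_spacing=intra_sheet_spacing,
                inter_sheet_spacing=inter_sheet_spacing,
                register_offset=(REGISTER_BY_ARRANGEMENT[arrangement]
                                 if register_offset is None else register_offset),
                noise_sigma=noise_sigma,
                min_separation=min_separation, sequence=seq.to_pattern_string())
    return Trajectory(frames, meta)
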