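"""Generate the idealized GlcN/GlcNAc residue templates as JSON package data.

Local frame convention (see chitosim.builder):
  +z : chain axis (rise per monomer applied along +z)
  +y : "amine side" lateral direction (N, O3, acetyl arm)
  -y : "hydroxymethyl side" (C6-O6 arm)
  +-x: sheet stacking direction (ring faces / axial hydrogens)
Ring centroid (C1,C2,C3,C4,C5,O5) is exactly at the local origin.
"""
import json
import os

import numpy as np

R = 1.43   # hexagon radius -> ring bond ~1.5 with pucker
PK = 0.25  # chair pucker amplitude along x

ring = {
    "C1": ( PK, 0.000,  1.430),
    "C2": (-PK, 1.238,  0.715),
    "C3": ( PK, 1.238, -0.715),
    "C4": (-PK, 0.000, -1.430),
    "C5": ( PK, -1.238, -0.715),
    "O5": (-PK, -1.238,  0.715),
}

common = dict(ring)
# glycosidic oxygen owned by this residue; bridges its C4 to C1 of the
# previous residue (one rise below, screw-rotated)
common["O4"] = (-0.25, 0.84, -2.60)
# amine nitrogen on C2, equatorial +y
common["N"] = (-0.25, 2.511, 1.450)
common["HN1"] = (-0.25, 3.514, 1.570)   # N-H donor pointing +y
# hydroxyl on C3, equatorial +y
common["O3"] = (0.25, 2.477, -1.430)
common["HO3"] = (0.25, 3.427, -1.564)   # O3-H donor pointing +y
# exocyclic C6-O6 arm on C5, -y side; kept high-z/+x so it clears the
# acetyl arm of the (screw-rotated) residue below
common["C6"] = (1.00, -2.450, -1.165)
common["O6"] = (0.60, -3.800, -0.966)
common["HO6"] = (1.272, -4.486, -0.966)  # O6-H donor, -y tilted +x so facing
# hydroxyl hydrogens of adjacent chains clear each other while O6 accepts
common["H61"] = (1.98, -2.180, -1.550)
common["H62"] = (1.16, -2.760, -2.200)
# ring hydrogens, axial (+-x)
common["H1"] = (1.33, 0.100, 1.560)
common["H2"] = (-1.34, 1.238, 0.715)
common["H3"] = (1.34, 1.238, -0.715)
common["H4"] = (-1.34, 0.000, -1.430)
common["H5"] = (1.34, -1.238, -0.715)

glcn = dict(common)
glcn["HN2"] = (0.58, 2.861, 0.980)      # second amine hydrogen

glcnac = dict(common)
# acetyl group replacing HN2: N-C7(=O7)-C8(H81..83); whole arm stays on the
# high-y amine side so the carbonyl O7 is exposed for interchain h-bonds and
# nothing collides with the next residue's ring above (z ~ 2.6-4, low y)
glcnac["HN1"] = (-0.25, 3.370, 0.918)   # amide H tilted -z, clear of O7
glcnac["C7"] = (-0.25, 3.535, 2.314)
glcnac["O7"] = (-0.25, 4.690, 1.900)    # carbonyl acceptor pointing +y
glcnac["C8"] = (0.96, 3.005, 3.040)    # out of the amide plane: the next
# residue's screw-rotated C6-O6 arm occupies the (+y, z~3.9) in-plane region
glcnac["H81"] = (0.84, 1.935, 3.210)
glcnac["H82"] = (1.85, 3.180, 2.430)
glcnac["H83"] = (1.06, 3.520, 3.990)

# chain terminal atoms (the "water of condensation"): HO4 caps the free O4 of
# residue 1 (non-reducing end); O1/HO1 cap the free C1 of residue DP.
terminal = {
    "HO4": (-0.25, 1.620, -3.170),
    "O1": (0.25, 0.420, 2.760),
    "HO1": (0.25, 1.000, 3.520),
}

HEAVY_BONDS = {
    "GlcN": [("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
             ("C5", "O5"), ("O5", "C1"), ("C2", "N"), ("C3", "O3"),
             ("C4", "O4"), ("C5", "C6"), ("C6", "O6")],
    "GlcNAc": [("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
               ("C5", "O5"), ("O5", "C1"), ("C2", "N"), ("C3", "O3"),
               ("C4", "O4"), ("C5", "C6"), ("C6", "O6"),
               ("N", "C7"), ("C7", "O7"), ("C7", "C8")],
}


def check(name, tpl):
    names = list(tpl)
    xyz = np.array([tpl[n] for n in names])
    # every H within 1.2 A of exactly one heavy atom (bond inference rule)
    heavy = [i for i, n in enumerate(names) if not n.startswith("H")]
    for i, n in enumerate(names):
        if n.startswith("H"):
            d = np.linalg.norm(xyz[heavy] - xyz[i], axis=1)
            close = [names[heavy[j]] for j in np.flatnonzero(d < 1.2)]
            assert len(close) == 1, (name, n, close)
    # no intra-template clash below 0.9
    d = np.linalg.norm(xyz[:, None] - xyz[None], axis=-1)
    np.fill_diagonal(d, 9)
    bad = np.argwhere(d < 0.9)
    assert not len(bad), [(names[i], names[j], d[i, j]) for i, j in bad[:5]]
    # heavy-atom bond inference (distance < 1.8) must reproduce exactly the
    # declared bond table: no spurious short non-bonded heavy pairs
    kind = "GlcN" if "HN2" in names else "GlcNAc"
    bonds = {frozenset(b) for b in HEAVY_BONDS[kind] if b[0] in tpl and b[1] in tpl}
    inferred = set()
    for i in heavy:
        for j in heavy:
            if i < j and d[i, j] < 1.8:
                inferred.add(frozenset((names[i], names[j])))
    assert inferred == bonds, (name, inferred ^ bonds)
    cen = xyz[[names.index(a) for a in ring]].mean(axis=0)
    assert np.allclose(cen, 0, atol=1e-9), cen
    print(name, len(tpl), "atoms ok; ring centroid", cen.round(3))


check("GlcN", glcn)
check("GlcNAc", glcnac)
assert len(glcn) == 22 and len(glcnac) == 27


def check_stack(lower, upper):
    """Verify a residue against its screw-rotated neighbor one rise above:
    every H keeps a unique parent, no cross-residue heavy pair < 1.8 except
    the glycosidic O4-C1 linkage."""
    rot = np.diag([-1.0, -1.0, 1.0])
    names_l = list(lower); xyz_l = np.array([lower[n] for n in names_l])
    names_u = list(upper); xyz_u = np.array([upper[n] for n in names_u]) @ rot + [0, 0, 5.2]
    names = names_l + names_u
    owner = ["L"] * len(names_l) + ["U"] * len(names_u)
    xyz = np.vstack([xyz_l, xyz_u])
    heavy = [i for i, n in enumerate(names) if not n.startswith("H")]
    for i, n in enumerate(names):
        if n.startswith("H"):
            d = np.linalg.norm(xyz[heavy] - xyz[i], axis=1)
            close = [(names[heavy[j]], owner[heavy[j]]) for j in np.flatnonzero(d < 1.2)]
            assert len(close) == 1, (n, owner[i], close)
    for ii in heavy:
        for jj in heavy:
            if ii < jj and owner[ii] != owner[jj]:
                dd = np.linalg.norm(xyz[ii] - xyz[jj])
                glyco = {names[ii], names[jj]} == {"O4", "C1"}
                assert dd >= 1.8 or glyco, (names[ii], names[jj], dd)
    d = np.linalg.norm(xyz[:, None] - xyz[None], axis=-1)
    np.fill_diagonal(d, 9)
    cross = [(names[i], names[j], d[i, j]) for i in range(len(names))
             for j in range(i + 1, len(names))
             if owner[i] != owner[j] and d[i, j] < 1.35
             and {names[i], names[j]} != {"O4", "C1"}]
    assert not cross, cross


for lo in (glcn, glcnac):
    for up in (glcn, glcnac):
        check_stack(lo, up)
print("stacked-neighbor checks ok")

out = os.path.join(os.path.dirname(__file__), "..", "src", "chitosim", "data")
os.makedirs(out, exist_ok=True)
payload = {
    "comment": "Idealized rigid chitosan residue templates; local frame: +z chain axis, +y amine side, ring centroid at origin.",
    "rise_per_monomer": 5.2,
    "residues": {"GlcN": glcn, "GlcNAc": glcnac},
    "terminal": terminal,
    "heavy_bonds": HEAVY_BONDS,
}
with open(os.path.join(out, "residue_templates.json"), "w") as fh:
    json.dump(payload, fh, indent=1)
print("written", os.path.join(out, "residue_templates.json"))
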