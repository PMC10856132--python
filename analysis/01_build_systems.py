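"""Build the three study systems and their reference states.

Emulates the simulated compositions: 24 chains of DP 10 in an 85 x 85 x 85 A
box, at DA 20% (block) and DA 50% (block and alternating). For each system a
dispersed solution state and an idealized antiparallel fibril are written as
PDB files under results/systems/, with compositions summarized in
results/systems/compositions.csv.
"""

from pathlib import Path

import pandas as pd

from chitosim import (build_fibril, composition, make_sequence,
                      random_solution_frame, write_pdb)

OUT = Path(__file__).resolve().parent.parent / "results" / "systems"
OUT.mkdir(parents=True, exist_ok=True)

SYSTEMS = [
    ("da20_block", 0.2, "block"),
    ("da50_block", 0.5, "block"),
    ("da50_alternating", 0.5, "alternating"),
]
BOX = (85.0, 85.0, 85.0)
SEED = 2024

rows = []
for name, da, pattern in SYSTEMS:
    seq = make_sequence(10, da, pattern)
    n_g, n_a, da_out = composition(seq)
    solution = random_solution_frame(seq, 24, BOX, min_separation=3.0,
                                     seed=SEED)
    fibril = build_fibril(seq, 3, 8, "antiparallel", box=BOX,
                          center=(42.5, 42.5, 42.5))
    write_pdb(solution, str(OUT / f"{name}_solution.pdb"))
    write_pdb(fibril, str(OUT / f"{name}_fibril.pdb"))
    rows.append({"system": name, "sequence": seq.to_pattern_string(),
                 "dp": seq.dp, "da": da_out, "n_glcn": n_g, "n_glcnac": n_a,
                 "n_chains": 24, "solution_atoms": solution.n_atoms,
                 "fibril_atoms": fibril.n_atoms})
    print(f"{name}: {seq} (GlcN {n_g}, GlcNAc {n_a}, DA {da_out:.0%}), "
          f"{solution.n_atoms} atoms dispersed / {fibril.n_atoms} in fibril")

pd.DataFrame(rows).to_csv(OUT / "compositions.csv", index=False)
print(f"wrote {OUT}/compositions.csv")
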