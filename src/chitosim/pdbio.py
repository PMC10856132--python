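"""Multi-model PDB reading and writing.

One MODEL block per frame, TER records between chains, CRYST1 carrying the
orthorhombic box. Conventions: 1-based residue numbering, coordinates in
angstrom written to 3 decimals, occupancy/B-factor fixed at 1.00/0.00.
Chain ids beyond Z use two characters written in columns 21-22 (the
character before the standard chain-id column is normally blank). Atom
serials above 99999 wrap modulo 100000; serials are not used to identify
atoms on read, so no information is lost. Insertion codes and altlocs are
not supported and are rejected loudly.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import Frame, Trajectory

logger = logging.getLogger(__name__)

_KNOWN_SKIP = ("REMARK", "TITLE", "HEADER", "COMPND", "SOURCE", "KEYWDS",
               "EXPDTA", "AUTHOR", "REVDAT", "JRNL", "SEQRES", "HETATM",
               "CONECT", "MASTER", "ANISOU", "SCALE", "ORIGX")


class PDBFormatError(ValueError):
    """Raised for malformed PDB content, carrying the offending line number."""


def write_pdb(traj: Trajectory | Frame, path: str) -> None:
    """Write a trajectory (or single frame) as a multi-model PDB file."""
    if isinstance(traj, Frame):
        traj = Trajectory([traj])
    if not len(traj):
        raise ValueError("cannot write an empty trajectory")
    with open(path, "w") as fh:
        first = traj[0]
        if first.box is not None:
            a, b, c = first.box
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        multi = len(traj) > 1
        for m, frame in enumerate(traj, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            serial = 0
            prev_chain = None
            for i in range(frame.n_atoms):
                chain = str(frame.chains[i])
                if prev_chain is not None and chain != prev_chain:
                    fh.write("TER\n")
                prev_chain = chain
                serial += 1
                name = str(frame.names[i])
                # PDB name column: pad 1-3 char names with a leading space
                fname = f" {name:<3s}" if len(name) < 4 else name
                cfield = f"{chain:>2s}"[-2:]
                x, y, z = frame.coords[i]
                fh.write(
                    f"ATOM  {serial % 100000:5d} {fname} {frame.resnames[i]:<3s}"
                    f"{cfield}{int(frame.resids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {str(frame.elements[i]):>2s}\n")
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[20:22].strip()
        resid_s = line[22:26].strip()
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM record on line {lineno}: {exc}") from exc
    if altloc:
        raise PDBFormatError(f"altloc {altloc!r} on line {lineno} is not supported")
    if icode:
        raise PDBFormatError(f"insertion code {icode!r} on line {lineno} is not supported")
    if not resid_s:
        raise PDBFormatError(f"missing residue number on line {lineno}")
    return name, resname, chain, int(resid_s), (x, y, z), element or None


def read_pdb(path: str) -> Trajectory:
    """Read a (multi-model) PDB file written in this package's conventions.

    All models must share the same topology (labels in the same order);
    a mismatch raises an error naming the model. Unknown record types are
    skipped with a logged count.
    """
    box = None
    frames: list[Frame] = []
    cur: list | None = None  # accumulating atom tuples for the open model
    skipped = 0
    in_model = False

    def finish(model_no: int):
        nonlocal cur
        if cur is None or not cur:
            cur = None
            return
        names, resnames, chains, resids, coords, elements = zip(*cur)
        frame = Frame(names, resnames, resids, chains, np.asarray(coords),
                      elements=None if any(e is None for e in elements) else elements,
                      box=box, frame_index=len(frames))
        if frames and not frames[0].same_topology(frame):
            raise PDBFormatError(
                f"model {model_no} topology differs from model 1")
        frames.append(frame)
        cur = None

    model_no = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])])
                except ValueError as exc:
                    raise PDBFormatError(f"bad CRYST1 on line {lineno}") from exc
            elif rec == "MODEL":
                if cur:
                    finish(model_no)
                in_model = True
                model_no = len(frames) + 1
                cur = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise PDBFormatError(f"ENDMDL without MODEL on line {lineno}")
                finish(model_no)
                in_model = False
            elif rec == "ATOM":
                if cur is None:
                    cur = []
                name, resname, chain, resid, xyz, element = _parse_atom_line(line, lineno)
                cur.append((name, resname, chain, resid, xyz, element))
            elif rec in ("TER", "END", ""):
                continue
            else:
                skipped += 1
    if in_model and cur:
        raise PDBFormatError("file ends inside an open MODEL block")
    if cur:
        finish(len(frames) + 1)
    if skipped:
        logger.info("read_pdb: skipped %d unrecognized records", skipped)
    if not frames:
        raise PDBFormatError(f"no ATOM records found in {path}")
    return Trajectory(frames)
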