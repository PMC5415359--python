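"""Structure and trajectory readers/writers.

PDB structures are read and written through :mod:`gemmi`; binary
trajectory formats (XTC, DCD) through :mod:`MDAnalysis`.  In addition the
package defines a small plain-text trajectory dialect ("xyzb") used by
the synthetic-data generators, one block per frame::

    <n_atoms>
    Lx Ly Lz time            # box lengths in Å, time in ps
    name resname resid chain element x y z [mass] [vx vy vz]

Coordinates are Å, velocities Å/ps, masses amu.  The optional columns
are recognised by count: 8 columns is the base record, 9 adds a mass,
11 adds a velocity, 12 adds both.

Only orthorhombic boxes are supported; a triclinic cell is rejected with
an explicit message because every analysis in the package bins along a
z-slab normal to the membrane.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .core import (
    Frame,
    StructureError,
    Trajectory,
    TrajectoryError,
    vdw_radius,
)

__all__ = [
    "read_structure",
    "write_pdb",
    "read_trajectory",
    "write_xyzb",
    "read_xyzb",
]

_ORTHO_TOL = 1e-3  # degrees


def _check_orthorhombic(alpha: float, beta: float, gamma: float, source: str) -> None:
    if max(abs(alpha - 90), abs(beta - 90), abs(gamma - 90)) > _ORTHO_TOL:
        raise StructureError(
            f"{source}: triclinic cell (angles {alpha:.2f}/{beta:.2f}/{gamma:.2f}°) "
            "is not supported; all analyses assume an orthorhombic box"
        )


def read_structure(path: str | os.PathLike, model_index: int = 0) -> Frame:
    """Read one model of a PDB file into a :class:`Frame`.

    Author residue numbering is preserved.  Alternate locations are
    resolved by keeping the highest-occupancy conformer (tie: first
    encountered).  A CRYST1 record, when present and not the P1
    placeholder cell, is captured as the frame box.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if model_index >= len(st):
        raise StructureError(
            f"{path}: model index {model_index} out of range ({len(st)} models)"
        )
    model = st[model_index]

    box = None
    cell = st.cell
    placeholder = abs(cell.a - 1) < 1e-6 and abs(cell.b - 1) < 1e-6 and abs(cell.c - 1) < 1e-6
    if cell.a > 0 and not placeholder:
        _check_orthorhombic(cell.alpha, cell.beta, cell.gamma, str(path))
        box = np.array([cell.a, cell.b, cell.c])

    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    chains: list[str] = []
    elements: list[str] = []
    serials: list[int] = []
    positions: list[list[float]] = []
    # altloc bookkeeping: (chain, resid, icode, atom name) -> row index
    seen: dict[tuple, int] = {}
    occs: dict[int, float] = {}

    for chain in model:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, res.seqid.icode, atom.name)
                if key in seen:
                    row = seen[key]
                    if atom.occ > occs[row]:
                        positions[row] = [atom.pos.x, atom.pos.y, atom.pos.z]
                        occs[row] = atom.occ
                    continue
                row = len(names)
                seen[key] = row
                occs[row] = atom.occ
                names.append(atom.name)
                resnames.append(res.name)
                resids.append(res.seqid.num)
                chains.append(chain.name)
                elements.append(atom.element.name.upper())
                serials.append(atom.serial)
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])

    if not names:
        raise StructureError(f"{path}: model {model_index} contains no atoms")
    return Frame(
        names=names,
        resnames=resnames,
        resids=resids,
        chains=chains,
        elements=elements,
        positions=np.array(positions),
        box=box,
        serials=serials,
    )


def write_pdb(frame: Frame, path: str | os.PathLike) -> None:
    """Write a frame as a single-model PDB snapshot (gemmi writer)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "k2pflex snapshot"
    if frame.box is not None:
        st.cell = gemmi.UnitCell(*frame.box, 90.0, 90.0, 90.0)
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple, gemmi.Residue] = {}
    for a in frame.atoms():
        ch = chain_map.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chain_map[a.chain] = ch
        rkey = (a.chain, a.resid, a.resname)
        res = res_map.get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, " ")
            res_map[rkey] = res
            ch.add_residue(res)
            res = ch[-1]
            res_map[rkey] = res
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element.capitalize())
        atom.pos = gemmi.Position(*a.position)
        atom.occ = 1.0
        atom.serial = a.serial
        res.add_atom(atom)
    for ch in chain_map.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ----------------------------------------------------------------------
# xyzb plain-text trajectory dialect
# ----------------------------------------------------------------------

def write_xyzb(traj: Trajectory | Frame, path: str | os.PathLike) -> None:
    """Write a trajectory (or single frame) in the xyzb text dialect."""
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    with open(path, "w") as fh:
        for fr in frames:
            box = fr.require_box()
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"{box[0]:.6f} {box[1]:.6f} {box[2]:.6f} {fr.time:.6f}\n")
            for i in range(fr.n_atoms):
                cols = [
                    str(fr.names[i]),
                    str(fr.resnames[i]),
                    str(fr.resids[i]),
                    str(fr.chains[i]),
                    str(fr.elements[i]),
                    f"{fr.positions[i, 0]:.6f}",
                    f"{fr.positions[i, 1]:.6f}",
                    f"{fr.positions[i, 2]:.6f}",
                ]
                if fr.masses is not None:
                    cols.append(f"{fr.masses[i]:.6f}")
                if fr.velocities is not None:
                    cols.extend(f"{v:.6f}" for v in fr.velocities[i])
                fh.write(" ".join(cols) + "\n")


def read_xyzb(path: str | os.PathLike) -> Trajectory:
    """Read an xyzb text trajectory."""
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"trajectory file not found: {path}")
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryError(
                f"{path}: expected atom count at line {pos + 1}, got {lines[pos]!r}"
            ) from exc
        header = lines[pos + 1].split()
        if len(header) != 4:
            raise TrajectoryError(
                f"{path}: expected 'Lx Ly Lz time' at line {pos + 2}"
            )
        box = np.array([float(x) for x in header[:3]])
        time = float(header[3])
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n or any(not ln.strip() for ln in body):
            raise TrajectoryError(f"{path}: truncated frame at line {pos + 1}")
        names, resnames, resids, chains, elements = [], [], [], [], []
        xyz = np.empty((n, 3))
        masses = None
        vels = None
        for i, ln in enumerate(body):
            parts = ln.split()
            if len(parts) not in (8, 9, 11, 12):
                raise TrajectoryError(
                    f"{path}: malformed atom record at line {pos + 3 + i}: {ln!r}"
                )
            names.append(parts[0])
            resnames.append(parts[1])
            resids.append(int(parts[2]))
            chains.append(parts[3])
            elements.append(parts[4])
            xyz[i] = [float(parts[5]), float(parts[6]), float(parts[7])]
            extra = parts[8:]
            if len(extra) in (1, 4):
                if masses is None:
                    masses = np.empty(n)
                masses[i] = float(extra[0])
                extra = extra[1:]
            if len(extra) == 3:
                if vels is None:
                    vels = np.empty((n, 3))
                vels[i] = [float(v) for v in extra]
        frames.append(
            Frame(
                names=names,
                resnames=resnames,
                resids=resids,
                chains=chains,
                elements=elements,
                positions=xyz,
                box=box,
                time=time,
                velocities=vels,
                masses=masses,
            )
        )
        pos += 2 + n
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return Trajectory(frames, topology_source=str(path))


def _read_mdanalysis(topology: str | os.PathLike, traj: str | os.PathLike) -> Trajectory:
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(topology), str(traj))
    except Exception as exc:
        raise TrajectoryError(f"cannot read {traj} with topology {topology}: {exc}") from exc
    atoms = u.atoms
    names = [a.name for a in atoms]
    try:
        resnames = list(atoms.resnames)
    except Exception:
        resnames = ["UNK"] * len(atoms)
    resids = list(atoms.resids)
    try:
        chains = list(atoms.chainIDs)
    except Exception:
        try:
            chains = list(atoms.segids)
        except Exception:
            chains = ["A"] * len(atoms)
    try:
        elements = [e.upper() for e in atoms.elements]
    except Exception:
        # fall back to the first letter of the atom name
        elements = [str(n)[0].upper() for n in names]

    frames = []
    for ts in u.trajectory:
        dims = ts.dimensions
        box = None
        if dims is not None and dims[:3].min() > 0:
            _check_orthorhombic(dims[3], dims[4], dims[5], str(traj))
            box = np.array(dims[:3], dtype=float)
        frames.append(
            Frame(
                names=names,
                resnames=resnames,
                resids=resids,
                chains=chains,
                elements=elements,
                positions=ts.positions.copy().astype(float),
                box=box,
                time=float(ts.time),
                velocities=ts.velocities.copy().astype(float) if ts.has_velocities else None,
            )
        )
    return Trajectory(frames, topology_source=str(topology))


def read_trajectory(topology: str | os.PathLike | None, traj: str | os.PathLike) -> Trajectory:
    """Read a trajectory file.

    The xyzb text dialect is self-describing and needs no topology;
    XTC/DCD require a topology file (PDB) for atom labels.
    """
    suffix = Path(traj).suffix.lower()
    if suffix in (".xyzb", ".xyz"):
        return read_xyzb(traj)
    if topology is None:
        raise TrajectoryError(f"format {suffix} requires a topology file")
    return _read_mdanalysis(topology, traj)
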