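"""Reading and writing conformational ensembles as multi-model PDB files.

PDB files are in ångström; everything in memory is in nm, so coordinates are
divided by 10 on read and multiplied by 10 on write.  The topology is taken
from the first MODEL and every further model must carry the identical atom
list.  Alternate locations: only blank or 'A' altlocs are kept (others are
dropped with a warning) so that the topology is deterministic.

Hydrogens are passed through untouched in both directions: this module never
adds or removes them.  H-bond analysis therefore requires input files with
explicit (polar) hydrogens and fails loudly otherwise.

A secondary plain-text dialect is supported for synthetic fixtures: XYZ-like
blocks of whitespace-delimited coordinates (in nm), one block per frame, on a
topology supplied by the caller.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi
import numpy as np

from .core import Atom, Ensemble, Frame, ParseError, TopologyError

_COORD_COLUMNS = ((30, 38), (38, 46), (46, 54), (54, 60), (60, 66))


def _validate_pdb_records(path: Path) -> None:
    """Reject malformed ATOM/HETATM records with a line number.

    gemmi parses a non-numeric coordinate field silently as 0.0; this guard
    runs first so corrupt files fail instead of producing wrong geometry.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}, line {lineno}: truncated atom record")
            for start, stop in _COORD_COLUMNS:
                fieldstr = line[start:stop].strip()
                if fieldstr == "" and start >= 54:
                    continue  # occupancy/B-factor may be absent
                try:
                    float(fieldstr)
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: unparseable numeric field "
                        f"{fieldstr!r} in columns {start + 1}-{stop}"
                    ) from None


def _model_atoms(model: gemmi.Model) -> tuple[list[Atom], np.ndarray, bool]:
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    dropped_altloc = False
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("\x00", "", "A"):
                    dropped_altloc = True
                    continue
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=residue.seqid.icode.strip(),
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                    )
                )
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    return atoms, np.asarray(coords, dtype=float), dropped_altloc


def read_multimodel(
    path: str | Path,
    *,
    label: str | None = None,
    frame_spacing: float = 2.0,
) -> Ensemble:
    """Read a (multi-)MODEL PDB file into an :class:`Ensemble` (nm).

    The ensemble label defaults to the file stem.  Raises
    :class:`TopologyError` naming the first model whose atom list differs
    from model 1, and :class:`ParseError` (with a line number) for malformed
    atom records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_records(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{path}: no models found")

    topology: list[Atom] | None = None
    frames: list[Frame] = []
    any_dropped = False
    for model_pos, model in enumerate(structure):
        atoms, coords, dropped = _model_atoms(model)
        any_dropped = any_dropped or dropped
        if topology is None:
            if not atoms:
                raise ParseError(f"{path}: first model contains no atoms")
            topology = atoms
        elif [a.key for a in atoms] != [a.key for a in topology]:
            raise TopologyError(
                f"{path}: model {model.num} (position {model_pos + 1}) has an "
                f"atom list inconsistent with the first model"
            )
        frames.append(Frame(coordinates=coords / 10.0, model_index=model_pos))
    if any_dropped:
        warnings.warn(
            f"{path}: alternate locations other than ' '/'A' were dropped",
            stacklevel=2,
        )
    assert topology is not None
    return Ensemble(
        label=label if label is not None else path.stem,
        topology=topology,
        frames=frames,
        frame_spacing=frame_spacing,
    )


def write_multimodel(
    ensemble: Ensemble,
    path: str | Path,
    frame_indices: list[int] | None = None,
    *,
    remark: str | None = None,
) -> None:
    """Write frames of ``ensemble`` as a multi-model PDB file (Å on disk).

    ``frame_indices`` selects and orders the frames to write (default: all).
    Occupancy and B-factor are written as 1.00 / 0.00.  Round trip:
    ``read_multimodel(write_multimodel(E))`` reproduces the topology exactly
    and coordinates to 3 decimals in Å (1e-4 nm).
    """
    if frame_indices is not None:
        if len(frame_indices) == 0:
            raise ValueError("frame_indices must not be empty")
        for idx in frame_indices:
            if not 0 <= idx < ensemble.n_frames:
                raise IndexError(f"frame index {idx} out of range")
        indices = list(frame_indices)
    else:
        indices = list(range(ensemble.n_frames))

    structure = gemmi.Structure()
    structure.name = ensemble.label
    if remark:
        structure.raw_remarks = [f"REMARK   6 {remark}"]
    for model_num, frame_idx in enumerate(indices, start=1):
        frame = ensemble.frames[frame_idx]
        model = gemmi.Model(model_num)
        chain: gemmi.Chain | None = None
        residue: gemmi.Residue | None = None
        current_res: tuple[str, int, str] | None = None
        for atom_meta, xyz in zip(ensemble.topology, frame.coordinates):
            if chain is None or chain.name != atom_meta.chain_id:
                chain = gemmi.Chain(atom_meta.chain_id)
                model.add_chain(chain)
                chain = model[-1]
                current_res = None
            if current_res != atom_meta.residue_id:
                residue = gemmi.Residue()
                residue.name = atom_meta.residue_name
                residue.seqid = gemmi.SeqId(
                    atom_meta.residue_number, atom_meta.insertion_code or " "
                )
                chain.add_residue(residue)
                residue = chain[-1]
                current_res = atom_meta.residue_id
            atom = gemmi.Atom()
            atom.name = atom_meta.atom_name
            atom.element = gemmi.Element(atom_meta.element or "X")
            atom.pos = gemmi.Position(*(np.asarray(xyz) * 10.0))
            atom.occ = 1.0
            atom.b_iso = 0.0
            residue.add_atom(atom)
        structure.add_model(model)
    try:
        structure.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def read_xyz_frames(
    path: str | Path,
    topology: list[Atom],
    *,
    label: str | None = None,
    frame_spacing: float = 2.0,
) -> Ensemble:
    """Read the plain whitespace-delimited XYZ-per-frame dialect (nm).

    Each frame is ``n_atoms`` lines of ``x y z``; frames are separated by
    blank lines or by a line containing only the atom count.  Intended for
    synthetic fixtures, not for structures from the wild.
    """
    path = Path(path)
    n = len(topology)
    rows: list[list[float]] = []
    frames: list[Frame] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            parts = line.split()
            if not parts or (len(parts) == 1 and parts[0] == str(n)):
                continue
            if len(parts) != 3:
                raise ParseError(
                    f"{path}, line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: unparseable coordinate"
                ) from None
            if len(rows) == n:
                frames.append(
                    Frame(coordinates=np.asarray(rows), model_index=len(frames))
                )
                rows = []
    if rows:
        raise ParseError(f"{path}: trailing partial frame of {len(rows)} atoms")
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Ensemble(
        label=label if label is not None else path.stem,
        topology=topology,
        frames=frames,
        frame_spacing=frame_spacing,
    )
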