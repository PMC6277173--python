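"""Core in-memory types shared by every analysis stage.

All coordinates handled by this package are in nanometres.  Conversion from
the ångström convention of PDB files happens exactly once, at the I/O
boundary (:mod:`cdrloop.io`), so the geometric criteria used downstream
(0.25 nm H-bond distance, 0.2 nm clustering cutoff, ...) can be applied
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CdrloopError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CdrloopError):
    """A file or expression could not be parsed."""


class TopologyError(CdrloopError):
    """Atom lists are inconsistent (across models or across ensembles)."""


class SelectionError(CdrloopError):
    """A selection expression is malformed or used out of contract."""


class DegenerateGeometryError(CdrloopError):
    """A geometric operation received degenerate input (collinear, < 3 atoms)."""


class MissingHydrogensError(CdrloopError):
    """H-bond analysis requires explicit hydrogens in the topology."""


@dataclass(frozen=True, slots=True)
class Atom:
    """One atom of a topology, identified in author (Kabat-compatible) numbering.

    ``insertion_code`` is the empty string for ordinary residues; Kabat
    insertions such as 100a carry a single letter.  The identity key used
    throughout is ``(chain_id, residue_number, insertion_code, atom_name)``.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""
    atom_name: str = ""
    element: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.atom_name)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def __str__(self) -> str:  # e.g. "H:94:NE", "H:100a:CA"
        res = f"{self.residue_number}{self.insertion_code}"
        return f"{self.chain_id}:{res}:{self.atom_name}"


@dataclass(frozen=True, slots=True)
class AtomId:
    """Reference to an atom by identity, resolvable on any compatible topology."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    atom_name: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.atom_name)

    def __str__(self) -> str:
        res = f"{self.residue_number}{self.insertion_code}"
        return f"{self.chain_id}:{res}:{self.atom_name}"


@dataclass(slots=True)
class Frame:
    """One conformation: an ``(n_atoms, 3)`` coordinate array in nm."""

    coordinates: np.ndarray
    model_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.model_index < 0:
            raise ValueError("model_index must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


def index_map(topology: list[Atom]) -> dict[tuple[str, int, str, str], int]:
    """Map each atom identity key to its position in topology order."""
    return {atom.key: i for i, atom in enumerate(topology)}


@dataclass(slots=True)
class Ensemble:
    """An ordered set of frames sharing one topology.

    ``frame_spacing`` is the time between stored frames in ps (metadata only;
    default 2 ps, the storage interval typical of the trajectories this
    package analyses).
    """

    label: str
    topology: list[Atom]
    frames: list[Frame]
    frame_spacing: float = 2.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("an Ensemble needs at least one frame")
        n = len(self.topology)
        for frame in self.frames:
            if frame.n_atoms != n:
                raise TopologyError(
                    f"frame with model_index {frame.model_index} has "
                    f"{frame.n_atoms} atoms, topology has {n}"
                )
        keys = [atom.key for atom in self.topology]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise TopologyError(f"duplicate atom identity {k} in topology")
                seen.add(k)
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """Stack all frames into an ``(n_frames, n_atoms, 3)`` array (nm)."""
        return np.stack([f.coordinates for f in self.frames])
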