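"""Geometric hydrogen-bond and parallel-stacking detection, with occurrence
statistics over ensembles.

The criteria are purely geometric and evaluated per frame:

* H-bond — hydrogen-acceptor distance strictly below 0.25 nm AND
  donor-hydrogen-acceptor angle strictly above 135 deg.  Both inequalities
  are strict; the boundary geometries (0.25 nm, 135 deg) do NOT count.
* parallel stacking — distance between the centers of geometry of the two
  planar sidechain groups at most 0.5 nm AND inter-plane angle at most
  30 deg.  Both inequalities are inclusive.

Occurrence is the fraction of frames in which the criterion holds.  An
interaction whose atoms do not exist on a topology (e.g. the partner residue
was mutated away in that variant) is reported as not-applicable — distinctly
from an occurrence of zero.

No periodic-boundary minimum-image convention is applied anywhere: input
ensembles must contain a gathered (whole) solute.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Atom,
    AtomId,
    DegenerateGeometryError,
    Ensemble,
    Frame,
    MissingHydrogensError,
    index_map,
)
from .geometry import angle, plane_angle, plane_fit
from .selection import Selection


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond thresholds; both tests are strict inequalities."""

    max_ha_distance: float = 0.25  # nm
    min_dha_angle: float = 135.0  # degrees

    def __post_init__(self) -> None:
        if self.max_ha_distance < 0:
            raise ValueError("max_ha_distance must be >= 0")
        if not 0 < self.min_dha_angle < 180:
            raise ValueError("min_dha_angle must be in (0, 180)")


@dataclass(frozen=True)
class StackingCriterion:
    """Parallel-stacking thresholds; both tests are inclusive."""

    max_centroid_distance: float = 0.5  # nm
    max_plane_angle: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.max_centroid_distance <= 0:
            raise ValueError("max_centroid_distance must be positive")
        if not 0 < self.max_plane_angle <= 90:
            raise ValueError("max_plane_angle must be in (0, 90]")


@dataclass(frozen=True)
class HBondTriplet:
    """Donor, covalently attached hydrogen, and acceptor.

    The hydrogen-donor covalency is declared by construction (atom-name
    conventions, e.g. HE belongs to NE in arginine), never inferred from
    distances.
    """

    donor: AtomId
    hydrogen: AtomId
    acceptor: AtomId

    def __post_init__(self) -> None:
        keys = {self.donor.key, self.hydrogen.key, self.acceptor.key}
        if len(keys) != 3:
            raise ValueError("donor, hydrogen and acceptor must be distinct atoms")

    @property
    def interaction_id(self) -> str:
        return f"{self.donor}--{self.hydrogen}..{self.acceptor}"


# Planar sidechain groups (atom names) per residue type.  Arg's guanidinium
# excludes CD by default; the table is a module-level constant a caller can
# copy and extend.
PLANAR_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class PlanarGroup:
    """A planar sidechain moiety of one residue, named by its member atoms."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    atom_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.atom_names) < 3:
            raise ValueError("a PlanarGroup needs at least 3 atoms")

    @property
    def group_id(self) -> str:
        res = f"{self.residue_number}{self.insertion_code}"
        return f"{self.chain_id}:{res}:{'+'.join(self.atom_names)}"

    def atom_ids(self) -> list[AtomId]:
        return [
            AtomId(self.chain_id, self.residue_number, self.insertion_code, name)
            for name in self.atom_names
        ]


def planar_group_for(topology: list[Atom], residue_id: tuple[str, int, str]) -> PlanarGroup:
    """Build the standard planar group for a residue found on ``topology``."""
    chain_id, resnum, icode = residue_id
    resname = None
    for atom in topology:
        if atom.residue_id == residue_id:
            resname = atom.residue_name.upper()
            break
    if resname is None:
        raise LookupError(f"residue {residue_id} not in topology")
    if resname not in PLANAR_GROUP_ATOMS:
        raise LookupError(f"no planar group defined for residue type {resname}")
    return PlanarGroup(chain_id, resnum, icode, PLANAR_GROUP_ATOMS[resname])


# ---------------------------------------------------------------------------
# per-frame detection
# ---------------------------------------------------------------------------

def _resolve_triplet(
    topology: list[Atom], triplet: HBondTriplet
) -> tuple[int, int, int]:
    amap = index_map(topology)
    missing = [aid for aid in (triplet.donor, triplet.hydrogen, triplet.acceptor)
               if aid.key not in amap]
    if missing:
        if any(aid.key == triplet.hydrogen.key for aid in missing):
            hyd = triplet.hydrogen
            # distinguish "no such hydrogen" from genuinely absent residue
            donor_present = triplet.donor.key in amap
            if donor_present:
                raise MissingHydrogensError(
                    f"hydrogen {hyd} not in topology; H-bond analysis needs "
                    f"explicit hydrogens"
                )
        raise LookupError(
            "atoms not in topology: " + ", ".join(str(a) for a in missing)
        )
    h_idx = amap[triplet.hydrogen.key]
    if topology[h_idx].element.upper() not in ("H", "D", ""):
        raise MissingHydrogensError(
            f"atom {triplet.hydrogen} has element "
            f"{topology[h_idx].element!r}, expected a hydrogen"
        )
    return amap[triplet.donor.key], h_idx, amap[triplet.acceptor.key]


def hbond_geometry(
    frame: Frame, topology: list[Atom], triplet: HBondTriplet
) -> tuple[float, float]:
    """Return (hydrogen-acceptor distance in nm, D-H-A angle in degrees)."""
    d, h, a = _resolve_triplet(topology, triplet)
    coords = frame.coordinates
    dist = float(np.linalg.norm(coords[h] - coords[a]))
    ang = angle(coords[d], coords[h], coords[a])
    return dist, ang


def detect_hbond(
    frame: Frame,
    topology: list[Atom],
    triplet: HBondTriplet,
    criterion: HBondCriterion = HBondCriterion(),
) -> bool:
    """True iff d(H, A) < max_ha_distance and angle(D-H-A) > min_dha_angle."""
    dist, ang = hbond_geometry(frame, topology, triplet)
    return dist < criterion.max_ha_distance and ang > criterion.min_dha_angle


def _resolve_group(topology: list[Atom], group: PlanarGroup) -> np.ndarray:
    amap = index_map(topology)
    indices = []
    for aid in group.atom_ids():
        if aid.key not in amap:
            raise LookupError(f"planar-group atom {aid} not in topology")
        indices.append(amap[aid.key])
    return np.asarray(indices, dtype=np.intp)


def detect_stacking(
    frame: Frame,
    topology: list[Atom],
    group_a: PlanarGroup,
    group_b: PlanarGroup,
    criterion: StackingCriterion = StackingCriterion(),
) -> bool:
    """True iff centroid distance <= 0.5 nm and plane angle <= 30 deg
    (inclusive, with the default criterion)."""
    ia = _resolve_group(topology, group_a)
    ib = _resolve_group(topology, group_b)
    ca, na = plane_fit(frame.coordinates[ia])
    cb, nb = plane_fit(frame.coordinates[ib])
    dist = float(np.linalg.norm(ca - cb))
    ang = plane_angle(na, nb)
    return dist <= criterion.max_centroid_distance and ang <= criterion.max_plane_angle


# ---------------------------------------------------------------------------
# occurrence tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "ensemble", "interaction_id", "n_frames", "n_hits", "fraction", "percent", "status",
]


def _occurrence_row(label: str, iid: str, n_frames: int, n_hits: int | None) -> dict:
    if n_hits is None:
        return {
            "ensemble": label, "interaction_id": iid, "n_frames": n_frames,
            "n_hits": 0, "fraction": np.nan, "percent": np.nan, "status": "na",
        }
    frac = n_hits / n_frames
    return {
        "ensemble": label, "interaction_id": iid, "n_frames": n_frames,
        "n_hits": n_hits, "fraction": frac, "percent": 100.0 * frac, "status": "ok",
    }


def hbond_occurrence(
    ensembles: list[Ensemble],
    triplets: list[HBondTriplet],
    criterion: HBondCriterion = HBondCriterion(),
) -> pd.DataFrame:
    """Fraction of frames satisfying the H-bond criterion, per triplet per
    ensemble.

    Triplets whose atoms are absent on an ensemble's topology (a mutated
    residue) get ``status='na'`` and NaN fraction — distinct from an
    occurrence of zero.
    """
    rows = []
    for ens in ensembles:
        coords = ens.coords_array()
        for triplet in triplets:
            try:
                d, h, a = _resolve_triplet(ens.topology, triplet)
            except LookupError:
                rows.append(_occurrence_row(ens.label, triplet.interaction_id,
                                            ens.n_frames, None))
                continue
            ha = coords[:, h, :] - coords[:, a, :]
            dist = np.linalg.norm(ha, axis=1)
            vd = coords[:, d, :] - coords[:, h, :]
            va = coords[:, a, :] - coords[:, h, :]
            cosang = np.sum(vd * va, axis=1) / (
                np.linalg.norm(vd, axis=1) * np.linalg.norm(va, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            hits = int(np.sum((dist < criterion.max_ha_distance)
                              & (ang > criterion.min_dha_angle)))
            rows.append(_occurrence_row(ens.label, triplet.interaction_id,
                                        ens.n_frames, hits))
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def stacking_occurrence(
    ensembles: list[Ensemble],
    pairs: list[tuple[PlanarGroup, PlanarGroup]],
    criterion: StackingCriterion = StackingCriterion(),
) -> pd.DataFrame:
    """Fraction (and percent) of frames in a parallel-stacked arrangement,
    per planar-group pair per ensemble; NA semantics as for H-bonds."""
    rows = []
    for ens in ensembles:
        for group_a, group_b in pairs:
            iid = f"{group_a.group_id}||{group_b.group_id}"
            try:
                ia = _resolve_group(ens.topology, group_a)
                ib = _resolve_group(ens.topology, group_b)
            except LookupError:
                rows.append(_occurrence_row(ens.label, iid, ens.n_frames, None))
                continue
            hits = 0
            for frame in ens.frames:
                ca, na_ = plane_fit(frame.coordinates[ia])
                cb, nb_ = plane_fit(frame.coordinates[ib])
                if (np.linalg.norm(ca - cb) <= criterion.max_centroid_distance
                        and plane_angle(na_, nb_) <= criterion.max_plane_angle):
                    hits += 1
            rows.append(_occurrence_row(ens.label, iid, ens.n_frames, hits))
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_occurrence_table(table: pd.DataFrame, path) -> None:
    """Write an occurrence table as tidy TSV (6 significant digits)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# triplet enumeration
# ---------------------------------------------------------------------------

# Protein donor table: donor heavy atom -> names of hydrogens covalently
# attached to it, by residue type.  Backbone amide N-H is handled for every
# residue type; N-terminal H1/H2/H3 are accepted as backbone hydrogens too.
BACKBONE_DONOR_HYDROGENS: tuple[str, ...] = ("H", "HN", "H1", "H2", "H3")

SIDECHAIN_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "TRP": {"NE1": ("HE1",)},
}

# Acceptor table: backbone carbonyl O (and terminal OXT) for every residue,
# plus sidechain O/N lone-pair bearers.
BACKBONE_ACCEPTORS: tuple[str, ...] = ("O", "OXT")

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


def _residues(topology: list[Atom]) -> dict[tuple[str, int, str], dict[str, int]]:
    out: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, atom in enumerate(topology):
        out.setdefault(atom.residue_id, {})[atom.atom_name.upper()] = i
    return out


def enumerate_triplets(
    topology: list[Atom],
    focus_selection: Selection,
    *,
    donors: dict[str, dict[str, tuple[str, ...]]] | None = None,
    acceptors: dict[str, tuple[str, ...]] | None = None,
    include_intra_residue: bool = False,
) -> list[HBondTriplet]:
    """Enumerate donor-H-acceptor triplets where donor or acceptor lies in
    ``focus_selection``.

    The donor/acceptor tables (module constants, overridable) declare the
    hydrogen-donor covalency by atom-name convention.  Intra-residue
    donor/acceptor pairs are skipped unless requested.  If the topology
    carries no hydrogens at all, an empty list is returned with a warning.
    """
    donors = donors if donors is not None else SIDECHAIN_DONORS
    acceptors = acceptors if acceptors is not None else SIDECHAIN_ACCEPTORS
    if not any(a.element.upper() == "H" or a.atom_name.upper().startswith("H")
               for a in topology):
        warnings.warn("topology contains no hydrogens; no donors available",
                      stacklevel=2)
        return []
    focus = set(focus_selection.indices.tolist())
    residues = _residues(topology)
    resname_of = {a.residue_id: a.residue_name.upper() for a in topology}

    donor_triples: list[tuple[tuple[str, int, str], int, int]] = []  # (rid, d, h)
    acceptor_atoms: list[tuple[tuple[str, int, str], int]] = []  # (rid, a)
    for rid, atoms in residues.items():
        resname = resname_of[rid]
        donor_table = dict(donors.get(resname, {}))
        if "N" in atoms:
            donor_table.setdefault("N", BACKBONE_DONOR_HYDROGENS)
        for donor_name, hydrogen_names in donor_table.items():
            if donor_name not in atoms:
                continue
            for hname in hydrogen_names:
                if hname in atoms:
                    donor_triples.append((rid, atoms[donor_name], atoms[hname]))
        for acc_name in BACKBONE_ACCEPTORS + acceptors.get(resname, ()):
            if acc_name in atoms:
                acceptor_atoms.append((rid, atoms[acc_name]))

    triplets: list[HBondTriplet] = []
    for (drid, d, h), (arid, a) in itertools.product(donor_triples, acceptor_atoms):
        if drid == arid and not include_intra_residue:
            continue
        if d not in focus and a not in focus:
            continue
        if a in (d, h):
            continue
        triplets.append(
            HBondTriplet(
                donor=_atom_id(topology[d]),
                hydrogen=_atom_id(topology[h]),
                acceptor=_atom_id(topology[a]),
            )
        )
    return triplets


def _atom_id(atom: Atom) -> AtomId:
    return AtomId(atom.chain_id, atom.residue_number, atom.insertion_code, atom.atom_name)
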