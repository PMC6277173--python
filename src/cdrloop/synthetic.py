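"""Synthetic conformational ensembles and interaction fixtures with known
ground truth.

Real variant trajectories are not redistributable, so every pipeline stage
is exercised on generated data that emulates their statistical structure:

* a toy loop system — a rigid "framework" scaffold (the superposition fit
  region) plus a loop of pseudo-residues numbered 95-102 in the antibody
  (Kabat-style) convention;
* per variant, frames drawn from a small number of distinct loop templates
  with variant-specific mixture weights, isotropic Gaussian coordinate noise
  on the loop atoms, and a random rigid-body motion of the whole molecule
  per frame (so nothing downstream may rely on lab-frame coordinates);
* exact-geometry donor-H-acceptor triads and planar-ring pairs for probing
  the interaction criteria at and around their thresholds.

All randomness flows through :class:`numpy.random.Generator` seeded from the
caller's seed; each ensemble label gets an independent stream derived from
(seed, label), so adding a label never perturbs the frames of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Atom, AtomId, Ensemble, Frame
from .interactions import HBondTriplet, PlanarGroup
from .selection import resolve_selection

_LOOP_FIRST_RESIDUE = 95  # default loop numbering: residues 95-102


@dataclass
class LoopSystem:
    """A toy loop-plus-framework topology with its canonical selections."""

    topology: list[Atom]
    base_frame: Frame
    loop_expression: str
    fit_expression: str

    @property
    def loop_indices(self) -> np.ndarray:
        return resolve_selection(self.loop_expression, self.topology).indices

    @property
    def fit_indices(self) -> np.ndarray:
        return resolve_selection(self.fit_expression, self.topology).indices


def _label_stream(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.blake2s(label.encode(), digest_size=4).digest()
    label_key = int.from_bytes(digest, "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), label_key]))


def make_loop_system(
    n_loop_residues: int = 8,
    n_fit_atoms: int = 12,
    seed: int = 0,
) -> LoopSystem:
    """Build a deterministic toy topology: framework scaffold + loop.

    Loop residues are numbered from 95 (so the default 8 residues span
    95-102) with backbone N/CA/C/O plus CB; framework residues flank the
    loop on both sides with N/CA/C backbone atoms.  ``n_fit_atoms`` is a
    minimum (at least 9, rounded up to whole residues).  Identical seeds
    give bit-identical coordinates.
    """
    if n_loop_residues < 3:
        raise ValueError("need at least 3 loop residues")
    if n_fit_atoms < 9:
        raise ValueError("need at least 9 fit atoms for a non-degenerate fit")
    rng = np.random.default_rng(seed)
    n_fit_res = -(-n_fit_atoms // 3)  # ceil
    n_before = -(-n_fit_res // 2)
    n_after = n_fit_res - n_before
    if n_after == 0:
        n_before -= 1
        n_after = 1

    loop_start = _LOOP_FIRST_RESIDUE
    loop_end = loop_start + n_loop_residues - 1
    residue_numbers = (
        [(n, "GLY") for n in range(loop_start - n_before, loop_start)]
        + [(n, "ALA") for n in range(loop_start, loop_end + 1)]
        + [(n, "GLY") for n in range(loop_end + 1, loop_end + 1 + n_after)]
    )

    topology: list[Atom] = []
    coords: list[np.ndarray] = []
    for j, (resnum, resname) in enumerate(residue_numbers):
        in_loop = loop_start <= resnum <= loop_end
        # CA trace along x with a zig-zag in y/z; the loop bulges out in y
        ca = np.array([0.38 * j, 0.12 * (-1) ** j, 0.05 * (j % 3)])
        if in_loop:
            t = (resnum - loop_start + 1) / (n_loop_residues + 1)
            ca = ca + np.array([0.0, 0.45 * np.sin(np.pi * t), 0.1 * np.sin(2 * np.pi * t)])
        offsets = {
            "N": np.array([-0.12, 0.08, 0.02]),
            "CA": np.zeros(3),
            "C": np.array([0.12, 0.08, -0.02]),
            "O": np.array([0.16, 0.19, -0.02]),
            "CB": np.array([0.0, -0.10, 0.12]),
        }
        names = ("N", "CA", "C", "O", "CB") if in_loop else ("N", "CA", "C")
        for name in names:
            jitter = rng.normal(0.0, 0.01, size=3)
            topology.append(
                Atom(
                    chain_id="H",
                    residue_number=resnum,
                    insertion_code="",
                    residue_name=resname,
                    atom_name=name,
                    element=name[0],
                )
            )
            coords.append(ca + offsets[name] + jitter)

    base = Frame(coordinates=np.asarray(coords), model_index=0)
    fit_expression = (
        f"(resi {loop_start - n_before}-{loop_start - 1} "
        f"or resi {loop_end + 1}-{loop_end + n_after}) and name N,CA,C"
    )
    return LoopSystem(
        topology=topology,
        base_frame=base,
        loop_expression=f"resi {loop_start}-{loop_end}",
        fit_expression=fit_expression,
    )


def make_template_set(
    system: LoopSystem, n_templates: int, separation: float = 0.5
) -> list[np.ndarray]:
    """Distinct loop conformations with pairwise fitted RMSD >= separation.

    Template ``i`` displaces every loop atom by a constant vector while the
    framework stays put, so the fitted RMSD between two templates equals the
    displacement difference exactly.  Supports up to 4 templates (vertex
    vectors 0, s*ex, s*ey, s*ez with s = separation).
    """
    if not 1 <= n_templates <= 4:
        raise ValueError("n_templates must be between 1 and 4")
    if separation <= 0:
        raise ValueError("separation must be positive")
    offsets = [np.zeros(3)]
    for axis in range(3):
        vec = np.zeros(3)
        vec[axis] = separation
        offsets.append(vec)
    loop_idx = system.loop_indices
    templates = []
    for k in range(n_templates):
        coords = system.base_frame.coordinates.copy()
        coords[loop_idx] += offsets[k]
        templates.append(coords)
    return templates


@dataclass
class TemplateMixtureSpec:
    """Study conditions for a multi-variant synthetic collection.

    Defaults reproduce the recovery experiment the package is validated on:
    loop-only Gaussian noise of 0.03 nm per axis, 500 frames per variant,
    and unrestricted rigid-body jitter (rotations up to 180 deg,
    translations up to 2 nm) so superposition has real work to do.
    """

    topology: list[Atom]
    templates: list[np.ndarray]  # full-coordinate frames sharing the topology
    loop_indices: np.ndarray  # noise is applied to these atoms only
    mixture_weights: dict[str, np.ndarray]  # ensemble label -> weights over templates
    noise_sigma: float = 0.03  # nm, per axis
    max_rotation_deg: float = 180.0
    max_translation_nm: float = 2.0
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.loop_indices = np.asarray(self.loop_indices, dtype=np.intp)
        k = len(self.templates)
        if k < 1:
            raise ValueError("need at least one template")
        weights = {}
        for label, w in self.mixture_weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != k:
                raise ValueError(f"weights for {label!r} must have length {k}")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError(f"weights for {label!r} must be >= 0 and sum to 1")
            weights[label] = w
        self.mixture_weights = weights
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually did, frame by frame."""

    template_labels: dict[str, np.ndarray]  # label -> template index per frame
    transforms: dict[str, list[tuple[np.ndarray, np.ndarray]]]  # (R, t) per frame
    interaction_flags: dict[str, np.ndarray] | None = None


def _random_rigid(rng: np.random.Generator, max_rot_deg: float,
                  max_trans: float) -> tuple[np.ndarray, np.ndarray]:
    if max_rot_deg > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, np.radians(max_rot_deg))
        rot = Rotation.from_rotvec(axis * angle).as_matrix()
    else:
        rot = np.eye(3)
    trans = rng.uniform(-max_trans, max_trans, size=3) if max_trans > 0 else np.zeros(3)
    return rot, trans


def sample_mixture_ensembles(
    spec: TemplateMixtureSpec,
) -> tuple[list[Ensemble], GroundTruth]:
    """Draw one ensemble per label from the template mixture.

    Per frame: pick a template by the label's weights, add N(0, sigma^2)
    noise to each loop-atom coordinate, then apply a random rigid motion to
    ALL atoms.  Fully reproducible from (spec, seed) with independent
    per-label streams.
    """
    ensembles: list[Ensemble] = []
    labels_out: dict[str, np.ndarray] = {}
    transforms_out: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for label, weights in spec.mixture_weights.items():
        rng = _label_stream(spec.seed, label)
        picks = rng.choice(len(spec.templates), size=spec.n_frames, p=weights)
        frames = []
        transforms = []
        for i, pick in enumerate(picks):
            coords = spec.templates[pick].copy()
            if spec.noise_sigma > 0:
                coords[spec.loop_indices] += rng.normal(
                    0.0, spec.noise_sigma, size=(len(spec.loop_indices), 3)
                )
            rot, trans = _random_rigid(rng, spec.max_rotation_deg,
                                       spec.max_translation_nm)
            coords = coords @ rot.T + trans
            frames.append(Frame(coordinates=coords, model_index=i))
            transforms.append((rot, trans))
        ensembles.append(
            Ensemble(label=label, topology=spec.topology, frames=frames)
        )
        labels_out[label] = picks
        transforms_out[label] = transforms
    return ensembles, GroundTruth(template_labels=labels_out,
                                  transforms=transforms_out)


# ---------------------------------------------------------------------------
# interaction fixtures
# ---------------------------------------------------------------------------

_HEXAGON_RADIUS = 0.14  # nm; regular hexagon edge == circumradius
_DH_BOND = 0.10  # nm donor-hydrogen bond length


def _hexagon(radius: float = _HEXAGON_RADIUS) -> np.ndarray:
    angles = np.radians(np.arange(0, 360, 60))
    return np.column_stack([radius * np.cos(angles), radius * np.sin(angles),
                            np.zeros(6)])


def make_hbond_fixture(
    d_ha: float, angle_dha: float
) -> tuple[list[Atom], Frame, HBondTriplet]:
    """A donor-H-acceptor triad with exactly the requested geometry.

    The donor-hydrogen bond is 0.10 nm; the acceptor is placed so that the
    hydrogen-acceptor distance is ``d_ha`` (nm) and the D-H-A angle is
    ``angle_dha`` (degrees).  The realised geometry is self-checked to
    1e-9 before the fixture is returned.
    """
    if d_ha <= 0:
        raise ValueError("d_ha must be positive")
    if not 0 < angle_dha <= 180:
        raise ValueError("angle_dha must be in (0, 180]")
    # The hydrogen sits at the origin so the H-A distance is an exact
    # floating-point product; the realised geometry is then nudged by ulps so
    # that rounding never puts a boundary probe on the wrong side of the
    # requested values (distance never below d_ha, angle never above
    # angle_dha) — the criterion is strict, so the exact boundary must fail.
    hydrogen = np.zeros(3)
    donor = np.array([-_DH_BOND, 0.0, 0.0])
    from .geometry import angle as _angle  # local import avoids a cycle

    def _build(angle_deg: float) -> np.ndarray:
        alpha = np.radians(angle_deg)
        direction = np.array([np.cos(np.pi - alpha), np.sin(np.pi - alpha), 0.0])
        direction /= np.linalg.norm(direction)
        dist_eff = d_ha
        for _ in range(100):
            candidate = dist_eff * direction
            if np.linalg.norm(candidate - hydrogen) >= d_ha:
                return candidate
            dist_eff = np.nextafter(dist_eff, np.inf)
        return candidate

    angle_eff = angle_dha
    for _ in range(100):
        acceptor = _build(angle_eff)
        if _angle(donor, hydrogen, acceptor) <= angle_dha:
            break
        angle_eff = np.nextafter(angle_eff, 0.0)
    topology = [
        Atom("H", 94, "", "ARG", "NE", "N"),
        Atom("H", 94, "", "ARG", "HE", "H"),
        Atom("H", 31, "", "ASP", "OD1", "O"),
    ]
    frame = Frame(coordinates=np.stack([donor, hydrogen, acceptor]))
    triplet = HBondTriplet(
        donor=AtomId("H", 94, "", "NE"),
        hydrogen=AtomId("H", 94, "", "HE"),
        acceptor=AtomId("H", 31, "", "OD1"),
    )
    from .interactions import hbond_geometry  # local import avoids a cycle

    dist, ang = hbond_geometry(frame, topology, triplet)
    assert abs(dist - d_ha) < 1e-9 and abs(ang - angle_dha) < 1e-9, (
        "fixture self-check failed"
    )
    return topology, frame, triplet


def make_ring_pair_fixture(
    centroid_distance: float, tilt: float
) -> tuple[list[Atom], Frame, PlanarGroup, PlanarGroup]:
    """Two regular hexagonal rings at an exact centroid separation and
    inter-plane angle (degrees); self-checked to 1e-9."""
    if centroid_distance <= 0:
        raise ValueError("centroid_distance must be positive")
    if not 0 <= tilt <= 90:
        raise ValueError("tilt must be in [0, 90]")
    from .geometry import plane_angle as _plane_angle, plane_fit as _plane_fit

    ring_a = _hexagon()
    # Nudge the realised tilt/separation by ulps so rounding never pushes a
    # boundary probe past the requested values: the stacking criterion is
    # inclusive, so the exact boundary must still satisfy it.
    tilt_eff = tilt
    for _ in range(100):
        tilt_rot = Rotation.from_euler("x", tilt_eff, degrees=True).as_matrix()
        ring_b = _hexagon() @ tilt_rot.T
        if _plane_angle(_plane_fit(ring_a)[1], _plane_fit(ring_b)[1]) <= tilt:
            break
        tilt_eff = np.nextafter(tilt_eff, 0.0)
    sep_eff = centroid_distance
    for _ in range(100):
        shifted = ring_b + np.array([0.0, 0.0, sep_eff])
        gap = np.linalg.norm(_plane_fit(shifted)[0] - _plane_fit(ring_a)[0])
        if gap <= centroid_distance:
            ring_b = shifted
            break
        sep_eff = np.nextafter(sep_eff, 0.0)
    else:
        ring_b = shifted
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    topology = [Atom("H", 27, "", "TYR", n, n[0]) for n in ring_names] + [
        Atom("H", 102, "", "TYR", n, n[0]) for n in ring_names
    ]
    frame = Frame(coordinates=np.concatenate([ring_a, ring_b]))
    group_a = PlanarGroup("H", 27, "", ring_names)
    group_b = PlanarGroup("H", 102, "", ring_names)
    from .geometry import plane_angle, plane_fit  # self-check

    ca, na = plane_fit(ring_a)
    cb, nb = plane_fit(ring_b)
    assert abs(np.linalg.norm(ca - cb) - centroid_distance) < 1e-9
    assert abs(plane_angle(na, nb) - tilt) < 1e-9
    return topology, frame, group_a, group_b


def make_interaction_ensemble(
    hbond_fraction: float = 0.4,
    stacking_fraction: float = 0.2,
    n_frames: int = 100,
    seed: int = 0,
    *,
    rigid_jitter: bool = True,
    label: str = "synthetic",
) -> tuple[Ensemble, HBondTriplet, tuple[PlanarGroup, PlanarGroup], GroundTruth]:
    """An ensemble with deterministically labelled interacting frames.

    Exactly ``round(fraction * n_frames)`` frames satisfy each criterion:
    H-bonded frames use (0.18 nm, 180 deg) vs (0.40 nm, 180 deg) otherwise;
    stacked frames use (0.35 nm, 0 deg) vs (0.80 nm, 0 deg).  A random rigid
    motion is applied per frame by default, which must not change any
    occurrence value.
    """
    for name, frac in (("hbond_fraction", hbond_fraction),
                       ("stacking_fraction", stacking_fraction)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = _label_stream(seed, label)
    n_hb = round(hbond_fraction * n_frames)
    n_st = round(stacking_fraction * n_frames)
    hb_flags = np.arange(n_frames) < n_hb
    st_flags = np.arange(n_frames) < n_st

    triad_on = make_hbond_fixture(0.18, 180.0)
    triad_off = make_hbond_fixture(0.40, 180.0)
    rings_on = make_ring_pair_fixture(0.35, 0.0)
    rings_off = make_ring_pair_fixture(0.80, 0.0)
    ring_shift = np.array([5.0, 0.0, 0.0])  # keep the two fixtures apart

    topology = triad_on[0] + rings_on[0]
    frames = []
    for i in range(n_frames):
        triad = (triad_on if hb_flags[i] else triad_off)[1].coordinates
        rings = (rings_on if st_flags[i] else rings_off)[1].coordinates + ring_shift
        coords = np.concatenate([triad, rings])
        if rigid_jitter:
            rot, trans = _random_rigid(rng, 180.0, 2.0)
            coords = coords @ rot.T + trans
        frames.append(Frame(coordinates=coords, model_index=i))
    ensemble = Ensemble(label=label, topology=topology, frames=frames)
    truth = GroundTruth(
        template_labels={label: hb_flags.astype(int)},
        transforms={label: []},
        interaction_flags={f"{label}:hbond": hb_flags, f"{label}:stacking": st_flags},
    )
    return ensemble, triad_on[2], (rings_on[2], rings_on[3]), truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write per-frame template labels and rigid-transform parameters as TSV."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("ensemble\tframe\ttemplate\trotvec_x\trotvec_y\trotvec_z"
                     "\ttrans_x\ttrans_y\ttrans_z\n")
        for label, picks in truth.template_labels.items():
            transforms = truth.transforms.get(label, [])
            for i, pick in enumerate(picks):
                if i < len(transforms):
                    rot, trans = transforms[i]
                    rv = Rotation.from_matrix(rot).as_rotvec()
                else:
                    rv = np.zeros(3)
                    trans = np.zeros(3)
                fields = [label, str(i), str(int(pick))] + [
                    f"{v:.6g}" for v in (*rv, *trans)
                ]
                handle.write("\t".join(fields) + "\n")
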