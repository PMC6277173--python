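"""Geometric kernels: centers of geometry, rigid-body superposition,
selection-scoped RMSD, and plane fitting for planar sidechain groups.

Superposition is the classic least-squares rototranslational fit (Kabsch):
SVD of the covariance matrix of the centered fit coordinates, with a
determinant sign correction so that only proper rotations (no reflections)
are returned.  Fit weights are uniform — no mass weighting.

``fitted_rmsd`` is the workhorse of the conformational clustering: superpose
frame A onto frame B on one atom selection (framework backbone), then
measure the RMSD over another (the loop atoms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateGeometryError, Frame
from .selection import Selection

_DEG = 180.0 / np.pi


def _indices(selection: Selection | np.ndarray) -> np.ndarray:
    if isinstance(selection, Selection):
        return selection.indices
    return np.asarray(selection, dtype=np.intp)


@dataclass(frozen=True)
class SuperpositionResult:
    """A rigid transform ``x -> rotation @ x + translation`` plus its fit RMSD."""

    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,) nm
    fit_rmsd: float  # nm, over the fit atoms after transformation

    def transform(self, coordinates: np.ndarray) -> np.ndarray:
        """Apply the transform to an ``(n, 3)`` coordinate array (pure)."""
        return np.asarray(coordinates) @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        """The transform as a 3x4 matrix ``[R | t]`` for plain-text export."""
        return np.hstack([self.rotation, self.translation[:, None]])


def center_of_geometry(
    frame: Frame | np.ndarray, selection: Selection | np.ndarray | None = None
) -> np.ndarray:
    """Unweighted mean position of the selected atoms (nm)."""
    coords = frame.coordinates if isinstance(frame, Frame) else np.asarray(frame)
    if selection is not None:
        coords = coords[_indices(selection)]
    if coords.shape[0] == 0:
        raise DegenerateGeometryError("center_of_geometry of an empty selection")
    return coords.mean(axis=0)


def _check_fit_points(points: np.ndarray, what: str) -> None:
    if points.shape[0] < 3:
        raise DegenerateGeometryError(f"{what}: need at least 3 atoms")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise DegenerateGeometryError(f"{what}: fit atoms are (near-)collinear")


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    if d == 0:  # numerically singular; resolve toward proper rotation
        d = 1.0
    dmat = np.diag([1.0, 1.0, d])
    rotation = vt.T @ dmat @ u.T
    translation = rc - rotation @ mc
    # evaluate the residual explicitly: the closed-form GA+GB-2*sum(S)
    # expression cancels catastrophically near zero
    diff = x @ rotation.T - y
    fit_rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, fit_rmsd=fit_rmsd)


def superpose(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    fit_selection: Selection | np.ndarray | None = None,
    *,
    fit_selection_reference: Selection | np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rototranslational fit of ``mobile`` onto ``reference``.

    The selections must resolve to equal-count, correspondingly ordered atom
    sets (same selection on both topologies by default).  The returned
    transform minimises the RMSD over the fit atoms; applying it to the full
    frame is a separate, pure step (:meth:`SuperpositionResult.transform`).
    """
    mob = mobile.coordinates if isinstance(mobile, Frame) else np.asarray(mobile)
    ref = reference.coordinates if isinstance(reference, Frame) else np.asarray(reference)
    if fit_selection is not None:
        mob = mob[_indices(fit_selection)]
        sel_ref = fit_selection_reference if fit_selection_reference is not None else fit_selection
        ref = ref[_indices(sel_ref)]
    if mob.shape != ref.shape:
        raise DegenerateGeometryError(
            f"fit selections resolve to different atom counts: "
            f"{mob.shape[0]} vs {ref.shape[0]}"
        )
    _check_fit_points(mob, "superpose")
    return _kabsch(mob, ref)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting) between two (n, 3) arrays."""
    diff = np.asarray(a) - np.asarray(b)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def fitted_rmsd(
    frame_a: Frame | np.ndarray,
    frame_b: Frame | np.ndarray,
    fit_selection: Selection | np.ndarray,
    rmsd_selection: Selection | np.ndarray,
) -> float:
    """RMSD over ``rmsd_selection`` after a rototranslational fit on
    ``fit_selection`` (frame A superposed onto frame B).

    The least-squares minimum makes this symmetric in its arguments (to
    numerical precision) and invariant under rigid-body motion of either
    frame.
    """
    a = frame_a.coordinates if isinstance(frame_a, Frame) else np.asarray(frame_a)
    b = frame_b.coordinates if isinstance(frame_b, Frame) else np.asarray(frame_b)
    fit_idx = _indices(fit_selection)
    rmsd_idx = _indices(rmsd_selection)
    result = superpose(a[fit_idx], b[fit_idx])
    return rmsd(result.transform(a[rmsd_idx]), b[rmsd_idx])


def plane_fit(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >= 3 non-collinear points.

    Returns ``(centroid, unit_normal)``; the normal is the direction of
    smallest principal variance of the centered coordinates, so every ring
    atom contributes and the fit is stable under coordinate noise.  The sign
    of the normal is arbitrary (plane angles ignore it).
    """
    pts = np.asarray(coords, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane_fit: need at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise DegenerateGeometryError("plane_fit: points are (near-)collinear")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    return centroid, normal


def plane_angle(normal_a: np.ndarray, normal_b: np.ndarray) -> float:
    """Angle between two planes in degrees, in [0, 90].

    Computed as ``arccos(|n_a . n_b|)``: the orientation (sign) of either
    normal is irrelevant.
    """
    na = np.asarray(normal_a, dtype=float)
    nb = np.asarray(normal_b, dtype=float)
    norm_a = np.linalg.norm(na)
    norm_b = np.linalg.norm(nb)
    if norm_a < 1e-12 or norm_b < 1e-12:
        raise DegenerateGeometryError("plane_angle: zero-length normal")
    cosine = abs(float(na @ nb) / (norm_a * norm_b))
    return float(np.arccos(np.clip(cosine, 0.0, 1.0)) * _DEG)


def angle(point_a: np.ndarray, vertex: np.ndarray, point_b: np.ndarray) -> float:
    """Angle A-V-B at the vertex, in degrees."""
    va = np.asarray(point_a, dtype=float) - np.asarray(vertex, dtype=float)
    vb = np.asarray(point_b, dtype=float) - np.asarray(vertex, dtype=float)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateGeometryError("angle: coincident points")
    cosine = np.clip(float(va @ vb) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosine) * _DEG)
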