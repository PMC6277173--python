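"""Distance monitoring, snapshot extraction, and sidechain flexibility.

These are the per-variant observables used alongside the clustering: the
distance between the centre of geometry of an aromatic ring (each tyrosine
of the "tyrosine cage") and a probe atom of the residue of interest, its
distribution, the fraction of time it falls below a contact threshold
(default 0.4 nm), snapshot thinning (e.g. one frame per ns), and a
quantitative summary of the positional cloud a sidechain traces out after
superposition — per-atom RMSF plus covariance eigenvalues, whose anisotropy
distinguishes a "narrow, elliptical" cloud from an isotropic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Atom, AtomId, Ensemble, Frame, index_map
from .geometry import superpose
from .selection import Selection, resolve_selection

# Probe atoms monitored on residue 94h, by residue type: the "central"
# carbon/nitrogen/oxygen atoms of the sidechain head group.  Configurable;
# these defaults cover the arginine / lysine / threonine identities the
# variants take at that position.
DEFAULT_PROBE_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("CZ", "NE", "NH1", "NH2"),
    "LYS": ("CE", "NZ"),
    "THR": ("CB", "OG1"),
}


@dataclass
class DistanceSeries:
    """Per-frame distance (nm) between a ring centroid and a probe atom."""

    ensemble_label: str
    group_expression: str
    probe: AtomId
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and >= 0")


@dataclass
class DistanceHistogram:
    """Density-normalised uniform-bin histogram of a distance series."""

    bin_edges: np.ndarray  # nm, uniform width, grid anchored at 0
    densities: np.ndarray  # integrates to 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mass_below(self, threshold: float) -> float:
        """Integrated density below ``threshold`` (exact on bin edges)."""
        widths = np.diff(self.bin_edges)
        upper = np.minimum(self.bin_edges[1:], threshold)
        overlap = np.clip(upper - self.bin_edges[:-1], 0.0, None)
        return float(np.sum(self.densities * np.minimum(overlap, widths)))


@dataclass
class FlexibilitySummary:
    """Positional spread of a residue's atoms after a global fit.

    ``covariance_eigenvalues`` (nm^2, descending) describe the shape of the
    pooled positional cloud: one dominant eigenvalue means a narrow,
    elongated (elliptical) cloud; three comparable eigenvalues an isotropic
    one.
    """

    residue_label: str
    atoms: list[Atom]
    mean_positions: np.ndarray  # (n_atoms, 3) nm, after fitting
    rmsf: np.ndarray  # (n_atoms,) nm
    covariance_eigenvalues: np.ndarray  # (3,) nm^2, sorted descending

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"atom": str(a), "mean_x": m[0], "mean_y": m[1], "mean_z": m[2],
             "rmsf": r}
            for a, m, r in zip(self.atoms, self.mean_positions, self.rmsf)
        ]
        return pd.DataFrame(rows)


def distance_series(
    ensemble: Ensemble,
    ring_selection: str | Selection,
    probe_atoms: list[AtomId],
) -> list[DistanceSeries]:
    """Distance between the ring's centre of geometry and each probe atom,
    per frame; one series per probe."""
    if isinstance(ring_selection, Selection):
        ring = ring_selection
    else:
        ring = resolve_selection(ring_selection, ensemble.topology, allow_empty=False)
    if len(ring) < 3:
        raise ValueError("ring selection must contain at least 3 atoms")
    amap = index_map(ensemble.topology)
    probe_idx = []
    for probe in probe_atoms:
        if probe.key not in amap:
            raise LookupError(f"probe atom {probe} not in topology")
        probe_idx.append(amap[probe.key])
    coords = ensemble.coords_array()
    centroids = coords[:, ring.indices, :].mean(axis=1)  # (n_frames, 3)
    series = []
    for probe, idx in zip(probe_atoms, probe_idx):
        dist = np.linalg.norm(coords[:, idx, :] - centroids, axis=1)
        series.append(
            DistanceSeries(
                ensemble_label=ensemble.label,
                group_expression=ring.expression,
                probe=probe,
                values=dist,
            )
        )
    return series


def histogram(
    series: DistanceSeries | np.ndarray, bin_width: float = 0.01
) -> DistanceHistogram:
    """Density histogram on a uniform bin grid anchored at zero.

    The range is ``[floor(min), ceil(max)]`` on the grid; a constant series
    occupies a single bin of density ``1/bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series)
    if values.size == 0:
        raise ValueError("cannot histogram an empty series")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo + 0.5 * bin_width:  # all values on a single grid line
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    densities, edges = np.histogram(values, bins=edges, density=True)
    return DistanceHistogram(bin_edges=edges, densities=densities)


def below_threshold_fraction(
    series: DistanceSeries | np.ndarray, threshold: float = 0.4
) -> float:
    """Fraction of frames with distance strictly below ``threshold`` (nm)."""
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series)
    if values.size == 0:
        raise ValueError("empty series")
    return float(np.mean(values < threshold))


def extract_snapshots(ensemble: Ensemble, interval_ps: float = 1000.0) -> Ensemble:
    """Thin an ensemble to one frame every ``interval_ps`` picoseconds.

    With the default 2 ps frame spacing and a 1000 ps interval this keeps
    every 500th frame (one snapshot per ns).  Frame order and topology are
    preserved; the returned ensemble carries the widened spacing.
    """
    k = int(round(interval_ps / ensemble.frame_spacing))
    if k < 1:
        raise ValueError(
            f"snapshot interval {interval_ps} ps is smaller than the frame "
            f"spacing {ensemble.frame_spacing} ps"
        )
    frames = ensemble.frames[::k]
    return Ensemble(
        label=ensemble.label,
        topology=ensemble.topology,
        frames=frames,
        frame_spacing=ensemble.frame_spacing * k,
    )


def flexibility_summary(
    ensemble: Ensemble,
    fit_selection: str | Selection,
    residue_selection: str | Selection,
    reference: Frame | None = None,
) -> FlexibilitySummary:
    """Per-atom RMSF and positional covariance eigenvalues after fitting.

    Every frame is superposed onto ``reference`` (default: the ensemble's
    first frame) on ``fit_selection``; spread is then measured over the
    atoms of ``residue_selection`` in the fitted coordinates.  Eigenvalues
    are of the 3x3 covariance of the pooled per-atom displacement vectors.
    """
    if ensemble.n_frames < 2:
        raise ValueError("flexibility needs at least 2 frames")
    if not isinstance(fit_selection, Selection):
        fit_selection = resolve_selection(fit_selection, ensemble.topology,
                                          allow_empty=False)
    if not isinstance(residue_selection, Selection):
        residue_selection = resolve_selection(residue_selection, ensemble.topology,
                                              allow_empty=False)
    ref = reference if reference is not None else ensemble.frames[0]
    fitted = np.empty((ensemble.n_frames, len(residue_selection), 3))
    for i, frame in enumerate(ensemble.frames):
        sup = superpose(frame, ref, fit_selection)
        fitted[i] = sup.transform(frame.coordinates[residue_selection.indices])
    mean_positions = fitted.mean(axis=0)
    deviations = fitted - mean_positions
    rmsf = np.sqrt(np.mean(np.sum(deviations**2, axis=2), axis=0))
    pooled = deviations.reshape(-1, 3)
    cov = pooled.T @ pooled / pooled.shape[0]
    eigenvalues = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    atoms = [ensemble.topology[i] for i in residue_selection.indices]
    residue_label = "+".join(
        sorted({f"{a.chain_id}:{a.residue_number}{a.insertion_code}" for a in atoms})
    )
    return FlexibilitySummary(
        residue_label=residue_label,
        atoms=atoms,
        mean_positions=mean_positions,
        rmsf=rmsf,
        covariance_eigenvalues=eigenvalues,
    )
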