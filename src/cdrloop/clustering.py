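"""Joint conformational clustering of pooled variant ensembles.

The metric is the fitted RMSD of ``fitted_rmsd``: frames are superposed on
the framework fit selection (e.g. the backbone of the regions flanking the
loop), and the RMSD is measured over the analysis selection (e.g. all CDRh3
atoms, residues 95-102).  Frames with a fitted RMSD strictly below the
cutoff (default 0.2 nm) are structural neighbours.

Clustering follows the greedy neighbour-count algorithm of Daura et al.:
repeatedly take the remaining frame with the most remaining neighbours as
the central member structure (CMS) of the next cluster, remove it together
with its neighbours, and continue until no frames remain.  Ties on the
neighbour count are broken by the lowest pooled frame index (pooling order =
ensemble list order, then frame order), which makes the partition fully
deterministic.

Clusters below an overall-occurrence threshold (default 2 %, inclusive) are
dropped from reports; their mass is carried as "other".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Ensemble, TopologyError
from .io import write_multimodel
from .selection import Selection, resolve_selection

logger = logging.getLogger(__name__)

_PAIR_CHUNK = 65536  # pairs per batched-SVD block; bounds peak memory


@dataclass(frozen=True)
class FrameKey:
    """Identity of a pooled frame: ensemble label + original frame index."""

    ensemble_label: str
    frame_index: int


@dataclass
class RmsdMatrix:
    """Symmetric matrix of fitted RMSD values (nm) over pooled frames."""

    keys: list[FrameKey]
    values: np.ndarray
    fit_expression: str
    rmsd_expression: str
    ensemble_frame_counts: dict[str, int]  # pooled (strided) frames per label

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.keys):
            raise ValueError("values must be square and match the key list")
        if not np.all(np.isfinite(v)):
            raise ValueError("RMSD matrix entries must be finite")
        if np.any(v < 0):
            raise ValueError("RMSD matrix entries must be >= 0")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric (tol 1e-9)")

    @property
    def n_frames(self) -> int:
        return len(self.keys)


@dataclass
class Cluster:
    """One conformational cluster of the pooled frame set."""

    cluster_id: int  # 1-based, in formation (size) order
    cms: FrameKey  # central member structure
    members: list[FrameKey]  # includes the CMS
    overall_fraction: float  # members / total pooled frames
    per_ensemble_fraction: dict[str, float]  # label -> members / label's frames

    @property
    def size(self) -> int:
        return len(self.members)


def _selected_identity(ensemble: Ensemble, sel: Selection) -> list[tuple]:
    return [
        (a.residue_number, a.insertion_code, a.atom_name, a.residue_name)
        for a in (ensemble.topology[i] for i in sel.indices)
    ]


def build_rmsd_matrix(
    ensembles: list[Ensemble],
    fit_selection: str,
    rmsd_selection: str,
    stride: int = 1,
) -> RmsdMatrix:
    """All-pairs fitted RMSD over the pooled (optionally strided) frames.

    Both selection expressions must resolve to the same atom count and the
    same atom identities, in order, on every ensemble (the loop being
    clustered is sequence-identical across variants).  Striding takes every
    ``stride``-th frame of each ensemble; keys retain original frame indices.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    labels = [e.label for e in ensembles]
    if len(set(labels)) != len(labels):
        raise ValueError("ensemble labels must be unique")

    fit_sels = [resolve_selection(fit_selection, e.topology, allow_empty=False)
                for e in ensembles]
    rmsd_sels = [resolve_selection(rmsd_selection, e.topology, allow_empty=False)
                 for e in ensembles]
    ref_fit = _selected_identity(ensembles[0], fit_sels[0])
    ref_rmsd = _selected_identity(ensembles[0], rmsd_sels[0])
    for ens, fsel, rsel in zip(ensembles[1:], fit_sels[1:], rmsd_sels[1:]):
        for name, ident, ref in (("fit", _selected_identity(ens, fsel), ref_fit),
                                 ("rmsd", _selected_identity(ens, rsel), ref_rmsd)):
            if ident != ref:
                for k, (a, b) in enumerate(zip(ident, ref)):
                    if a != b:
                        raise TopologyError(
                            f"{name} selection differs between ensemble "
                            f"{ens.label!r} and {ensembles[0].label!r} at "
                            f"selected atom {k}: {a} vs {b}"
                        )
                raise TopologyError(
                    f"{name} selection resolves to {len(ident)} atoms on "
                    f"{ens.label!r} but {len(ref)} on {ensembles[0].label!r}"
                )

    keys: list[FrameKey] = []
    fit_blocks: list[np.ndarray] = []
    rmsd_blocks: list[np.ndarray] = []
    counts: dict[str, int] = {}
    for ens, fsel, rsel in zip(ensembles, fit_sels, rmsd_sels):
        coords = ens.coords_array()[::stride]
        counts[ens.label] = coords.shape[0]
        keys.extend(FrameKey(ens.label, i * stride) for i in range(coords.shape[0]))
        fit_blocks.append(coords[:, fsel.indices, :])
        rmsd_blocks.append(coords[:, rsel.indices, :])
    if not keys:
        raise ValueError("pooled frame set is empty")

    fit = np.concatenate(fit_blocks)  # (n, m, 3)
    loop = np.concatenate(rmsd_blocks)  # (n, l, 3)
    centroids = fit.mean(axis=1, keepdims=True)
    fit_c = fit - centroids
    loop_c = loop - centroids

    n = fit.shape[0]
    n_loop = loop.shape[1]
    values = np.zeros((n, n), dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    logger.info("building %dx%d fitted-RMSD matrix (%d pairs)", n, n, len(iu))
    for start in range(0, len(iu), _PAIR_CHUNK):
        ii = iu[start:start + _PAIR_CHUNK]
        jj = ju[start:start + _PAIR_CHUNK]
        # Kabsch per pair, batched: mobile i onto reference j
        cov = np.einsum("pmi,pmj->pij", fit_c[ii], fit_c[jj])
        u, s, vt = np.linalg.svd(cov)
        d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
        d[d == 0] = 1.0
        vt[:, 2, :] *= d[:, None]
        rot = np.matmul(vt.transpose(0, 2, 1), u.transpose(0, 2, 1))
        moved = np.matmul(loop_c[ii], rot.transpose(0, 2, 1))
        diff = moved - loop_c[jj]
        msd = np.einsum("pli,pli->p", diff, diff) / n_loop
        values[ii, jj] = values[jj, ii] = np.sqrt(np.maximum(msd, 0.0))

    return RmsdMatrix(
        keys=keys,
        values=values,
        fit_expression=fit_selection,
        rmsd_expression=rmsd_selection,
        ensemble_frame_counts=counts,
    )


def greedy_neighbor_cluster(matrix: RmsdMatrix, cutoff: float = 0.2) -> list[Cluster]:
    """Greedy neighbour-count (Daura-style) clustering at a strict RMSD cutoff.

    The result is a partition of the pooled frames; cluster sizes are
    non-increasing with cluster id, and ties on the neighbour count are
    broken by the lowest pooled index.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.n_frames
    neighbours = matrix.values < cutoff  # strict; includes the diagonal
    np.fill_diagonal(neighbours, True)
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    total = n
    while remaining.any():
        counts = (neighbours & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        member_idx = np.flatnonzero(neighbours[center] & remaining)
        remaining[member_idx] = False
        members = [matrix.keys[i] for i in member_idx]
        per_label: dict[str, int] = {}
        for key in members:
            per_label[key.ensemble_label] = per_label.get(key.ensemble_label, 0) + 1
        clusters.append(
            Cluster(
                cluster_id=len(clusters) + 1,
                cms=matrix.keys[center],
                members=members,
                overall_fraction=len(members) / total,
                per_ensemble_fraction={
                    label: per_label.get(label, 0) / cnt
                    for label, cnt in matrix.ensemble_frame_counts.items()
                },
            )
        )
    sizes = [c.size for c in clusters]
    assert sizes == sorted(sizes, reverse=True), "greedy cluster sizes must be non-increasing"
    assert sum(sizes) == total, "clusters must partition the pooled frames"
    return clusters


def filter_clusters(
    clusters: list[Cluster],
    min_overall_fraction: float = 0.02,
    *,
    inclusive: bool = True,
) -> list[Cluster]:
    """Keep clusters whose overall occurrence meets the threshold.

    The default keeps clusters at *at least* the threshold (a cluster at
    exactly 2 % survives); ``inclusive=False`` switches to a strict ``>``.
    Original cluster ids are preserved.
    """
    if inclusive:
        kept = [c for c in clusters if c.overall_fraction >= min_overall_fraction]
    else:
        kept = [c for c in clusters if c.overall_fraction > min_overall_fraction]
    removed = sum(c.overall_fraction for c in clusters) - sum(
        c.overall_fraction for c in kept
    )
    logger.info("kept %d of %d clusters; %.3f of total mass moved to 'other'",
                len(kept), len(clusters), removed)
    return kept


def occupancy_report(clusters: list[Cluster]) -> pd.DataFrame:
    """Wide occupancy table: one row per ensemble, one column per kept
    cluster plus ``other``; each row sums to 1.

    Pass the *filtered* cluster list; the mass of dropped clusters appears
    in the ``other`` column.
    """
    labels: list[str] = []
    for cluster in clusters:
        for label in cluster.per_ensemble_fraction:
            if label not in labels:
                labels.append(label)
    columns = [f"cluster_{c.cluster_id}" for c in clusters]
    data = {
        col: [c.per_ensemble_fraction.get(label, 0.0) for label in labels]
        for col, c in zip(columns, clusters)
    }
    table = pd.DataFrame(data, index=pd.Index(labels, name="ensemble"))
    table["other"] = 1.0 - table.sum(axis=1)
    # clip the tiny negative residue floating-point subtraction can leave
    table["other"] = table["other"].clip(lower=0.0)
    return table


def occupancy_tidy(clusters: list[Cluster]) -> pd.DataFrame:
    """Tidy occupancy table: ensemble, cluster_id, n_frames, fraction."""
    rows = []
    for cluster in clusters:
        per_label: dict[str, int] = {}
        for key in cluster.members:
            per_label[key.ensemble_label] = per_label.get(key.ensemble_label, 0) + 1
        for label, fraction in cluster.per_ensemble_fraction.items():
            rows.append({
                "ensemble": label,
                "cluster_id": cluster.cluster_id,
                "n_frames": per_label.get(label, 0),
                "fraction": fraction,
            })
    return pd.DataFrame(rows, columns=["ensemble", "cluster_id", "n_frames", "fraction"])


def export_cms(
    clusters: list[Cluster],
    ensembles: list[Ensemble],
    out_dir: str | Path,
) -> list[Path]:
    """Write each cluster's central member structure as a single-model PDB.

    Files are named ``cms_cluster_<id>.pdb`` and carry the cluster id and
    source frame in a REMARK.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not clusters:
        warnings.warn("no clusters to export", stacklevel=2)
        return []
    by_label = {e.label: e for e in ensembles}
    paths = []
    for cluster in clusters:
        ens = by_label[cluster.cms.ensemble_label]
        path = out_dir / f"cms_cluster_{cluster.cluster_id:02d}.pdb"
        write_multimodel(
            ens,
            path,
            frame_indices=[cluster.cms.frame_index],
            remark=(
                f"CMS of cluster {cluster.cluster_id} "
                f"(ensemble {cluster.cms.ensemble_label}, "
                f"frame {cluster.cms.frame_index}, "
                f"overall occurrence {cluster.overall_fraction:.4f})"
            ),
        )
        paths.append(path)
    return paths
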