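"""Bound-pose clustering on helix-core Cα RMSD.

Bound frames are compared by superposition-minimised RMSD over the Cα atoms
of the helix core (residues 5-12 by default), clustered by unweighted
average linkage (UPGMA-style agglomeration), and each family is summarised
by the member closest to the iteratively superposed average structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError
from .model_io import PeptideTopology, Topology, Trajectory

__all__ = ["DistanceMatrix", "ClusterResult", "kabsch_superpose", "core_rmsd",
           "rmsd_matrix", "average_linkage", "representatives"]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(moving: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition (proper rotations only) via SVD.

    Returns ``(rotation, translation, rmsd)`` such that
    ``moving @ rotation.T + translation`` best fits ``reference`` in the
    least-squares sense; ``det(rotation) = +1``.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(f"point counts differ: {moving.shape} vs {reference.shape}")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    cm, cr = moving.mean(axis=0), reference.mean(axis=0)
    a, b = moving - cm, reference - cr
    # collinearity makes the rotation ill-determined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise DegenerateGeometryError("points are collinear; rotation ill-conditioned")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - cm @ rotation.T
    fitted = moving @ rotation.T + translation
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum() / len(reference)))
    return rotation, translation, rmsd


def _core_ca_indices(topology: Topology | PeptideTopology,
                     core: tuple[int, int] = (5, 12)) -> np.ndarray:
    pep = topology if isinstance(topology, PeptideTopology) else topology.peptide()
    lo, hi = core
    if not (1 <= lo <= hi <= pep.n_residues):
        raise ValueError(f"core range {core} outside residues 1..{pep.n_residues}")
    return np.array(pep.ca_indices(range(lo, hi + 1)), dtype=int)


def core_rmsd(frame_a, frame_b, topology, core: tuple[int, int] = (5, 12)) -> float:
    """Superposition-minimised RMSD over the helix-core Cα atoms."""
    idx = _core_ca_indices(topology, core)
    a = np.asarray(frame_a.coordinates if hasattr(frame_a, "coordinates") else frame_a)
    b = np.asarray(frame_b.coordinates if hasattr(frame_b, "coordinates") else frame_b)
    _, _, rmsd = kabsch_superpose(a[idx], b[idx])
    return rmsd


# ---------------------------------------------------------------------------
# Pairwise matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Condensed pairwise core-RMSD matrix over the bound frames."""

    condensed: np.ndarray        # (k*(k-1)/2,) A
    frame_indices: np.ndarray    # (k,) map back into the trajectory

    def __post_init__(self):
        self.condensed = np.asarray(self.condensed, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        k = self.size
        if self.condensed.shape != (k * (k - 1) // 2,):
            raise ValueError("condensed length inconsistent with frame count")
        if not np.isfinite(self.condensed).all() or (self.condensed < 0).any():
            raise ValueError("distances must be finite and non-negative")

    @property
    def size(self) -> int:
        return len(self.frame_indices)

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform
        return squareform(self.condensed)


def _batched_pair_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs Kabsch RMSD for centred coordinate sets (k, p, 3).

    Returns the condensed upper triangle.  Uses batched 3x3 SVDs; equivalent
    to per-pair :func:`kabsch_superpose` to numerical precision.
    """
    k, p, _ = coords.shape
    centred = coords - coords.mean(axis=1, keepdims=True)
    sq = (centred ** 2).sum(axis=(1, 2))  # per-frame squared norm
    ii, jj = np.triu_indices(k, 1)
    out = np.empty(len(ii))
    chunk = 20000
    for start in range(0, len(ii), chunk):
        a = centred[ii[start:start + chunk]]
        b = centred[jj[start:start + chunk]]
        h = np.einsum("npi,npj->nij", a, b)
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(vt.transpose(0, 2, 1) @ u.transpose(0, 2, 1))
        s_fixed = s.copy()
        s_fixed[:, 2] *= np.sign(det)
        msd = (sq[ii[start:start + chunk]] + sq[jj[start:start + chunk]]
               - 2.0 * s_fixed.sum(axis=1)) / p
        out[start:start + chunk] = np.sqrt(np.maximum(msd, 0.0))
    return out


def rmsd_matrix(trajectory: Trajectory, bound_mask: np.ndarray, topology=None,
                core: tuple[int, int] = (5, 12)) -> DistanceMatrix:
    """Pairwise core-RMSD matrix over the frames flagged in ``bound_mask``."""
    topology = topology if topology is not None else trajectory.topology
    bound_mask = np.asarray(bound_mask, dtype=bool)
    frame_idx = np.flatnonzero(bound_mask)
    if len(frame_idx) < 2:
        raise InsufficientDataError(
            f"need at least 2 bound frames, got {len(frame_idx)}")
    ca = _core_ca_indices(topology, core)
    coords = np.stack([trajectory.frames[i].coordinates[ca] for i in frame_idx])
    condensed = _batched_pair_rmsd(coords)
    return DistanceMatrix(condensed=condensed, frame_indices=frame_idx)


# ---------------------------------------------------------------------------
# Average-linkage agglomeration
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Merge tree, flat labels and per-cluster summaries."""

    merges: np.ndarray           # (k-1, 4): id_a, id_b, height A, new size
    labels: np.ndarray           # (k,) flat labels 0..n_clusters-1
    frame_indices: np.ndarray    # (k,) trajectory frame per observation
    populations: np.ndarray      # per-cluster counts, ordered by label
    fractions: np.ndarray
    representative_frames: dict[int, int] = field(default_factory=dict)
    average_structures: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def clusters_by_population(self) -> list[int]:
        """Cluster labels sorted most-populated first (ties: lower label)."""
        order = np.lexsort((np.arange(self.n_clusters), -self.populations))
        return [int(c) for c in order]


def average_linkage(matrix: DistanceMatrix, n_clusters: int = 10) -> ClusterResult:
    """Unweighted average-linkage (UPGMA-style) agglomeration.

    Ties on the minimal inter-cluster distance are broken by the smallest
    (i, j) condensed index over the current cluster ids, making the merge
    sequence deterministic across platforms.  Flat labels come from cutting
    the tree at ``n_clusters`` groups and are numbered by first occurrence.
    """
    k = matrix.size
    if not (1 <= n_clusters <= k):
        raise ValueError(f"n_clusters must be in [1, {k}], got {n_clusters}")
    d = matrix.square().astype(float)
    np.fill_diagonal(d, np.inf)
    sizes = {i: 1 for i in range(k)}           # active cluster id -> size
    members: dict[int, list[int]] = {i: [i] for i in range(k)}
    slot = {i: i for i in range(k)}            # cluster id -> row in d
    active = list(range(k))
    merges = np.zeros((k - 1, 4))
    labels_at_cut = None
    next_id = k
    for step in range(k - 1):
        # find minimal distance among active slots; np.argmin scans row-major,
        # i.e. lexicographic (i, j) order over condensed indices
        rows = [slot[c] for c in active]
        sub = d[np.ix_(rows, rows)]
        iu = np.triu_indices(len(rows), 1)
        flat = sub[iu]
        best = int(np.argmin(flat))
        i_loc, j_loc = iu[0][best], iu[1][best]
        ci, cj = active[i_loc], active[j_loc]
        height = float(flat[best])
        ni, nj = sizes[ci], sizes[cj]
        merges[step] = (ci, cj, height, ni + nj)
        # Lance-Williams update for unweighted average linkage
        ri, rj = slot[ci], slot[cj]
        new_row = (ni * d[ri] + nj * d[rj]) / (ni + nj)
        d[ri] = new_row
        d[:, ri] = new_row
        d[ri, ri] = np.inf
        d[rj] = np.inf
        d[:, rj] = np.inf
        members[next_id] = members.pop(ci) + members.pop(cj)
        sizes[next_id] = ni + nj
        sizes.pop(ci); sizes.pop(cj)
        slot[next_id] = ri
        slot.pop(ci); slot.pop(cj)
        active = [c for c in active if c not in (ci, cj)] + [next_id]
        next_id += 1
        if len(active) == n_clusters:
            labels_at_cut = [members[c] for c in active]
    if labels_at_cut is None:  # n_clusters == k: no merges needed for the cut
        labels_at_cut = [[i] for i in range(k)]
    labels = np.empty(k, dtype=int)
    # number clusters by first occurrence for determinism
    firsts = sorted(range(len(labels_at_cut)), key=lambda c: min(labels_at_cut[c]))
    for new_label, c in enumerate(firsts):
        labels[labels_at_cut[c]] = new_label
    populations = np.bincount(labels, minlength=len(labels_at_cut))
    return ClusterResult(
        merges=merges, labels=labels, frame_indices=matrix.frame_indices,
        populations=populations, fractions=populations / k)


# ---------------------------------------------------------------------------
# Representatives
# ---------------------------------------------------------------------------

def _iterative_mean_structure(coords: np.ndarray, tol: float = 1e-6,
                              max_iter: int = 200) -> np.ndarray:
    """Mean Cα structure after iterative re-superposition of all members to
    the running mean, until the mean moves by less than ``tol`` A."""
    fitted = coords - coords.mean(axis=1, keepdims=True)
    mean = fitted[0].copy()
    for _ in range(max_iter):
        new_fitted = []
        for x in fitted:
            rot, trans, _ = kabsch_superpose(x, mean)
            new_fitted.append(x @ rot.T + trans)
        new_mean = np.mean(new_fitted, axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum() / len(mean)))
        fitted = np.stack(new_fitted)
        mean = new_mean
        if shift < tol:
            break
    return mean


def representatives(result: ClusterResult, trajectory: Trajectory, topology=None,
                    core: tuple[int, int] = (5, 12)) -> dict[int, int]:
    """Representative frame per cluster: the member with the lowest core-Cα
    RMSD to the cluster's (iteratively superposed) average structure.
    Ties go to the lowest frame index.  Fills ``result.representative_frames``
    and ``result.average_structures`` and returns the frame map."""
    topology = topology if topology is not None else trajectory.topology
    ca = _core_ca_indices(topology, core)
    reps: dict[int, int] = {}
    for label in range(result.n_clusters):
        obs = np.flatnonzero(result.labels == label)
        frames = result.frame_indices[obs]
        coords = np.stack([trajectory.frames[i].coordinates[ca] for i in frames])
        if len(frames) == 1:
            reps[int(label)] = int(frames[0])
            result.average_structures[int(label)] = coords[0] - coords[0].mean(axis=0)
            continue
        mean = _iterative_mean_structure(coords)
        rmsds = np.array([kabsch_superpose(x, mean)[2] for x in coords])
        best = int(np.lexsort((frames, rmsds))[0])
        reps[int(label)] = int(frames[best])
        result.average_structures[int(label)] = mean
    result.representative_frames = reps
    return reps
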