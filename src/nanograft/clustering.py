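"""RMSD-based gromos clustering of conformational ensembles.

The pairwise RMSD matrix is computed on C-alpha atoms after optimal
least-squares superposition of each pair (closed-form Kabsch rotation with
reflection correction).  The clustering cutoff defaults to the mean of the
off-diagonal pairwise RMSDs ("average-RMSD cutoff rule"), and clusters are
extracted with the greedy gromos procedure: repeatedly take the
conformation with the most neighbours within the cutoff, remove it and its
neighbours as one cluster, and continue until no conformation remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EnsembleError
from .structure import ConformationEnsemble, Structure


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Least-squares-fit RMSD of two (n, 3) coordinate sets.

    Uses the closed-form optimal rotation (SVD of the covariance matrix)
    with the determinant sign corrected so reflections are never applied.
    """
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    cov = p.T @ q
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= d
    # RMSD directly from the trace identity: avoids building the rotation.
    sq = (p ** 2).sum() + (q ** 2).sum() - 2.0 * s.sum()
    return float(np.sqrt(max(sq, 0.0) / len(p)))


def rmsd_matrix(
    ensemble: ConformationEnsemble,
    atom_selection: str = "CA",
) -> np.ndarray:
    """Symmetric matrix of pairwise least-squares-fit RMSDs (Å).

    ``atom_selection`` is an atom name (default C-alpha only) or ``"all"``
    for every heavy atom.
    """
    if ensemble.n_frames < 2:
        raise EnsembleError("RMSD matrix requires at least 2 conformations")
    if atom_selection == "all":
        coords = ensemble.stack.coord
    else:
        mask = ensemble.stack.atom_name == atom_selection
        if not mask.any():
            raise EnsembleError(f"no atoms named {atom_selection!r} in ensemble")
        coords = ensemble.stack.coord[:, mask, :]
    n = coords.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(coords[i], coords[j])
    return out


def auto_cutoff(matrix: np.ndarray) -> float:
    """The average-RMSD cutoff: mean of the off-diagonal unique pairs."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("cutoff requires at least 2 conformations")
    iu = np.triu_indices(n, k=1)
    return float(matrix[iu].mean())


@dataclass(frozen=True)
class ClusterResult:
    """gromos clustering outcome.

    ``labels[f]`` is the cluster of frame ``f`` (0 = most populated);
    ``sizes`` are descending; ``centers[c]`` is the frame chosen as cluster
    ``c``'s representative (the frame that, at extraction time, had the
    maximal within-cutoff neighbour count).
    """

    labels: np.ndarray
    sizes: tuple[int, ...]
    centers: tuple[int, ...]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, cluster: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.labels == cluster)]

    def top_fraction(self) -> float:
        return self.sizes[0] / len(self.labels)


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbour-count (gromos) clustering of an RMSD matrix.

    Iteratively the conformation with the most remaining neighbours within
    ``cutoff`` (ties broken by lowest frame index) becomes a cluster center;
    it and its neighbours form the cluster and are removed.  Clusters are
    relabelled by descending size afterwards (ties: earlier extraction
    first).
    """
    matrix = np.asarray(matrix)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.shape[0]
    within = matrix <= cutoff
    np.fill_diagonal(within, False)
    remaining = np.ones(n, dtype=bool)
    raw_labels = np.full(n, -1)
    raw_centers: list[int] = []
    raw_sizes: list[int] = []
    cluster = 0
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(within[center] & remaining).tolist()
        group = [center] + members
        raw_labels[group] = cluster
        raw_centers.append(center)
        raw_sizes.append(len(group))
        remaining[group] = False
        cluster += 1
    order = sorted(range(cluster), key=lambda c: (-raw_sizes[c], c))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw_labels])
    sizes = tuple(raw_sizes[c] for c in order)
    centers = tuple(raw_centers[c] for c in order)
    return ClusterResult(labels, sizes, centers, float(cutoff))


def select_representatives(
    ensemble: ConformationEnsemble, result: ClusterResult
) -> tuple[dict[int, Structure], Structure]:
    """Representative conformation per cluster, plus the overall reference.

    The representative of a cluster is its gromos center; the overall
    reference conformation is the representative of the most populated
    cluster.  Deterministic given the input frame order.
    """
    reps = {c: ensemble.frame(f) for c, f in enumerate(result.centers)}
    return reps, reps[0]
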