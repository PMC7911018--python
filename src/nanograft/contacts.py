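"""Residue contact maps, contact-map differences and active-residue nomination.

A contact map over an ensemble records, for every residue pair, the fraction
of conformations in which the two residues touch (any heavy-atom pair closer
than a cutoff, short-range pairs excluded).  Comparing a mutant's map with
the wild type's and projecting the absolute difference matrix onto residues
highlights the residues whose packing the mutations rewired; combined with
the hydrophobic solvent-exposed surface set, these nominate the candidate
aggregation-interface ("active") residues handed to docking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, ConformationEnsemble

#: Default heavy-atom contact cutoff (Å) and sequence-separation exclusion.
CONTACT_CUTOFF = 4.5
MIN_SEPARATION = 2

#: Default spatial-clustering distance (Å) for active-residue nomination,
#: shared with hotspot detection.
NEIGHBOR_DISTANCE = 6.0


@dataclass(frozen=True)
class ContactMap:
    """Symmetric residue-pair contact-frequency matrix in [0, 1]."""

    matrix: np.ndarray
    res_ids: tuple[int, ...]
    cutoff: float
    min_separation: int

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    def compatible_with(self, other: "ContactMap") -> bool:
        return (
            self.matrix.shape == other.matrix.shape
            and self.cutoff == other.cutoff
            and self.min_separation == other.min_separation
        )


def _frame_contacts(structure: Structure, cutoff: float) -> np.ndarray:
    """Boolean residue-pair contact matrix for one conformation."""
    d = structure.min_heavy_distance_matrix()
    return d < cutoff


def contact_map(
    ensemble: ConformationEnsemble | Structure,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
) -> ContactMap:
    """Ensemble contact map: per-pair fraction of contacting conformations.

    Two residues are in contact in a conformation when any heavy-atom pair
    lies closer than ``cutoff``.  The diagonal band ``|i - j| <=
    min_separation`` is forced to zero.
    """
    if isinstance(ensemble, Structure):
        frames = [ensemble]
        n = ensemble.n_residues
        res_ids = tuple(ensemble.res_ids)
    else:
        frames = [ensemble.frame(i) for i in range(ensemble.n_frames)]
        n = ensemble.n_residues
        res_ids = tuple(ensemble.res_ids)
    acc = np.zeros((n, n))
    for frame in frames:
        acc += _frame_contacts(frame, cutoff)
    acc /= len(frames)
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= min_separation
    acc[band] = 0.0
    return ContactMap(acc, res_ids, cutoff, min_separation)


@dataclass(frozen=True)
class DiffProfile:
    """Per-residue projection of a contact-map difference matrix.

    ``values[i] = sum_j |wt_ij - mut_ij|`` (L1 row projection; L2
    optionally); ``mask`` flags the most affected residues, those with
    ``d_i > mean(d) + k * sd(d)``.
    """

    values: np.ndarray
    mask: np.ndarray
    res_ids: tuple[int, ...]
    norm: str
    k: float

    def selected(self) -> list[int]:
        """Indices of the most affected residues."""
        return [int(i) for i in np.flatnonzero(self.mask)]

    def ranking(self) -> list[int]:
        """Residue indices sorted by descending projection value."""
        order = np.argsort(-self.values, kind="stable")
        return [int(i) for i in order]


def contact_diff_projection(
    wt: ContactMap,
    mut: ContactMap,
    k: float = 1.0,
    norm: str = "l1",
) -> DiffProfile:
    """Project |wt - mut| onto residues and flag the most affected ones."""
    if wt.matrix.shape != mut.matrix.shape:
        raise ValueError(
            f"contact map dimensions differ: {wt.matrix.shape} vs {mut.matrix.shape}"
        )
    if not wt.compatible_with(mut):
        raise ValueError("contact maps were built with different contact rules")
    delta = np.abs(wt.matrix - mut.matrix)
    if norm == "l1":
        values = delta.sum(axis=1)
    elif norm == "l2":
        values = np.sqrt((delta ** 2).sum(axis=1))
    else:
        raise ValueError(f"unknown projection norm {norm!r}")
    threshold = values.mean() + k * values.std()
    mask = values > threshold
    return DiffProfile(values, mask, wt.res_ids, norm, k)


def nominate_active_residues(
    hydrophobic_exposed_set,
    diff_selected,
    structure: Structure,
    neighbor_distance: float = NEIGHBOR_DISTANCE,
    mode: str = "union",
) -> dict[int, str]:
    """Nominate candidate aggregation-interface residues.

    Combines the hydrophobic solvent-exposed residue set with the
    contact-difference selection (``mode="union"``, the default, or
    ``mode="intersection"``), then keeps only residues that are spatially
    clustered: each must have at least one other combined-set residue within
    ``neighbor_distance`` (minimum heavy-atom distance).  Returns a mapping
    residue index -> provenance ("exposure", "diff" or "both").
    """
    exposed = set(int(i) for i in hydrophobic_exposed_set)
    affected = set(int(i) for i in diff_selected)
    if mode == "union":
        candidates = exposed | affected
    elif mode == "intersection":
        candidates = exposed & affected
    else:
        raise ValueError(f"unknown nomination mode {mode!r}")
    if not candidates:
        return {}
    dmat = structure.min_heavy_distance_matrix()
    members = sorted(candidates)
    keep = {}
    for i in members:
        neighbors = [j for j in members if j != i and dmat[i, j] <= neighbor_distance]
        if neighbors:
            if i in exposed and i in affected:
                keep[i] = "both"
            elif i in exposed:
                keep[i] = "exposure"
            else:
                keep[i] = "diff"
    return keep
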