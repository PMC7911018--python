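"""Per-residue solubility profiling and aggregation-hotspot detection.

The per-residue *intrinsic* score is a documented surrogate scorer: a
z-scaled, sliding-window-smoothed linear combination of side-chain
hydropathy, net side-chain charge at the working pH (charge promotes
solubility) and aromatic/beta-aggregation propensity.  More hydrophobic
means lower (worse) score.  It is deliberately simple and is labelled
"surrogate-intrinsic" in reports; externally computed per-residue profiles
can be supplied instead and flow through the same structural correction and
hotspot machinery, which is where the analysis actually lives.

The *structural correction* averages intrinsic scores over the spatial
neighbourhood of each residue (side-chain centroids within a patch radius,
default 10 Å), weighting neighbours by solvent exposure, so that buried
poorly-soluble residues stop dominating and surface patches emerge.

*Hotspots* are then the connected neighbourhoods of the poorest-solubility
exposed residues: seeds are exposed residues with corrected score below a
threshold, members are exposed residues within a hotspot distance (default
6 Å, minimum side-chain heavy-atom distance; CA for Gly) of any seed, and
seed neighbourhoods sharing a member merge (single linkage).  A hotspot's
aggregation propensity is the sum of its members' solubility scores: the
lower (more negative) the sum, the worse the hotspot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .numbering import VHHSequence
from .structure import (
    EXPOSURE_THRESHOLD,
    Structure,
    SasaResult,
    compute_sasa,
)

#: Kyte-Doolittle hydropathy (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Aromatic / beta-aggregation propensity term (dimensionless weights).
AGGREGATION_PROPENSITY = {
    "F": 1.0, "W": 1.0, "Y": 0.8, "I": 0.7, "V": 0.7,
    "L": 0.5, "M": 0.4, "C": 0.3,
}

#: Side-chain pKa values for the charge term.
SIDECHAIN_PKA = {"D": 3.9, "E": 4.1, "H": 6.0, "C": 8.4, "Y": 10.5, "K": 10.5, "R": 12.5}
ACIDIC = {"D", "E", "C", "Y"}
BASIC = {"H", "K", "R"}

DEFAULT_PH = 7.0
DEFAULT_WINDOW = 7
PATCH_RADIUS = 10.0
HOTSPOT_DISTANCE = 6.0
SEED_THRESHOLD = -1.0
#: Exposure weight floor: buried residues still contribute to patch
#: averages, but down-weighted to this relative-SASA equivalent.
BURIED_WEIGHT = 0.1


def sidechain_charge(residue: str, pH: float = DEFAULT_PH) -> float:
    """Henderson-Hasselbalch net side-chain charge of one residue at pH."""
    pka = SIDECHAIN_PKA.get(residue)
    if pka is None:
        return 0.0
    if residue in ACIDIC:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with a window that shrinks at the edges."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def intrinsic_profile(
    sequence: VHHSequence | str,
    pH: float = DEFAULT_PH,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Surrogate per-residue intrinsic solubility scores (z-scaled).

    ``raw_i = -(hydropathy_i / 4.5) - 0.5 * aggregation_i + |charge_i(pH)|``
    smoothed over a centred ``window`` and standardised to zero mean and
    unit variance across the sequence.  Negative values mark poorly soluble
    stretches.
    """
    residues = sequence.residues if isinstance(sequence, VHHSequence) else str(sequence)
    raw = np.array(
        [
            -KYTE_DOOLITTLE.get(res, 0.0) / 4.5
            - 0.5 * AGGREGATION_PROPENSITY.get(res, 0.0)
            + abs(sidechain_charge(res, pH))
            for res in residues
        ]
    )
    smoothed = _smooth(raw, window)
    sd = smoothed.std()
    if sd < 1e-12:
        return np.zeros_like(smoothed)
    return (smoothed - smoothed.mean()) / sd


@dataclass(frozen=True)
class SolubilityProfile:
    """Intrinsic and structurally corrected per-residue solubility scores."""

    res_ids: tuple[int, ...]
    residues: str                 # one-letter codes, aligned with res_ids
    intrinsic: np.ndarray         # s_i
    corrected: np.ndarray         # S_i
    relative_sasa: np.ndarray
    patch_radius: float = PATCH_RADIUS
    pH: float = DEFAULT_PH
    source: str = "surrogate-intrinsic"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "res_id": self.res_ids,
                "residue": list(self.residues),
                "intrinsic": self.intrinsic,
                "corrected": self.corrected,
                "relative_sasa": self.relative_sasa,
                "source": self.source,
            }
        )


def structural_correction(
    structure: Structure,
    intrinsic: np.ndarray,
    patch_radius: float = PATCH_RADIUS,
    exposure_threshold: float = EXPOSURE_THRESHOLD,
    buried_weight: float = BURIED_WEIGHT,
    sasa: SasaResult | None = None,
    pH: float = DEFAULT_PH,
    source: str = "surrogate-intrinsic",
) -> SolubilityProfile:
    """Exposure-weighted spatial smoothing of an intrinsic profile.

    ``S_i`` is the weighted mean of ``s_j`` over residues ``j`` (including
    ``i``) whose side-chain centroids lie within ``patch_radius`` of residue
    ``i``'s centroid.  The weight of an exposed residue is its relative
    SASA; buried residues (relative SASA below ``exposure_threshold``)
    contribute with the floor weight ``buried_weight``.
    """
    intrinsic = np.asarray(intrinsic, dtype=float)
    n = structure.n_residues
    if len(intrinsic) != n:
        raise ValueError(
            f"intrinsic profile has {len(intrinsic)} scores, structure has "
            f"{n} residues"
        )
    if sasa is None:
        sasa = compute_sasa(structure)
    centroids = structure.sidechain_centroids()
    bad = ~np.all(np.isfinite(centroids), axis=1)
    if bad.any():
        warnings.warn(
            f"residues {np.flatnonzero(bad).tolist()} lack usable coordinates; "
            "their corrected score falls back to the intrinsic score",
            stacklevel=2,
        )
    weights = np.maximum(sasa.relative, buried_weight)
    corrected = np.empty(n)
    for i in range(n):
        if bad[i]:
            corrected[i] = intrinsic[i]
            continue
        d = np.linalg.norm(centroids - centroids[i], axis=1)
        patch = (d <= patch_radius) & ~bad
        w = weights[patch]
        corrected[i] = float(np.dot(w, intrinsic[patch]) / w.sum())
    return SolubilityProfile(
        tuple(structure.res_ids),
        structure.one_letter(),
        intrinsic,
        corrected,
        sasa.relative,
        patch_radius=patch_radius,
        pH=pH,
        source=source,
    )


def profile_from_scores(
    structure: Structure,
    corrected: np.ndarray,
    intrinsic: np.ndarray | None = None,
    sasa: SasaResult | None = None,
    source: str = "external",
) -> SolubilityProfile:
    """Wrap externally computed per-residue scores into a profile."""
    corrected = np.asarray(corrected, dtype=float)
    if len(corrected) != structure.n_residues:
        raise ValueError("score vector length does not match residue count")
    if sasa is None:
        sasa = compute_sasa(structure)
    if intrinsic is None:
        intrinsic = corrected.copy()
    return SolubilityProfile(
        tuple(structure.res_ids),
        structure.one_letter(),
        np.asarray(intrinsic, dtype=float),
        corrected,
        sasa.relative,
        source=source,
    )


@dataclass(frozen=True)
class Hotspot:
    """A merged neighbourhood of poorest-solubility exposed residues."""

    seeds: tuple[int, ...]     # residue indices that nucleated the hotspot
    members: tuple[int, ...]   # exposed residues within reach of a seed
    score: float               # sum of members' solubility scores

    def __len__(self) -> int:
        return len(self.members)


def detect_hotspots(
    structure: Structure,
    profile: SolubilityProfile,
    hotspot_distance: float = HOTSPOT_DISTANCE,
    seed_threshold: float = SEED_THRESHOLD,
    exposure_threshold: float = EXPOSURE_THRESHOLD,
    use_corrected: bool = True,
) -> list[Hotspot]:
    """Detect and score aggregation hotspots on one conformation.

    Seeds are exposed residues whose (corrected, by default) score falls
    below ``seed_threshold``; members are exposed residues whose minimum
    side-chain heavy-atom distance to any seed's side chain is at most
    ``hotspot_distance`` (a seed is always a member of its own hotspot).
    Seed neighbourhoods sharing at least one member merge (single linkage);
    each hotspot is scored as the exact sum of its members' scores and the
    list is returned worst (lowest score) first.  No residue passing the
    seed rule is a valid outcome: the result is then empty.
    """
    scores = profile.corrected if use_corrected else profile.intrinsic
    if len(scores) != structure.n_residues:
        raise ValueError("profile does not match structure")
    exposed = profile.relative_sasa >= exposure_threshold
    seeds = [
        i
        for i in range(structure.n_residues)
        if exposed[i] and scores[i] < seed_threshold
    ]
    if not seeds:
        return []
    dmat = structure.min_sidechain_distance_matrix()
    neighborhoods = {
        s: frozenset(
            j
            for j in range(structure.n_residues)
            if exposed[j] and dmat[s, j] <= hotspot_distance
        )
        for s in seeds
    }
    # single-linkage merge of seed neighbourhoods sharing >= 1 member
    groups: list[list[int]] = []
    for s in seeds:
        merged = [g for g in groups if neighborhoods[s] & frozenset().union(
            *(neighborhoods[t] for t in g)
        )]
        for g in merged:
            groups.remove(g)
        groups.append(sorted({s} | {t for g in merged for t in g}))
    hotspots = []
    for g in groups:
        members = sorted(frozenset().union(*(neighborhoods[s] for s in g)))
        score = float(np.sum(scores[members]))
        hotspots.append(Hotspot(tuple(g), tuple(members), score))
    return sorted(hotspots, key=lambda h: h.score)


def hotspot_report(
    results: dict[str, tuple[SolubilityProfile, list[Hotspot]]],
) -> pd.DataFrame:
    """Side-by-side hotspot table for one or more constructs.

    ``results`` maps a construct id to its (profile, hotspots) pair; the
    returned frame has one row per construct x hotspot with id, seeds,
    members and score, supporting hotspot1/hotspot2-style comparisons.
    An empty hotspot list contributes no rows (header-only table).
    """
    rows = []
    for construct, (profile, hotspots) in results.items():
        for rank, h in enumerate(hotspots, start=1):
            rows.append(
                {
                    "construct": construct,
                    "hotspot": f"hotspot{rank}",
                    "score": h.score,
                    "n_members": len(h.members),
                    "seeds": ",".join(str(profile.res_ids[i]) for i in h.seeds),
                    "members": ",".join(str(profile.res_ids[i]) for i in h.members),
                    "score_source": profile.source,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "construct", "hotspot", "score", "n_members",
            "seeds", "members", "score_source",
        ],
    )
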