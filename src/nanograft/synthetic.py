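"""Synthetic ground-truth generators for every pipeline input.

Sequences, structures and conformational ensembles produced here are
deliberately non-physical (pseudo-atoms, idealized geometry): the pipeline's
operators depend only on residue identities, distances, exposure and labels,
so each generator can plant a known truth — hallmark states, mutation sets,
exposed patches, contact rewiring, shielding loops, cluster basins — and
emit it alongside the data, making every downstream stage testable
closed-loop.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as bst

from .grafting import MutationSet, apply_mutations
from .numbering import (
    CAMELID_TETRAD,
    DEFAULT_FINGERPRINTS,
    DEFAULT_REGIONS,
    HALLMARK_POSITIONS,
    HUMAN_TETRAD,
    VHHSequence,
    number_sequence,
    scheme_key,
)
from .structure import ONE_TO_THREE, ConformationEnsemble, Structure

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def make_sequence(
    seed: int = 0,
    hallmarks: str = "camelid",
    fingerprints: dict[int, str] | None = None,
    region_lengths: dict[str, int] | None = None,
    seq_id: str | None = None,
) -> tuple[VHHSequence, dict]:
    """A random VHH-like sequence with controlled hallmark/fingerprint states.

    Residues are drawn uniformly at random, then the FW2 tetrad is set to
    the requested species signature and any requested fingerprint sites to
    the reference prototype of their species.  Returns the sequence and a
    ground-truth dict (hallmark state, fingerprint assignments, region
    lengths).
    """
    rng = np.random.default_rng(seed)
    if hallmarks not in ("camelid", "human", "hybrid"):
        raise ValueError(f"unknown hallmark state {hallmarks!r}")
    lengths = {"FW1": 25, "CDR1": 7, "FW2": 19, "CDR2": 5, "FW3": 38,
               "CDR3": 8, "FW4": 11}
    lengths.update(region_lengths or {})
    total = sum(lengths.values())
    raw = "".join(rng.choice(list(_ALPHABET), size=total))
    vhh = number_sequence(
        raw,
        region_lengths=lengths,
        seq_id=seq_id or f"synthetic-{seed}",
    )
    mapping = vhh.position_map()
    if hallmarks == "camelid":
        tetrad = CAMELID_TETRAD
    elif hallmarks == "human":
        tetrad = HUMAN_TETRAD
    else:
        tetrad = ("V", "E", "R", "F")  # one human, three camelid positions
    for pos, res in zip(HALLMARK_POSITIONS, tetrad):
        mapping[pos] = res
    fingerprints = dict(fingerprints or {})
    for site, species in fingerprints.items():
        species = "llama" if species == "camelid" else species
        mapping[str(site)] = DEFAULT_FINGERPRINTS.prototype(site, species)
    if lengths["FW4"] == DEFAULT_REGIONS["FW4"].capacity:
        mapping["103"] = "W"  # keep the FW4 anchor consistent with renumbering
    vhh = VHHSequence.from_position_map(vhh.seq_id, mapping, vhh.regions)
    truth = {
        "hallmarks": hallmarks,
        "fingerprints": fingerprints,
        "region_lengths": lengths,
    }
    return vhh, truth


def make_sequence_pair(
    seed: int = 0,
    n_sub: int = 4,
    n_ins: int = 0,
    n_del: int = 1,
) -> tuple[VHHSequence, VHHSequence, dict]:
    """A base sequence and a mutant with a planted difference pattern.

    The mutant carries exactly ``n_sub`` framework substitutions (hallmark
    positions excluded so the planted hallmark state survives), loses the
    last ``n_del`` CDR3 residues and gains ``n_ins`` CDR3 insertion-code
    residues.  ``diff_sequences(mutant, base)`` therefore reports
    ``(n_sub, n_ins, n_del)``.
    """
    rng = np.random.default_rng(seed)
    base, _ = make_sequence(seed=seed, seq_id=f"pair-base-{seed}")
    fw_positions = [
        pos
        for pos in base.numbering
        if base.region_of(pos).startswith("FW") and pos not in HALLMARK_POSITIONS
    ]
    sub_positions = sorted(
        rng.choice(fw_positions, size=n_sub, replace=False), key=scheme_key
    )
    substitutions = []
    for pos in sub_positions:
        old = base.get(pos)
        new = rng.choice([a for a in _ALPHABET if a != old])
        substitutions.append((pos, old, str(new)))
    cdr3 = [p for p in base.numbering if base.region_of(p) == "CDR3"]
    if n_del > len(cdr3) - 1:
        raise ValueError("cannot delete that many CDR3 residues")
    deletions = tuple((p, base.get(p)) for p in cdr3[len(cdr3) - n_del:])
    region = base.regions["CDR3"]
    insertions = tuple(
        (f"{region.end}{chr(ord('A') + k)}", str(rng.choice(list(_ALPHABET))))
        for k in range(n_ins)
    )
    mutations = MutationSet(tuple(substitutions), insertions, deletions)
    mutant = apply_mutations(base, mutations)
    mutant = VHHSequence(
        f"pair-mutant-{seed}", mutant.residues, mutant.numbering, mutant.regions
    )
    truth = {"n_sub": n_sub, "n_ins": n_ins, "n_del": n_del,
             "mutations": mutations}
    return base, mutant, truth


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """n approximately uniform points on a sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    pts = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )
    return center + radius * pts


def make_structure(
    sequence: str,
    ca_positions: np.ndarray,
    sidechain_directions: np.ndarray | None = None,
    extra_atoms: list[tuple[int, str, np.ndarray]] | None = None,
) -> Structure:
    """Build a pseudo-atom Structure from a one-letter sequence.

    Each residue gets a 4-atom backbone plate (N, CA, C, O) around its CA
    position and, for non-Gly residues, a two-atom side chain (CB at 1.8 Å,
    CG at 3.2 Å along its direction; default +z).  ``extra_atoms`` appends
    further atoms ``(res_index, atom_name, coord)`` to existing residues —
    used by fixtures to plant shells, shields and rewired side chains.
    """
    ca = np.asarray(ca_positions, dtype=float)
    n = len(sequence)
    if ca.shape != (n, 3):
        raise ValueError("ca_positions must have shape (n_residues, 3)")
    if sidechain_directions is None:
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    else:
        dirs = np.asarray(sidechain_directions, dtype=float)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    names, res_ids, res_names, coords = [], [], [], []
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE.get(aa, "UNK")
        backbone = [
            ("N", ca[i] + [-1.2, -0.5, 0.0]),
            ("CA", ca[i]),
            ("C", ca[i] + [1.2, -0.5, 0.0]),
            ("O", ca[i] + [1.6, -1.6, 0.0]),
        ]
        sidechain = []
        if aa != "G":
            sidechain = [
                ("CB", ca[i] + 1.8 * dirs[i]),
                ("CG", ca[i] + 3.2 * dirs[i]),
            ]
        for atom_name, coord in backbone + sidechain:
            names.append(atom_name)
            res_ids.append(i + 1)
            res_names.append(res_name)
            coords.append(coord)
    for res_index, atom_name, coord in extra_atoms or []:
        insert_at = max(
            k for k, rid in enumerate(res_ids) if rid == res_index + 1
        ) + 1
        names.insert(insert_at, atom_name)
        res_ids.insert(insert_at, res_index + 1)
        res_names.insert(insert_at, ONE_TO_THREE.get(sequence[res_index], "UNK"))
        coords.insert(insert_at, np.asarray(coord, dtype=float))
    atoms = bst.AtomArray(len(names))
    atoms.coord = np.asarray(coords)
    atoms.atom_name = np.asarray(names)
    atoms.res_id = np.asarray(res_ids)
    atoms.res_name = np.asarray(res_names)
    atoms.chain_id = np.full(len(names), "A")
    atoms.element = np.array([nm[0] for nm in names])
    atoms.hetero = np.zeros(len(names), dtype=bool)
    return Structure(atoms)


def make_exposure_fixture(seed: int = 0) -> tuple[Structure, dict]:
    """A chain where exactly three valines are solvent-exposed.

    Serine background with five valines on a straight, well-spaced chain;
    two of the valines are enclosed in a spherical shell of extra pseudo
    atoms (attached to their own residue) and are therefore buried.  Ground
    truth lists the exposed and buried valine indices.
    """
    sequence = "SSVSSVSSVSSVSSVSS"  # valines at indices 2, 5, 8, 11, 14
    n = len(sequence)
    ca = np.zeros((n, 3))
    ca[:, 0] = np.arange(n) * 7.0
    buried = [5, 11]
    extra = []
    for idx in buried:
        center = ca[idx] + [0.0, 0.0, 1.5]
        # the cage is carried by the neighbouring serine so the valine's own
        # surface budget is untouched
        for k, pt in enumerate(_fibonacci_sphere(120, 6.0, center)):
            extra.append((idx + 1, f"S{k%9}", pt))
    structure = make_structure(sequence, ca, extra_atoms=extra)
    truth = {
        "exposed_val": [2, 8, 14],
        "buried_val": buried,
    }
    return structure, truth


def make_two_patch_fixture(seed: int = 0) -> tuple[Structure, np.ndarray, dict]:
    """A chain with two well-separated poorly soluble surface patches.

    24 residues on a line, everything solvent-exposed; two phenylalanine
    triplets (indices 4-6 and 16-18) are packed at 4 Å spacing while the
    rest of the chain is spaced at 8 Å, so each triplet is mutually within
    the 6 Å hotspot distance but more than 6 Å from any other residue.
    Returns the structure, a planted per-residue solubility score vector
    (patches at -2.0, background at +0.3) and the ground-truth hotspot
    memberships.
    """
    patches = [(4, 5, 6), (16, 17, 18)]
    patch_set = {i for p in patches for i in p}
    sequence = "".join("F" if i in patch_set else "S" for i in range(24))
    x = 0.0
    xs = []
    for i in range(24):
        xs.append(x)
        gap = 4.0 if (i in patch_set and i + 1 in patch_set) else 8.0
        x += gap
    ca = np.zeros((24, 3))
    ca[:, 0] = xs
    structure = make_structure(sequence, ca)
    scores = np.where(
        [i in patch_set for i in range(24)], -2.0, 0.3
    ).astype(float)
    truth = {"memberships": [tuple(p) for p in patches]}
    return structure, scores, truth


def make_shielding_pair(
    seed: int = 0,
) -> tuple[Structure, Structure, np.ndarray, dict]:
    """The same sequence in an exposed and a loop-shielded conformation.

    A hydrophobic patch (phenylalanines 8-11) sits on a linear scaffold; the
    four C-terminal "loop" residues either point away from the patch
    (exposed conformation) or wrap it in shells of pseudo atoms (shielded
    conformation), burying the patch side chains.  Returns (exposed,
    shielded, planted scores, truth); the planted per-residue scores mark
    the patch as poorly soluble in both conformations, so any drop in
    hotspot membership is purely structural.
    """
    n = 20
    patch = [8, 9, 10, 11]
    loop = [16, 17, 18, 19]
    sequence = "".join("F" if i in patch else "S" for i in range(n))
    ca = np.zeros((n, 3))
    x = 0.0
    for i in range(n):
        ca[i, 0] = x
        x += 4.5 if (i in patch and i + 1 in patch) else 7.0
    exposed = make_structure(sequence, ca.copy())
    shield_atoms = []
    for loop_res, patch_res in zip(loop, patch):
        center = ca[patch_res] + [0.0, 0.0, 2.5]
        for k, pt in enumerate(_fibonacci_sphere(110, 6.0, center)):
            shield_atoms.append((loop_res, f"S{k%9}", pt))
    shielded = make_structure(sequence, ca.copy(), extra_atoms=shield_atoms)
    scores = np.where([i in patch for i in range(n)], -2.0, 0.3).astype(float)
    truth = {"patch": patch, "loop": loop}
    return exposed, shielded, scores, truth


def make_rewired_pair(seed: int = 0) -> tuple[Structure, Structure, dict]:
    """Wild-type / mutant structures where one residue rewires 5 contacts.

    Twelve residues on a line; residue 5's (0-based) side chain reaches a
    point 6 Å above its CA where the side-chain tips of five
    sequence-distant partners converge (3 Å away each).  In the "mutant" the
    rewired residue's side chain is swung 20 Å aside, breaking exactly those
    five contacts while every other pair is untouched.
    """
    n = 12
    mutated = 5
    partners = [0, 2, 8, 10, 11]
    sequence = "G" * n  # glycines: no default side chains to confound contacts
    ca = np.zeros((n, 3))
    ca[:, 0] = np.arange(n) * 8.0
    hub = ca[mutated] + [0.0, 0.0, 6.0]
    angles = 2 * np.pi * np.arange(len(partners)) / len(partners)
    tips = hub + 3.0 * np.stack(
        [np.cos(angles), np.sin(angles), np.zeros_like(angles)], axis=1
    )

    def build(mutant: bool) -> Structure:
        extra = []
        for j, tip in zip(partners, tips):
            extra.append((j, "CD", (ca[j] + tip) / 2.0))
            extra.append((j, "CE", tip))
        if mutant:
            extra.append((mutated, "CD", ca[mutated] + [0.0, 0.0, 14.0]))
            extra.append((mutated, "CE", ca[mutated] + [0.0, 0.0, 20.0]))
        else:
            extra.append((mutated, "CD", (ca[mutated] + hub) / 2.0))
            extra.append((mutated, "CE", hub))
        return make_structure(sequence, ca, extra_atoms=extra)

    truth = {"mutated": mutated, "partners": partners}
    return build(False), build(True), truth


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def make_ensemble(
    seed: int = 0,
    n_frames: int = 200,
    basin_proportions: tuple[float, ...] = (0.85, 0.10, 0.05),
    displacement: float = 8.0,
    jitter: float = 0.15,
    n_residues: int = 30,
) -> tuple[ConformationEnsemble, dict]:
    """A conformational ensemble with planted cluster basins.

    The backbone is a helix-like curve of CA pseudo atoms.  Each basin
    rigidly displaces a 10-residue loop segment in its own direction by
    ``displacement`` Å; every atom then receives isotropic Gaussian jitter.
    Frame order is shuffled (deterministically); ground truth contains the
    per-frame basin labels and the planted frame counts.
    """
    rng = np.random.default_rng(seed)
    proportions = np.asarray(basin_proportions, dtype=float)
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("basin proportions must sum to 1")
    counts = np.floor(proportions * n_frames).astype(int)
    counts[0] += n_frames - counts.sum()
    t = np.arange(n_residues)
    base = np.stack(
        [8.0 * np.cos(0.6 * t), 8.0 * np.sin(0.6 * t), 1.5 * t], axis=1
    )
    segment = slice(10, 20)
    directions = [
        np.zeros(3),
        np.array([1.0, 0.0, 0.0]),
        np.array([-1.0, 0.3, 0.2]) / np.linalg.norm([-1.0, 0.3, 0.2]),
        np.array([0.2, -1.0, 0.4]) / np.linalg.norm([0.2, -1.0, 0.4]),
        np.array([0.0, 0.5, -1.0]) / np.linalg.norm([0.0, 0.5, -1.0]),
    ]
    if len(counts) > len(directions):
        raise ValueError(f"at most {len(directions)} basins supported")
    labels = np.repeat(np.arange(len(counts)), counts)
    order = rng.permutation(n_frames)
    labels = labels[order]
    frames = []
    sequence = "A" * n_residues
    for label in labels:
        coords = base.copy()
        coords[segment] += displacement * directions[label]
        coords += rng.normal(0.0, jitter, size=coords.shape)
        frames.append(make_structure(sequence, coords))
    ensemble = ConformationEnsemble.from_structures(frames)
    truth = {"labels": labels, "counts": counts.tolist()}
    return ensemble, truth
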