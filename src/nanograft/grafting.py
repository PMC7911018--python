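"""CDR grafting, mutation panels and numbering-aligned sequence accounting.

All comparisons here are anchored on scheme positions, never on a
gap-optimising aligner: two sequences differ at position 37 if and only if
both carry a residue numbered 37 and those residues differ.  Positions held
by only one sequence are indels.  This is the convention under which the
classical humanization bookkeeping (hallmark swaps, fingerprint counts,
boundary insertions such as the FW4-initial Trp) is deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import DesignConflictError, GraftError, StaleMutationError
from .numbering import (
    CAMELID_TETRAD,
    DEFAULT_FINGERPRINTS,
    HALLMARK_POSITIONS,
    HUMAN_TETRAD,
    FingerprintReference,
    VHHSequence,
    scheme_key,
)

#: Default fingerprint sites mutated by species-conversion panel options.
FINGERPRINT_SITES = (35, 50, 89, 91)


def _check_unique(entries, category):
    positions = [e[0] for e in entries]
    dup = [p for p, c in Counter(positions).items() if c > 1]
    if dup:
        raise DesignConflictError(
            f"{category} target scheme position(s) {dup} more than once"
        )


@dataclass(frozen=True)
class MutationSet:
    """Position-anchored substitutions, insertions and deletions.

    ``substitutions`` are ``(scheme_pos, from_residue, to_residue)``;
    ``insertions`` and ``deletions`` are ``(scheme_pos, residue)``.  No two
    entries share a scheme position within one category.
    """

    substitutions: tuple[tuple[str, str, str], ...] = ()
    insertions: tuple[tuple[str, str], ...] = ()
    deletions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        _check_unique(self.substitutions, "substitutions")
        _check_unique(self.insertions, "insertions")
        _check_unique(self.deletions, "deletions")

    def __len__(self):
        return len(self.substitutions) + len(self.insertions) + len(self.deletions)

    def inverse(self) -> "MutationSet":
        """The mutation set that exactly reverts this one."""
        return MutationSet(
            substitutions=tuple((p, to, frm) for p, frm, to in self.substitutions),
            insertions=self.deletions,
            deletions=self.insertions,
        )


def apply_mutations(vhh: VHHSequence, mutations: MutationSet) -> VHHSequence:
    """Apply a MutationSet, returning a new sequence.

    Every substitution's ``from_residue`` and every deletion's residue must
    match the sequence (re-applying a set therefore fails); insertion
    positions must be vacant.
    """
    mapping = vhh.position_map()
    stale = []
    for pos, frm, _to in mutations.substitutions:
        if mapping.get(pos) != frm:
            stale.append(pos)
    for pos, res in mutations.deletions:
        if mapping.get(pos) != res:
            stale.append(pos)
    for pos, _res in mutations.insertions:
        if pos in mapping:
            stale.append(pos)
    if stale:
        raise StaleMutationError(
            f"{vhh.seq_id}: mutation set does not match sequence at "
            f"position(s) {sorted(stale, key=scheme_key)}",
            positions=stale,
        )
    for pos, _frm, to in mutations.substitutions:
        mapping[pos] = to
    for pos, _res in mutations.deletions:
        del mapping[pos]
    for pos, res in mutations.insertions:
        mapping[pos] = res
    return VHHSequence.from_position_map(vhh.seq_id, mapping, vhh.regions)


@dataclass(frozen=True)
class SequenceDiff:
    """Numbering-aligned differences of sequence ``a`` relative to ``b``.

    Substitutions are recorded as ``(pos, from=b residue, to=a residue)`` so
    that ``apply_mutations(b, diff.as_mutation_set())`` reconstructs ``a``;
    insertions are positions present only in ``a``, deletions positions
    present only in ``b``.  Each substitution additionally carries its region
    and the fingerprint class of both sides.
    """

    a_id: str
    b_id: str
    substitutions: tuple[tuple[str, str, str], ...]
    insertions: tuple[tuple[str, str], ...]
    deletions: tuple[tuple[str, str], ...]
    regions: tuple[str, ...] = ()          # region per substitution
    classes_a: tuple[str, ...] = ()        # fingerprint class of the a-side residue
    classes_b: tuple[str, ...] = ()
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_sub(self) -> int:
        return len(self.substitutions)

    @property
    def n_ins(self) -> int:
        return len(self.insertions)

    @property
    def n_del(self) -> int:
        return len(self.deletions)

    def substitution_positions(self) -> tuple[str, ...]:
        return tuple(p for p, _f, _t in self.substitutions)

    def fingerprint_counts(self, side: str = "a") -> Counter:
        """Counter of fingerprint classes of the substituted residues."""
        classes = self.classes_a if side == "a" else self.classes_b
        return Counter(classes)

    def as_mutation_set(self) -> MutationSet:
        return MutationSet(
            substitutions=self.substitutions,
            insertions=self.insertions,
            deletions=self.deletions,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: scheme_pos, kind, from, to, region, classes."""
        rows = []
        for (pos, frm, to), region, ca, cb in zip(
            self.substitutions, self.regions, self.classes_a, self.classes_b
        ):
            rows.append((pos, "substitution", frm, to, region, ca, cb))
        for pos, res in self.insertions:
            rows.append((pos, "insertion", "-", res, None, None, None))
        for pos, res in self.deletions:
            rows.append((pos, "deletion", res, "-", None, None, None))
        frame = pd.DataFrame(
            rows,
            columns=[
                "scheme_pos", "kind", "from", "to",
                "region", "class_a", "class_b",
            ],
        )
        key = frame["scheme_pos"].map(scheme_key)
        return frame.iloc[key.argsort(kind="stable")].reset_index(drop=True)


def diff_sequences(
    a: VHHSequence,
    b: VHHSequence,
    scope: tuple[str, ...] | None = None,
    ref: FingerprintReference = DEFAULT_FINGERPRINTS,
) -> SequenceDiff:
    """Numbering-aligned difference of ``a`` relative to ``b``.

    ``scope`` optionally restricts the comparison to a subset of region
    names (e.g. ``("FW1", "FW2", "FW3", "FW4")`` for framework-only
    accounting).
    """
    map_a, map_b = a.position_map(), b.position_map()
    positions = sorted(set(map_a) | set(map_b), key=scheme_key)
    if scope is not None:
        scope = tuple(scope)
        positions = [p for p in positions if a.regions.region_of(p) in scope]
    subs, ins, dels, regions, cls_a, cls_b = [], [], [], [], [], []
    for pos in positions:
        ra, rb = map_a.get(pos), map_b.get(pos)
        if ra is not None and rb is not None:
            if ra != rb:
                subs.append((pos, rb, ra))
                regions.append(a.regions.region_of(pos))
                cls_a.append(ref.classify(pos, ra))
                cls_b.append(ref.classify(pos, rb))
        elif ra is not None:
            ins.append((pos, ra))
        else:
            dels.append((pos, rb))
    return SequenceDiff(
        a.seq_id, b.seq_id,
        tuple(subs), tuple(ins), tuple(dels),
        tuple(regions), tuple(cls_a), tuple(cls_b),
    )


def graft_cdrs(
    donor: VHHSequence,
    acceptor: VHHSequence,
    seq_id: str | None = None,
    cdr_intervals: dict[str, tuple[int, int]] | None = None,
) -> tuple[VHHSequence, dict[str, str]]:
    """Graft the donor's CDR1-3 onto the acceptor's framework.

    The product carries the acceptor's residues at every framework scheme
    position and the donor's residues (verbatim, including insertion codes)
    at every CDR position, then is renumbered from scratch.

    ``cdr_intervals`` optionally overrides the scheme interval transferred
    for a CDR, e.g. ``{"CDR3": (95, 101)}`` to leave position 102 with the
    scaffold — the convention under which grafting onto a scaffold lacking
    Tyr102 deletes that residue from the product.

    Returns the grafted sequence and a provenance map
    ``scheme_pos -> "donor" | "acceptor"``.
    """
    regions = acceptor.regions
    intervals = {}
    for name in ("CDR1", "CDR2", "CDR3"):
        region = regions[name]
        intervals[name] = (region.start, region.end)
    if cdr_intervals:
        intervals.update({k: tuple(v) for k, v in cdr_intervals.items()})

    def in_cdr(pos: str) -> bool:
        n = scheme_key(pos)[0]
        return any(lo <= n <= hi for lo, hi in intervals.values())

    mapping: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for pos, res in acceptor.position_map().items():
        if not in_cdr(pos):
            mapping[pos] = res
            provenance[pos] = "acceptor"
    n_donor = 0
    for pos, res in donor.position_map().items():
        if in_cdr(pos):
            mapping[pos] = res
            provenance[pos] = "donor"
            n_donor += 1
    if n_donor == 0:
        raise GraftError(
            f"donor {donor.seq_id} contributes no CDR residues; check numbering"
        )
    graft_id = seq_id or f"{donor.seq_id}-on-{acceptor.seq_id}"
    # Renumber from scratch: re-derive the raw string and per-region lengths,
    # then run the numbering engine (also validates insertion capacity).
    from .numbering import number_sequence

    ordered = sorted(mapping.items(), key=lambda kv: scheme_key(kv[0]))
    raw = "".join(res for _, res in ordered)
    lengths = Counter(regions.region_of(pos) for pos, _ in ordered)
    try:
        product = number_sequence(
            raw, regions=regions, region_lengths=dict(lengths), seq_id=graft_id
        )
    except Exception as exc:
        raise GraftError(f"grafting {graft_id} failed renumbering: {exc}") from exc
    return product, provenance


def hallmark_mutations(vhh: VHHSequence, target: str) -> MutationSet:
    """Mutations converting the FW2 tetrad to the camelid or human signature."""
    tetrad = CAMELID_TETRAD if target == "camelid" else HUMAN_TETRAD
    if target not in ("camelid", "human"):
        raise ValueError(f"unknown hallmark target {target!r}")
    subs = []
    for pos, to in zip(HALLMARK_POSITIONS, tetrad):
        current = vhh.get(pos)
        if current is None:
            raise StaleMutationError(
                f"{vhh.seq_id}: hallmark position {pos} missing", positions=[pos]
            )
        if current != to:
            subs.append((pos, current, to))
    return MutationSet(substitutions=tuple(subs))


def fingerprint_mutations(
    vhh: VHHSequence,
    target: str,
    sites: tuple[int, ...] = FINGERPRINT_SITES,
    ref: FingerprintReference = DEFAULT_FINGERPRINTS,
) -> MutationSet:
    """Mutations converting fingerprint sites to a species prototype.

    Sites whose residue already belongs to the target species' set are left
    untouched; the others are substituted with the reference prototype.
    """
    if target not in ("camelid", "human", "llama"):
        raise ValueError(f"unknown fingerprint target {target!r}")
    species = "llama" if target == "camelid" else target
    subs = []
    for site in sites:
        pos = str(site)
        current = vhh.get(pos)
        if current is None:
            continue
        wanted = f"{species}-type"
        if ref.classify(pos, current) != wanted:
            subs.append((pos, current, ref.prototype(site, species)))
    return MutationSet(substitutions=tuple(subs))


@dataclass(frozen=True)
class PanelEntry:
    name: str
    sequence: VHHSequence
    from_graft: MutationSet   # audit trail: mutations applied on top of the graft
    provenance: dict[str, str]


def build_variant_panel(
    donor: VHHSequence,
    acceptor: VHHSequence,
    hallmarks: str | None = None,
    fingerprints: str | None = None,
    fingerprint_sites: tuple[int, ...] = FINGERPRINT_SITES,
    ref: FingerprintReference = DEFAULT_FINGERPRINTS,
    cdr_intervals: dict[str, tuple[int, int]] | None = None,
) -> list[PanelEntry]:
    """Construct the grafting panel: the plain graft plus, if requested, a
    variant with hallmark- and/or fingerprint-converted framework.

    Returns ``[graft]`` with default options, or ``[graft, variant]`` when a
    hallmark or fingerprint target state is given.  The variant's
    ``from_graft`` MutationSet is the auditable difference from the plain
    graft.
    """
    graft, provenance = graft_cdrs(donor, acceptor, cdr_intervals=cdr_intervals)
    entries = [PanelEntry("graft", graft, MutationSet(), provenance)]
    if hallmarks is None and fingerprints is None:
        return entries
    subs: list[tuple[str, str, str]] = []
    if hallmarks is not None:
        subs.extend(hallmark_mutations(graft, hallmarks).substitutions)
    if fingerprints is not None:
        fp = fingerprint_mutations(graft, fingerprints, fingerprint_sites, ref)
        overlap = {p for p, *_ in subs} & {p for p, *_ in fp.substitutions}
        if overlap:
            raise DesignConflictError(
                f"hallmark and fingerprint options both target position(s) "
                f"{sorted(overlap, key=scheme_key)}"
            )
        subs.extend(fp.substitutions)
    mutations = MutationSet(substitutions=tuple(subs))
    variant = apply_mutations(graft, mutations)
    variant = VHHSequence(
        f"{graft.seq_id}-variant", variant.residues, variant.numbering, variant.regions
    )
    entries.append(PanelEntry("variant", variant, mutations, provenance))
    return entries
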