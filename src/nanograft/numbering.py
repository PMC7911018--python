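"""VHH sequence numbering, region segmentation and hallmark detection.

A VHH (nanobody) variable domain is segmented into seven contiguous regions,
FW1-CDR1-FW2-CDR2-FW3-CDR3-FW4, and every residue is assigned a *scheme
position*: a string such as ``"37"`` or ``"102A"`` (integer part plus an
optional insertion-code letter).  The shipped default is a simplified
Kabat-style numbering whose CDR intervals are chosen so that the classical
framework landmarks land in their conventional regions: the FW2 hallmark
tetrad at 37/44/45/47, the species fingerprint sites 35/50/89/91 inside the
frameworks, CDR3 ending at 102 and FW4 opening with the (optionally absent)
Trp at 103.

Region boundaries are data, not code: they are read from
``data/regions.tsv`` and can be swapped for another convention without
touching the implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import IncompleteFrameworkError, NumberingError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: FW2 hallmark scheme positions and their species prototypes.
HALLMARK_POSITIONS = ("37", "44", "45", "47")
CAMELID_TETRAD = ("F", "E", "R", "F")
HUMAN_TETRAD = ("V", "G", "L", "W")

REGION_ORDER = ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3", "FW4")

#: Sequence-length bounds accepted by :func:`number_sequence`.
MIN_LENGTH, MAX_LENGTH = 90, 140

_INSERTION_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def scheme_key(pos: str) -> tuple[int, str]:
    """Sort key for a scheme position string ("100A" -> (100, "A"))."""
    pos = pos.strip()
    digits = "".join(c for c in pos if c.isdigit())
    suffix = pos[len(digits):]
    return int(digits), suffix


@dataclass(frozen=True)
class Region:
    name: str
    start: int          # first scheme position (inclusive)
    end: int            # last scheme position (inclusive)
    fill: str = "left"  # "left" or "right", see data/regions.tsv

    @property
    def capacity(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: str) -> bool:
        return self.start <= scheme_key(pos)[0] <= self.end


@dataclass(frozen=True)
class RegionMap:
    """Ordered, contiguous, non-overlapping region boundaries."""

    regions: tuple[Region, ...]

    def __post_init__(self):
        names = tuple(r.name for r in self.regions)
        if names != REGION_ORDER:
            raise ValueError(f"regions must be exactly {REGION_ORDER}, got {names}")
        for prev, cur in zip(self.regions, self.regions[1:]):
            if cur.start != prev.end + 1:
                raise ValueError(
                    f"regions must be contiguous: {prev.name} ends at {prev.end}, "
                    f"{cur.name} starts at {cur.start}"
                )

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def region_of(self, pos: str) -> str:
        """Name of the region containing a scheme position."""
        n = scheme_key(pos)[0]
        for r in self.regions:
            if r.start <= n <= r.end:
                return r.name
        raise KeyError(f"scheme position {pos!r} outside the numbering scheme")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)


def _load_default_regions() -> RegionMap:
    text = resources.files("nanograft.data").joinpath("regions.tsv").read_text()
    regions = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("region\t"):
            continue
        name, start, end, fill = line.split("\t")
        regions.append(Region(name, int(start), int(end), fill))
    return RegionMap(tuple(regions))


DEFAULT_REGIONS = _load_default_regions()


@dataclass(frozen=True)
class VHHSequence:
    """An amino-acid sequence with scheme numbering and region annotation.

    ``numbering[i]`` is the scheme position of ``residues[i]``; positions are
    strictly increasing in scheme order and each maps to exactly one index.
    """

    seq_id: str
    residues: str
    numbering: tuple[str, ...]
    regions: RegionMap = DEFAULT_REGIONS
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.residues) != len(self.numbering):
            raise ValueError("residues and numbering must have equal length")
        keys = [scheme_key(p) for p in self.numbering]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("scheme positions must be strictly increasing")
        bad = set(self.residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"invalid residue codes: {sorted(bad)}")
        if "X" in self.residues:
            warnings.warn(
                f"{self.seq_id}: sequence contains X residues; they are "
                "excluded from fingerprint classification",
                stacklevel=2,
            )
        object.__setattr__(
            self, "_index", {p: i for i, p in enumerate(self.numbering)}
        )

    def __len__(self) -> int:
        return len(self.residues)

    def get(self, pos: str) -> str | None:
        """Residue at a scheme position, or None if the position is absent."""
        i = self._index.get(pos)
        return None if i is None else self.residues[i]

    def index_of(self, pos: str) -> int | None:
        return self._index.get(pos)

    def region_of(self, pos: str) -> str:
        return self.regions.region_of(pos)

    def region_sequence(self, name: str) -> str:
        region = self.regions[name]
        return "".join(
            res
            for res, pos in zip(self.residues, self.numbering)
            if region.contains(pos)
        )

    def position_map(self) -> dict[str, str]:
        return dict(zip(self.numbering, self.residues))

    @classmethod
    def from_position_map(
        cls,
        seq_id: str,
        mapping: dict[str, str],
        regions: RegionMap = DEFAULT_REGIONS,
    ) -> "VHHSequence":
        """Build a sequence directly from a scheme-position -> residue map."""
        items = sorted(mapping.items(), key=lambda kv: scheme_key(kv[0]))
        return cls(
            seq_id,
            "".join(res for _, res in items),
            tuple(pos for pos, _ in items),
            regions,
        )

    def to_record(self) -> SeqRecord:
        return SeqRecord(Seq(self.residues), id=self.seq_id, description="")


@dataclass(frozen=True)
class HallmarkState:
    """The FW2 tetrad (positions 37/44/45/47) and its species class."""

    tetrad: tuple[str, str, str, str]
    classification: str  # "camelid" | "human" | "hybrid"


def _default_length_plan(
    seq: str, regions: RegionMap, overrides: dict[str, int] | None
) -> dict[str, int]:
    """Per-region residue counts for a raw sequence.

    FW1-FW3 and the first two CDRs take their full canonical widths; FW4 is
    anchored at the C terminus and is 11 residues when the conserved
    FW4-initial Trp is present, 10 otherwise; CDR3 absorbs the remaining
    length variation.  Any region may be overridden explicitly.
    """
    overrides = dict(overrides or {})
    plan: dict[str, int] = {}
    for r in regions.regions:
        if r.name in overrides:
            plan[r.name] = overrides[r.name]
        elif r.name == "FW4":
            cap = r.capacity
            if len(seq) >= cap and seq[-cap] == "W":
                plan[r.name] = cap
            else:
                plan[r.name] = cap - 1
        elif r.name != "CDR3":
            plan[r.name] = r.capacity
    if "CDR3" not in plan:
        plan["CDR3"] = len(seq) - sum(plan.values())
    return plan


def number_sequence(
    seq: str,
    regions: RegionMap = DEFAULT_REGIONS,
    region_lengths: dict[str, int] | None = None,
    seq_id: str = "seq",
) -> VHHSequence:
    """Assign scheme numbering and region annotation to a raw sequence.

    Parameters
    ----------
    seq
        One-letter amino-acid string (``X`` tolerated, flagged downstream).
    regions
        Region boundary convention; defaults to the shipped scheme.
    region_lengths
        Optional explicit residue count per region.  Unspecified frameworks
        default to their canonical widths, FW4 to 10/11 depending on the
        presence of the FW4-initial Trp, and CDR3 to the remainder.

    Raises
    ------
    NumberingError
        If the sequence is outside the accepted length bounds, a region
        cannot be anchored, or a framework would require insertion codes
        (insertion codes are assigned within CDR loops only).
    """
    seq = seq.strip().upper()
    bad = set(seq) - AMINO_ACIDS - {"X"}
    if bad:
        raise NumberingError(f"{seq_id}: invalid residue codes {sorted(bad)}")
    if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
        raise NumberingError(
            f"{seq_id}: length {len(seq)} outside [{MIN_LENGTH}, {MAX_LENGTH}]; "
            "cannot anchor region FW1",
            region="FW1",
        )

    plan = _default_length_plan(seq, regions, region_lengths)
    consumed = 0
    numbering: list[str] = []
    for region in regions.regions:
        n = plan[region.name]
        if n < 0 or consumed + n > len(seq):
            raise NumberingError(
                f"{seq_id}: cannot anchor region {region.name} "
                f"({n} residues requested, {len(seq) - consumed} available)",
                region=region.name,
            )
        if n > region.capacity:
            if not region.name.startswith("CDR"):
                raise NumberingError(
                    f"{seq_id}: region {region.name} has {n} residues but "
                    f"capacity {region.capacity}; insertion codes are "
                    "assigned within CDRs only",
                    region=region.name,
                )
            extra = n - region.capacity
            if extra > len(_INSERTION_LETTERS):
                raise NumberingError(
                    f"{seq_id}: region {region.name} exceeds insertion-code "
                    f"capacity ({extra} > {len(_INSERTION_LETTERS)})",
                    region=region.name,
                )
            positions = [str(p) for p in range(region.start, region.end + 1)]
            positions += [
                f"{region.end}{_INSERTION_LETTERS[k]}" for k in range(extra)
            ]
        elif region.fill == "right":
            positions = [str(p) for p in range(region.end - n + 1, region.end + 1)]
        else:
            positions = [str(p) for p in range(region.start, region.start + n)]
        numbering.extend(positions)
        consumed += n
    if consumed != len(seq):
        raise NumberingError(
            f"{seq_id}: length plan covers {consumed} residues, sequence has "
            f"{len(seq)}; cannot anchor region CDR3",
            region="CDR3",
        )
    return VHHSequence(seq_id, seq, tuple(numbering), regions)


def detect_hallmarks(vhh: VHHSequence) -> HallmarkState:
    """Classify the FW2 hallmark tetrad at scheme positions 37/44/45/47.

    The camelid signature is F-E-R-F, the human one V-G-L-W; anything else
    is a hybrid.
    """
    tetrad = tuple(vhh.get(p) for p in HALLMARK_POSITIONS)
    missing = [p for p, r in zip(HALLMARK_POSITIONS, tetrad) if r is None]
    if missing:
        raise IncompleteFrameworkError(
            f"{vhh.seq_id}: hallmark position(s) {missing} absent from numbering"
        )
    if tetrad == CAMELID_TETRAD:
        classification = "camelid"
    elif tetrad == HUMAN_TETRAD:
        classification = "human"
    else:
        classification = "hybrid"
    return HallmarkState(tetrad, classification)


class FingerprintReference:
    """Per-position sets of human-type and llama-type framework residues.

    The first residue of each set is the prototype installed when a panel
    operation mutates a position toward that species.
    """

    def __init__(self, table: dict[int, tuple[tuple[str, ...], tuple[str, ...]]]):
        for pos, (human, llama) in table.items():
            if set(human) & set(llama):
                raise ValueError(
                    f"human and llama sets overlap at position {pos}"
                )
        self._table = dict(table)

    @classmethod
    def default(cls) -> "FingerprintReference":
        text = resources.files("nanograft.data").joinpath("fingerprints.tsv").read_text()
        table = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position\t"):
                continue
            pos, human, llama = line.split("\t")
            table[int(pos)] = (tuple(human.split(",")), tuple(llama.split(",")))
        return cls(table)

    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self._table))

    def classify(self, scheme_pos: str, residue: str) -> str:
        """Label a residue as human-type, llama-type or unclassified."""
        key, suffix = scheme_key(str(scheme_pos))
        if suffix or key not in self._table or residue == "X":
            return "unclassified"
        human, llama = self._table[key]
        if residue in human:
            return "human-type"
        if residue in llama:
            return "llama-type"
        return "unclassified"

    def prototype(self, scheme_pos: int, species: str) -> str:
        human, llama = self._table[int(scheme_pos)]
        if species == "human":
            return human[0]
        if species == "llama":
            return llama[0]
        raise ValueError(f"unknown species {species!r}")


DEFAULT_FINGERPRINTS = FingerprintReference.default()


def classify_residue(
    scheme_pos: str, residue: str, ref: FingerprintReference = DEFAULT_FINGERPRINTS
) -> str:
    """Species fingerprint class of a residue at a scheme position."""
    return ref.classify(scheme_pos, residue)


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA file into an ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(path, sequences) -> None:
    """Write VHHSequence objects (or (id, seq) pairs) to a FASTA file."""
    records = []
    for item in sequences:
        if isinstance(item, VHHSequence):
            records.append(item.to_record())
        else:
            seq_id, seq = item
            records.append(SeqRecord(Seq(seq), id=seq_id, description=""))
    SeqIO.write(records, str(path), "fasta")
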