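"""SYNTHETIC stand-in sequences for the A10/C8 humanization panel.

The published construct sequences (donor A10, scaffold C8WT and the derived
mutants C8H, C8VI, A10C, A10VI, A10-HLL) are not redistributed here.  This
module instead ships *synthetic* sequences, written from scratch, that
reproduce every documented relationship between the constructs:

* A10 carries the camelid FW2 hallmark tetrad F37/E44/R45/F47, the human
  fingerprint residues Gly35/Ala50/Tyr91 plus Thr89, the FW4-initial Trp103
  and a CDR3 ending in Tyr102.
* C8WT carries the human tetrad V37/G44/L45/W47, the llama fingerprints
  Tyr35/Ser50/Leu89/Phe91, and lacks both Tyr102 and Trp103.
* The frameworks of A10 and C8WT differ by 14 substitutions plus the Trp
  insertion at the start of FW4; of A10's residues at the 14 sites, seven
  classify human-type and seven llama-type.
* C8VI's framework differs from A10's at exactly four positions
  (Leu11, Ser35, Leu78, Val89); C8H is C8VI with the human VGLW tetrad, so
  C8H and C8VI interconvert by the tetrad swap alone.
* Grafting A10's CDRs (with the CDR3 boundary drawn at 101, leaving 102 to
  the scaffold) onto C8WT gives A10C and onto C8VI gives A10VI; humanizing
  the fingerprints and camelizing the hallmarks of A10C gives A10-HLL.
  The resulting difference counts are A10VI vs A10 = 4 substitutions + the
  Tyr102 deletion, A10-HLL vs A10C = 8 and A10-HLL vs A10VI = 4.

Construct names and derivations are also available as a JSON-style manifest
(:func:`panel_manifest`) rather than being baked into the operations.
"""

from __future__ import annotations

from .grafting import (
    MutationSet,
    apply_mutations,
    build_variant_panel,
    graft_cdrs,
)
from .numbering import VHHSequence, number_sequence

#: CDR3 scheme interval used when grafting onto the C8 scaffolds: position
#: 102 is treated as scaffold, so grafting onto a scaffold that lacks Tyr102
#: removes that residue from the product.
PANEL_CDR_INTERVALS = {"CDR3": (95, 101)}

# Framework and CDR segments (synthetic).  Scheme positions of the special
# residues: FW1 holds 1/5/11, FW2 holds 33-51 (hallmarks 37/44/45/47,
# fingerprints 35/50, plus 42), FW3 holds 57-94 (78/89/91), FW4 holds
# 103-113 (108; leading Trp103 where present).
_A10_FW1 = "EVQLVESGGGSVQAGGSLRLSCAAS"   # E1  V5  S11
_C8_FW1 = "QVQLQESGGGLVQAGGSLRLSCAAS"    # Q1  Q5  L11
_C8VI_FW1 = "EVQLVESGGGLVQAGGSLRLSCAAS"  # A10 FW1 with S11->L

_A10_FW2 = "AMGWFRQAPFKEREFVAAI"         # G35 F37 F42 E44 R45 F47 A50
_C8_FW2 = "AMYWVRQAPGKGLEWVASI"          # Y35 V37 G42 G44 L45 W47 S50
_C8VI_FW2 = "AMSWFRQAPFKEREFVAAI"        # A10 FW2 with G35->S

_A10_FW3 = "STYYADSVKGRFTISRDNAKNVLYLQMNSLRATDYYCA"   # V78 T89 Y91
_C8_FW3 = "STYYADSVKGRFTISRDNAKNLLYLQMNSLRALDFYCA"    # L78 L89 F91
_C8VI_FW3 = "STYYADSVKGRFTISRDNAKNLLYLQMNSLRAVDYYCA"  # L78 V89 Y91

_A10_FW4 = "WGQGTQVTVSS"                 # W103 ... Q108
_C8_FW4 = "GQGTLVTVSS"                   # no 103 ... L108

_A10_CDR1, _A10_CDR2, _A10_CDR3 = "GFTFSSY", "ISGSG", "DRAFSGYY"  # Y102
_C8_CDR1, _C8_CDR2, _C8_CDR3 = "GRTFSEY", "INSGG", "GRGSVAY"      # no 102

#: MutationSet converting the camelid FERF tetrad into the human VGLW.
TETRAD_TO_HUMAN = MutationSet(
    substitutions=(("37", "F", "V"), ("44", "E", "G"), ("45", "R", "L"), ("47", "F", "W"))
)
TETRAD_TO_CAMELID = TETRAD_TO_HUMAN.inverse()


def a10() -> VHHSequence:
    """Synthetic stand-in for the camelid-hallmark donor nanobody A10."""
    seq = _A10_FW1 + _A10_CDR1 + _A10_FW2 + _A10_CDR2 + _A10_FW3 + _A10_CDR3 + _A10_FW4
    return number_sequence(seq, seq_id="A10")


def c8wt() -> VHHSequence:
    """Synthetic stand-in for the human-hallmark scaffold nanobody C8WT."""
    seq = _C8_FW1 + _C8_CDR1 + _C8_FW2 + _C8_CDR2 + _C8_FW3 + _C8_CDR3 + _C8_FW4
    return number_sequence(seq, seq_id="C8WT")


def c8vi() -> VHHSequence:
    """Synthetic C8VI: camelid tetrad, near-A10 framework, C8 CDRs, Trp103."""
    seq = _C8VI_FW1 + _C8_CDR1 + _C8VI_FW2 + _C8_CDR2 + _C8VI_FW3 + _C8_CDR3 + _A10_FW4
    return number_sequence(seq, seq_id="C8VI")


def c8h() -> VHHSequence:
    """Synthetic C8H: the humanized mutant, i.e. C8VI with the VGLW tetrad."""
    mutant = apply_mutations(c8vi(), TETRAD_TO_HUMAN)
    return VHHSequence("C8H", mutant.residues, mutant.numbering, mutant.regions)


def a10c() -> VHHSequence:
    """A10C: A10 CDRs grafted onto the C8WT scaffold."""
    product, _ = graft_cdrs(
        a10(), c8wt(), seq_id="A10C", cdr_intervals=PANEL_CDR_INTERVALS
    )
    return product


def a10vi() -> VHHSequence:
    """A10VI: A10 CDRs grafted onto the C8VI scaffold."""
    product, _ = graft_cdrs(
        a10(), c8vi(), seq_id="A10VI", cdr_intervals=PANEL_CDR_INTERVALS
    )
    return product


def a10_hll() -> VHHSequence:
    """A10-HLL: A10C with camelid hallmarks and humanized fingerprints."""
    entries = build_variant_panel(
        a10(),
        c8wt(),
        hallmarks="camelid",
        fingerprints="human",
        cdr_intervals=PANEL_CDR_INTERVALS,
    )
    variant = entries[-1].sequence
    return VHHSequence("A10-HLL", variant.residues, variant.numbering, variant.regions)


def make_panel() -> dict[str, VHHSequence]:
    """All seven synthetic panel constructs, keyed by construct name."""
    return {
        "A10": a10(),
        "C8WT": c8wt(),
        "C8VI": c8vi(),
        "C8H": c8h(),
        "A10C": a10c(),
        "A10VI": a10vi(),
        "A10-HLL": a10_hll(),
    }


def panel_manifest() -> dict:
    """Manifest describing how each derived construct is built."""
    return {
        "cdr_intervals": {"CDR3": [95, 101]},
        "constructs": [
            {"name": "A10", "kind": "input"},
            {"name": "C8WT", "kind": "input"},
            {"name": "C8VI", "kind": "input"},
            {"name": "C8H", "kind": "mutant", "parent": "C8VI",
             "mutations": "hallmarks->human"},
            {"name": "A10C", "kind": "graft", "donor": "A10", "acceptor": "C8WT"},
            {"name": "A10VI", "kind": "graft", "donor": "A10", "acceptor": "C8VI"},
            {"name": "A10-HLL", "kind": "graft+variant", "donor": "A10",
             "acceptor": "C8WT", "hallmarks": "camelid", "fingerprints": "human"},
        ],
    }
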