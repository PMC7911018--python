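# Default VHH scheme-region boundaries (inclusive scheme positions).
# fill=left: residues are numbered from `start`; extra residues beyond `end`
#   receive insertion codes at `end` (endA, endB, ...); shorter regions omit
#   positions from `end` inward.
# fill=right: residues are numbered so the region always terminates at `end`;
#   shorter regions omit positions from `start` onward (e.g. the FW4-initial
#   Trp103 that some scaffolds lack).
region	start	end	fill
FW1	1	25	left
CDR1	26	32	left
FW2	33	51	left
CDR2	52	56	left
FW3	57	94	left
CDR3	95	102	left
FW4	103	113	right
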