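# Framework fingerprint reference: per scheme position, the residues regarded
# as typical of human VH ("human") and of llama VHH ("llama") germlines.
# Comma-separated alternatives; the FIRST entry is the prototype used when a
# position is mutated toward that species. Human and llama sets are disjoint
# at every position. The FW2 hallmark tetrad (37/44/45/47) is included:
# V/G/L/W are the human identities, F/E/R/F the camelid ones.
# SYNTHETIC reference table: curated to be consistent with the shipped
# synthetic humanization panel, not transcribed from any germline database.
position	human	llama
1	E	Q
5	V	Q
11	L	S
35	S,G	Y
37	V	F
42	G	F
44	G	E
45	L	R
47	W	F
50	A	S
78	L	V
89	V,T	L
91	Y	F
108	Q	L
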