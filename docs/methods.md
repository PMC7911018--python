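# Methods

This note records the models and procedures implemented in `nanograft`, the
parameter choices behind them, and what the shipped synthetic data can and
cannot establish.

## Numbering and regions

Sequences are segmented into FW1–CDR1–FW2–CDR2–FW3–CDR3–FW4 under a
simplified Kabat-style scheme whose boundaries are data
(`data/regions.tsv`): FW1 = 1–25, CDR1 = 26–32, FW2 = 33–51, CDR2 = 52–56,
FW3 = 57–94, CDR3 = 95–102, FW4 = 103–113. The CDR intervals are
deliberately Chothia-like so that the classical framework landmarks fall in
their conventional regions: the FW2 hallmark tetrad at 37/44/45/47, the
species fingerprint sites 35 and 50 inside FW2 (not in the CDRs, where
Kabat intervals would put them), 78/89/91 in FW3, CDR3 terminating at 102,
and FW4 opening with the conserved tryptophan at 103.

The default length plan fixes FW1–FW3 and CDR1–2 at their canonical widths
and lets CDR3 absorb length variation; FW4 is anchored at the C terminus
and is recognised as 11 residues when the FW4-initial Trp is present, 10
otherwise. This is a heuristic: a sequence whose eleventh-to-last residue
happens to be Trp for another reason would be mis-segmented, which is why
`number_sequence` accepts an explicit per-region length plan (the synthetic
generators and the grafting engine always pass one). Insertion codes
(102A, 102B, …) are assigned only inside CDR loops, at the loop's
C-terminal anchor; a framework longer than its canonical interval is a
numbering error, not an insertion. Shorter CDRs omit scheme positions from
their C-terminal end inward (a 7-residue CDR3 occupies 95–101, so position
102 is simply absent), and a 10-residue FW4 omits position 103. This
convention is what makes indel bookkeeping at the CDR3/FW4 junction — the
missing Tyr102 of short scaffolds, the FW4-initial Trp insertion —
deterministic under position-wise comparison.

X residues are accepted with a warning and never classify as fingerprints.

## Difference accounting and grafting

Two numbered sequences are compared **by scheme position only**: a
substitution is a position carried by both with different residues; a
position carried by one side only is an indel. No gap-optimising alignment
is ever run — the counts a protein engineer quotes for a mutant panel are
residue-anchored, and position-wise comparison reproduces them
deterministically and symmetrically (`diff(a,b)` and `diff(b,a)` have equal
substitution counts with insertions and deletions swapped). The mutation
set extracted from `diff(a, b)` applied to `b` reconstructs `a` exactly;
this round trip is property-tested.

Grafting copies the acceptor's residues at framework positions and the
donor's residues (verbatim, including insertion codes) at CDR positions,
then renumbers the product from scratch. The interval transferred for a CDR
is configurable per graft: the shipped humanization panel draws the CDR3
boundary at 101, treating position 102 as scaffold, so grafting onto a
scaffold lacking Tyr102 removes that residue from the product. Panel
options (`hallmarks=`, `fingerprints=`) compose hallmark-tetrad swaps and
fingerprint-site conversions on top of the graft, each with an auditable
mutation set; fingerprint conversions mutate a configurable site list
(default 35/50/89/91) to the reference prototype of the target species.

The fingerprint reference table (`data/fingerprints.tsv`) is itself
synthetic — curated to be internally consistent with the synthetic panel
rather than transcribed from a germline database — with human-type and
llama-type sets disjoint at every position and the first listed residue
acting as the mutation prototype.

### The synthetic humanization panel

The package does not redistribute any published construct sequences.
`synthetic_panel` builds seven stand-in constructs whose *relationships*
reproduce the documented bookkeeping of a classical grafting experiment:
donor framework vs scaffold framework = 14 substitutions (7 human-type + 7
llama-type on the donor side) plus the FW4 Trp insertion; graft onto the
camelized near-donor scaffold differs from the donor at exactly 4 positions
(11/35/78/89) plus the Tyr102 deletion; the hallmark/fingerprint-converted
graft differs from the plain graft by 8 and from the camelized-scaffold
graft by 4; the two humanized scaffold mutants interconvert by the tetrad
swap alone. One useful identity on this panel: the 12 substitutions between
the camelized-scaffold graft (A10VI) and the plain graft (A10C) decompose
exactly into the two legs through the hallmark/fingerprint variant
(A10-HLL), 4 + 8 with disjoint position sets. Passing these checks shows
the *accounting machinery* is exact; it says nothing about any real
antibody's sequence.

## Solvent accessibility

Per-atom SASA comes from biotite's numerical surface sampling (a
Shrake–Rupley-class algorithm) with probe radius 1.4 Å, 960 sphere points
and single per-element van der Waals radii, so pseudo-atom structures are
handled; residue SASA is the per-residue sum. Relative SASA divides by the
Tien et al. (2013) theoretical maxima, clipped to [0, 1.5]; unknown residue
types fall back to a generic 200 Å² maximum with a warning. A residue is
*exposed* at relative SASA ≥ 0.25 — a standard surface-residue threshold,
shared by every stage that needs an exposure rule.

Numerical caveat: the sampling lattice is fixed in the laboratory frame, so
SASA is exactly translation invariant but only approximately rotation
invariant (≈1–3 % at 960 points). The tests assert translation invariance
at 1e-9 and rotation invariance at 3 %; against a closed-form two-sphere
cap oracle the sampled areas agree to 2 %.

## Solubility surrogate and structural correction

The intrinsic per-residue score is a deliberately simple, fully documented
surrogate: `raw_i = −KD_i/4.5 − 0.5·agg_i + |q_i(pH)|`, where `KD` is
Kyte–Doolittle hydropathy, `agg` an aromatic/β-aggregation propensity table
(F/W = 1.0 down to C = 0.3), and `q` the Henderson–Hasselbalch net
side-chain charge at the working pH (default 7.0 — charge of either sign
promotes solubility, hence the absolute value). The raw profile is
smoothed with a centred 7-residue window (shrinking at the edges) and
z-scaled per sequence; negative values mark poorly soluble stretches.
The surrogate is labelled `surrogate-intrinsic` in every report and its
numbers are not comparable with any external predictor's scale; externally
computed per-residue profiles can be supplied (TSV keyed by residue id, or
`profile_from_scores`) and flow through the identical downstream machinery.
The analysis that matters — structural correction and hotspot construction
— is scorer-agnostic, which the rank-correlation test (Spearman ≥ 0.6
against a plain inverted-hydropathy window on random sequences) pins down
without over-fitting the surrogate's coefficients.

Structural correction: `S_i` is the exposure-weighted mean of `s_j` over
residues whose side-chain centroids lie within the patch radius (10 Å,
the conventional residue-interaction distance) of residue `i`, including
`i` itself. Weights are relative SASA with a floor of 0.1 for buried
residues, so buried neighbours still contribute, down-weighted ~an order of
magnitude. A uniform intrinsic profile is a fixed point of the correction
regardless of geometry; residues without usable coordinates keep their
intrinsic score, with a warning.

## Aggregation hotspots

Seeds are exposed residues with corrected score below −1 on the z scale
("poorest solubility"; a quantile rule can be substituted by passing a
different threshold). Members are exposed residues whose minimum side-chain
heavy-atom distance (CA for glycine) to any seed's side chain is at most
6 Å; a seed is always a member of its own hotspot. Seed neighbourhoods
sharing at least one member merge by single linkage, each hotspot is scored
`H = Σ S_i` over members — exactly, to machine precision — and hotspots are
reported worst (lowest `H`) first. Membership is monotone non-decreasing in
the distance cutoff, and on small structures it equals an exhaustive
all-pairs distance check (both are test invariants). The sum uses the
*corrected* scores by default (`use_corrected=False` switches to intrinsic)
— with per-residue scores already exposure-aware, summing corrected values
keeps buried-residue contributions from sneaking into a surface score. An
empty hotspot list is a valid result, not an error.

## Contact maps, difference projection, active residues

A contact map over an ensemble records for each residue pair the fraction
of conformations in which any heavy-atom pair lies within 4.5 Å, with the
trivial band |i−j| ≤ 2 excluded — the standard residue-contact convention;
both parameters are configuration. Wild-type and mutant maps built under
the same rule are compared as `d_i = Σ_j |Δ_ij|` (L1 row projection; L2
available), and the "most affected" residues are those with
`d_i > mean(d) + k·sd(d)`, `k = 1` by default. Identical maps give an
all-zero profile and an empty selection; a single flipped contact gives
`d_i = d_j = 1` by construction; the per-residue triangle bound
`d(A,C)_i ≤ d(A,B)_i + d(B,C)_i` holds for all inputs.

Active-residue nomination combines the exposed-hydrophobic set
(V/I/L/M/F/W/Y at relative SASA ≥ 0.25) with the most-affected set. The
shipped default is the **union**, filtered by a spatial-clustering rule —
a candidate must have at least one other candidate within 6 Å (minimum
heavy-atom distance) — with each surviving residue labelled by provenance
(`exposure` / `diff` / `both`); a strict-intersection mode is available.
The union-plus-clustering rule was an open design choice: it keeps
singleton noise out while retaining residues that only one of the two
complementary analyses flags, and the provenance labels preserve the
distinction for downstream docking setups.

## Ensemble clustering

Pairwise RMSD is computed on C-alpha atoms after optimal least-squares
superposition of each pair — closed-form Kabsch rotation via SVD, with the
determinant sign corrected so reflections are never applied (the RMSD is
evaluated from the trace identity, without building the rotation matrix).
The automatic cutoff is the mean of the off-diagonal upper-triangle RMSDs;
for a symmetric matrix the mean over unique pairs equals the mean over all
ordered pairs, so the distinction is moot. gromos clustering then
iterates: the conformation with the most neighbours within the cutoff
(ties broken by lowest frame index — the greedy rule itself is
tie-ambiguous and the convention must be fixed for determinism) forms a
cluster with its neighbours and is removed. Neighbourhoods use ≤, so a
frame exactly at the cutoff counts as a neighbour. Clusters are relabelled
by descending size; each cluster's representative is its extraction-time
centre, and the overall reference conformation is the representative of the
most populated cluster — deterministic given the frame order. Frame
subsampling is the caller's responsibility; the module clusters whatever
ensemble it is given.

## Synthetic data: what it emulates, and what passing tests show

The generators produce pseudo-atom structures: 4-atom backbone plates with
1–2 side-chain pseudo atoms, chains laid out on lines, arcs or helix-like
curves, shells of extra atoms to bury or shield residues, and rigid
segment displacements plus isotropic Gaussian jitter for ensembles. They
are deliberately non-physical — no bonded geometry, no energetics — because
every operator downstream depends only on distances, exposure and labels.
Each generator emits its ground truth (exposed sets, hotspot memberships,
rewired partners, basin labels), and identical seeds give byte-identical
outputs.

Default study conditions for the ensemble checks: 200 frames, three basins
at proportions 0.85/0.10/0.05, 8 Å basin displacement of a 10-residue
segment against 0.15 Å per-atom jitter, 30 residues — a separation regime
(between-basin distance ≫ within-basin spread) chosen to emulate a stable
single-domain trajectory in which a dominant conformational family holds
80–90 % of the frames next to a few minor families. Clustering at the
automatic cutoff recovers exactly three pure clusters with the top one at
85 %.

Passing on these fixtures establishes that the operators are exact with
respect to their definitions (counts, memberships, rankings, cluster
recovery). It does **not** establish that the defaults are optimal for
real proteins: real ensembles have anisotropic fluctuations and overlapping
basins, real surfaces are not linear chains, and a real humanization
campaign would feed the pipeline homology models and MD snapshots rather
than planted geometry.

## Degenerate inputs and tie-breaks

Empty mutation sets are identities; re-applying a mutation set fails its
precondition (stale source residues are reported, never silently
overwritten). A constant intrinsic profile z-scales to all zeros rather
than dividing by ~0. Clustering requires ≥ 2 frames; a non-positive cutoff
is rejected. Contact maps force the excluded band to zero even when atoms
of band pairs are within the cutoff. Hotspot detection with no qualifying
seed returns an empty list. All tie-breaks (gromos centres, insertion-code
letters, report orderings) resolve to the lowest index / earliest position.

## Known limitations

* The numbering heuristic fixes FW1–FW3 lengths; heavily non-canonical
  frameworks need an explicit length plan. No IMGT/Chothia/Martin server
  parity is attempted.
* The solubility surrogate is a transparent hydropathy/charge/β-propensity
  blend; its absolute numbers are meaningless outside this package.
* Trajectory input is multi-model PDB only; binary trajectory formats and
  any MD engine integration are out of scope, as are docking execution and
  scoring (the active-residue lists are the hand-off point).
* The O(N²) RMSD matrix is a Python loop over frame pairs — fine for a few
  hundred frames, not for tens of thousands.
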