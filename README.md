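# nanograft

Tools for the computational side of **nanobody (VHH) humanization by CDR
grafting**, and for predicting the stability and aggregation consequences of
the resulting chimeras.

Camelid heavy-chain-only antibodies carry single variable domains (VHHs)
that make excellent binders but are immunogenic in vivo. Humanizing them is
hard because the framework-2 **hallmark tetrad** — positions 37/44/45/47 in
conventional numbering, F-E-R-F in camelids versus V-G-L-W in human VH —
stabilises the domain, and swapping it often unfolds or aggregates the
protein. An alternative strategy transplants a nanobody's
complementarity-determining regions (CDR1–3) onto a scaffold that
*naturally* carries the human hallmarks, and asks, residue by residue and
conformation by conformation, what each intermediate mutant does to
stability. `nanograft` implements that workflow for computational antibody
engineers:

* **Numbering & annotation** — a simplified Kabat-style scheme with
  data-driven region boundaries (FW1–CDR1–…–FW4), hallmark-tetrad detection
  (camelid / human / hybrid), and classification of framework residues as
  human-type or llama-type *fingerprints* from a shipped reference table.
* **Grafting & panel design** — CDR grafting onto an acceptor scaffold,
  hallmark interconversion (FERF ↔ VGLW), fingerprint
  humanization/camelization, and exact numbering-aligned difference
  accounting (substitutions / insertions / deletions per scheme position —
  never a gap-optimising aligner).
* **Solubility & aggregation hotspots** — per-residue solubility scores
  (a documented surrogate scorer, or any externally computed profile),
  structural correction by exposure-weighted averaging over a 10 Å patch,
  and hotspot detection: exposed residues within 6 Å of the side chains of
  the poorest-solubility residues, merged by single linkage and scored as
  `H = Σ_i S_i` over members (lower = worse).
* **Contact-map differences** — ensemble contact maps `c_ij ∈ [0,1]`
  (heavy-atom cutoff 4.5 Å, |i−j| ≤ 2 excluded), per-residue projection
  `d_i = Σ_j |c_ij^wt − c_ij^mut|` of the wild-type/mutant difference
  matrix, and nomination of candidate aggregation-interface residues from
  exposed-hydrophobic and most-affected sets.
* **gromos clustering** — pairwise C-alpha least-squares-fit RMSD (closed
  form Kabsch), the average-RMSD automatic cutoff, greedy neighbour-count
  clustering, and representative-conformation selection.
* **Synthetic data** — generators for VHH-like sequences and pseudo-atom
  structures/ensembles with planted ground truth (hallmark states, mutation
  sets, exposure patterns, contact rewiring, shielding loops, cluster
  basins), so every stage is testable closed-loop.

The package ships a *synthetic* stand-in for a classical humanization panel
(donor `A10`, human-hallmark scaffold `C8WT`, and the derived constructs
`C8H`, `C8VI`, `A10C`, `A10VI`, `A10-HLL`) whose pairwise difference
structure reproduces the documented bookkeeping of that experiment; see
`nanograft.synthetic_panel`.

## Worked example

```python
from nanograft import detect_hallmarks, diff_sequences
from nanograft.synthetic_panel import make_panel

panel = make_panel()
print(detect_hallmarks(panel["A10"]).classification)   # camelid
print(detect_hallmarks(panel["C8WT"]).classification)  # human

fw = ("FW1", "FW2", "FW3", "FW4")
diff = diff_sequences(panel["A10"], panel["C8WT"], scope=fw)
print(diff.n_sub, diff.n_ins)            # 14 1
print(diff.fingerprint_counts("a"))      # {'human-type': 7, 'llama-type': 7}
print(diff.to_frame().head(4).to_string(index=False))
```

```
scheme_pos         kind from to region    class_a    class_b
         1 substitution    Q  E    FW1 human-type llama-type
         5 substitution    Q  V    FW1 human-type llama-type
        11 substitution    L  S    FW1 llama-type human-type
        35 substitution    Y  G    FW2 human-type llama-type
```

The donor framework differs from the scaffold at 14 positions (seven of the
donor's residues are human-type, seven llama-type) and additionally carries
the FW4-initial tryptophan (inserted at scheme position 103) that the
scaffold lacks. Grafting the donor CDRs onto the scaffold
(`graft_cdrs(panel["A10"], panel["C8WT"], cdr_intervals={"CDR3": (95, 101)})`)
yields `A10C`, which differs from the acceptor only inside the CDRs.

Clustering a planted three-basin ensemble recovers the basin structure at
the automatic cutoff:

```python
from nanograft import auto_cutoff, gromos_cluster, rmsd_matrix
from nanograft.synthetic import make_ensemble

ensemble, truth = make_ensemble(seed=1, n_frames=200,
                                basin_proportions=(0.85, 0.10, 0.05))
matrix = rmsd_matrix(ensemble)            # C-alpha pairwise RMSD (Å)
result = gromos_cluster(matrix, auto_cutoff(matrix))
print(round(auto_cutoff(matrix), 2))      # 1.30
print(result.sizes)                       # (170, 20, 10)
print(result.top_fraction())              # 0.85
```

Three clusters emerge, the most populated holding 85 % of the frames — the
regime typical of a stable single-domain simulation.

A command-line layer wraps the same operations
(`nanograft annotate|graft|hotspots|cluster|contactdiff`); every run writes
its fully resolved parameter set as JSON next to its outputs.

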