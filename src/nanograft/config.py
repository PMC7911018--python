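"""Pipeline configuration: every tunable threshold in one place.

Each CLI run writes its fully resolved configuration as JSON next to its
outputs, so a result can always be traced back to the exact parameter set
that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    patch_radius: float = 10.0        # Å, solubility structural correction
    hotspot_distance: float = 6.0     # Å, seed side chain -> member
    seed_threshold: float = -1.0      # z-scale corrected-score seed rule
    pH: float = 7.0                   # surrogate charge term
    contact_cutoff: float = 4.5       # Å, heavy-atom contact rule
    min_separation: int = 2           # |i-j| exclusion band for contacts
    exposure_threshold: float = 0.25  # relative SASA exposure rule
    probe_radius: float = 1.4         # Å, SASA probe
    sasa_points: int = 960            # SASA sphere points
    projection_norm: str = "l1"       # contact-diff projection
    projection_k: float = 1.0         # "most affected" = mean + k*sd
    cluster_atoms: str = "CA"         # RMSD atom selection
    nomination_mode: str = "union"    # active-residue combination rule
    seed: int = 0                     # RNG seed for synthetic inputs

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})
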