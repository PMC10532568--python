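"""Ground-truth manifest for simulated datasets."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class TruthManifest:
    """Everything planted by the simulators, with its truth.

    planted_degs: gene -> {stage_a, stage_b, log2fc}
    archetypes:   gene -> archetype index (1..6)
    planted_as:   list of {event_id, gene_id, as_type, region, psi{stage}}
    planted_edits: list of {contig, pos0, ref_plus, alt_plus, strand, ed_type,
                            level, stages}
    negative_controls: list of {contig, pos0, control_class, ...}
    phylostrata:  gene -> 1..12
    divergence:   gene -> stratum
    mapped_read_totals: sample -> int
    """

    planted_degs: dict = field(default_factory=dict)
    archetypes: dict = field(default_factory=dict)
    planted_as: list = field(default_factory=list)
    planted_edits: list = field(default_factory=list)
    negative_controls: list = field(default_factory=list)
    phylostrata: dict = field(default_factory=dict)
    divergence: dict = field(default_factory=dict)
    mapped_read_totals: dict = field(default_factory=dict)
    seed: int | None = None

    def merge(self, other: "TruthManifest") -> "TruthManifest":
        for key in ("planted_degs", "archetypes", "phylostrata", "divergence",
                    "mapped_read_totals"):
            getattr(self, key).update(getattr(other, key))
        for key in ("planted_as", "planted_edits", "negative_controls"):
            getattr(self, key).extend(getattr(other, key))
        return self

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
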