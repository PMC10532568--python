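"""Stage/replicate layout of the 9-stage developmental design.

The default design has nine stages with three biological replicates each,
grouped into five developmental processes (germination, oidiation,
sclerotia formation, fruiting, sporulation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from fdrm.errors import DesignError

DEFAULT_STAGES = ["BS", "BS12h", "BS24h", "Myc", "Oidia", "Scl", "Knot", "Pri", "YFB"]

DEFAULT_PROCESSES = {
    "germination": ["BS", "BS12h", "BS24h"],
    "oidiation": ["Myc", "Oidia"],
    "sclerotia": ["Myc", "Scl"],
    "fruiting": ["Myc", "Knot", "Pri"],
    "sporulation": ["Pri", "YFB", "BS"],
}

DEFAULT_REPLICATES = 3


@dataclass
class StageDesign:
    """Ordered stages, their replicate sample ids, and process groupings."""

    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    replicates: dict[str, list[str]] = field(default_factory=dict)
    processes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PROCESSES.items()}
    )

    def __post_init__(self) -> None:
        if not self.replicates:
            self.replicates = {
                s: [f"{s}_{i}" for i in range(1, DEFAULT_REPLICATES + 1)]
                for s in self.stages
            }
        missing = [s for s in self.stages if s not in self.replicates]
        if missing:
            raise DesignError(f"stages without replicates: {missing}")
        for proc, stages in self.processes.items():
            unknown = [s for s in stages if s not in self.stages]
            if unknown:
                raise DesignError(f"process {proc!r} references unknown stages {unknown}")

    @property
    def samples(self) -> list[str]:
        """All sample ids in stage order."""
        return [r for s in self.stages for r in self.replicates[s]]

    def stage_of(self, sample: str) -> str:
        for stage, reps in self.replicates.items():
            if sample in reps:
                return stage
        raise DesignError(f"unknown sample {sample!r}")

    def stage_pairs(self, process: str | None = None) -> list[tuple[str, str]]:
        """Ordered within-process stage pairs, or all pairwise stages."""
        if process is not None:
            if process not in self.processes:
                raise DesignError(f"unknown process {process!r}")
            stages = self.processes[process]
            return [
                (stages[i], stages[j])
                for i in range(len(stages))
                for j in range(i + 1, len(stages))
            ]
        return [
            (self.stages[i], self.stages[j])
            for i in range(len(self.stages))
            for j in range(i + 1, len(self.stages))
        ]

    def check_stage(self, stage: str) -> None:
        if stage not in self.stages:
            raise DesignError(f"unknown stage {stage!r}")
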