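"""Analysis configuration: the thresholds and conventions shared by all stages.

Every tunable constant of the pipeline lives here so that a run is fully
described by (input files, AnalysisConfig, seed).  All randomness in the
package flows from ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Pipeline-wide thresholds and options.

    Parameters
    ----------
    z_cutoff
        Latent-vector z-score at or above which a feature is called
        tissue-specific (DV-regulated).
    enhancer_top_fraction
        Fraction of regions (per assay, per condition) whose z-scores mark
        them as potential enhancers.
    accessibility_fc
        |log2 fold change| boundary separating gained/lost from stable
        chromatin accessibility.
    proximal_bp
        Enhancer-to-TSS distance (bp) at or below which an enhancer is
        classed proximal.
    min_gene_body_reads
        Genes with fewer total gene-body reads are dropped before any
        differential analysis.
    tss_exclusion_flank
        Half-width (bp) of the window around each TSS used to exclude
        promoter-overlapping regions from enhancer calling.
    n_bootstrap
        Bootstrap iterations for kinetic confidence intervals.
    ci_level
        Coverage level of the bootstrap percentile intervals.
    min_cells
        Minimum cells in a cluster for a kinetic fit to be attempted.
    pc_subsets
        Optional per-assay list of principal-component indices (0-based)
        used for the latent vectors; ``None`` selects automatically.
    seed
        Root seed for every stochastic step.
    """

    z_cutoff: float = 3.0
    enhancer_top_fraction: float = 0.05
    accessibility_fc: float = 0.5
    proximal_bp: int = 700
    min_gene_body_reads: int = 10
    tss_exclusion_flank: int = 150
    n_bootstrap: int = 100
    ci_level: float = 0.95
    min_cells: int = 30
    n_quad_nodes: int = 50
    mle_restarts: int = 2
    pc_subsets: dict[str, list[int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "z_cutoff": self.z_cutoff,
            "enhancer_top_fraction": self.enhancer_top_fraction,
            "accessibility_fc": self.accessibility_fc,
            "proximal_bp": self.proximal_bp,
            "tss_exclusion_flank": self.tss_exclusion_flank,
            "n_bootstrap": self.n_bootstrap,
            "min_cells": self.min_cells,
            "n_quad_nodes": self.n_quad_nodes,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        if self.min_gene_body_reads < 0:
            raise ValueError("min_gene_body_reads must be >= 0")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must lie in (0, 1), got {self.ci_level!r}")
        if not 0.0 < self.enhancer_top_fraction <= 1.0:
            raise ValueError("enhancer_top_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)
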