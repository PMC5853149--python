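"""Pipeline and simulation configuration.

Every tunable threshold in the pipeline lives in :class:`PipelineConfig`, so
all reported counts are explicitly config-relative. Defaults follow common
practice where the underlying study leaves a value open (promoter window,
association window); printed constants (10-kb TAD boundary window, 8-mer
k, alpha 1e-4, 73% top conservation group, 20-kb meta-locus flank) keep
their published values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    association_window: int = 50_000
    bidirectional_window: int = 1000
    min_exons: int = 2
    max_orf_codons: int = 100
    synteny_min_identity: float = 0.6
    synteny_window: int = 500
    domain_window: int = 100
    domain_step: int = 50
    domain_min_identity: float = 0.6
    high_conservation_fraction: float = 0.73
    medium_conservation_fraction: float = 0.30
    tad_boundary_window: int = 10_000
    kmer_k: int = 8
    kmer_alpha: float = 1e-4
    meta_flank: int = 20_000
    seed: int = 0

    def __post_init__(self):
        for name in ("promoter_upstream", "promoter_downstream",
                     "association_window", "bidirectional_window",
                     "synteny_window", "domain_window", "domain_step",
                     "tad_boundary_window", "meta_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("synteny_min_identity", "domain_min_identity",
                     "high_conservation_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.kmer_k < 1:
            raise ValueError("kmer_k must be >= 1")

    @property
    def promoter_match_distance(self) -> int:
        """Cross-species TSS-to-hit tolerance: half the promoter window."""
        return (self.promoter_upstream + self.promoter_downstream) // 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


#: Per-category planted pcRNA counts for the default two-genome fixture
#: (~40 pcRNAs across all seven orientation categories, BT predominant).
DEFAULT_PCRNA_COUNTS = {
    "BT": 10, "AS": 8, "DS-S": 5, "DS-AS": 5,
    "US-S": 4, "US-AS": 4, "OLAP": 4,
}

DEFAULT_CANCER_TYPES = (
    "BRCA", "LUAD", "LIHC", "SKCM", "COAD", "PRAD", "KIRC", "GBM",
)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic human-like/mouse-like pair."""

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_ortholog_genes: int = 46      # one per planted pcRNA + spares
    n_pcrnas: dict = field(default_factory=lambda: dict(DEFAULT_PCRNA_COUNTS))
    promoter_mutation_rate: float = 0.1
    n_decoys: int = 10
    n_loops: int = 8                # background loops beyond planted anchors
    anchor_width: int = 1000
    tad_count: int = 5              # per chromosome
    fraction_taprna: float = 0.5
    enhancer_fraction: float = 0.8  # of each planted distal anchor
    n_tissues: int = 12
    pair_rho: float = 0.25
    tissue_specificity_target: float = 0.0  # 0 = no sparsification
    planted_kmer: str = "GCGCATGC"
    site_mutation_rate_test: float = 0.3
    site_mutation_rate_background: float = 0.1
    cancer_types: tuple = DEFAULT_CANCER_TYPES
    seed: int = 0

    def __post_init__(self):
        for name in ("promoter_mutation_rate", "fraction_taprna",
                     "enhancer_fraction", "tissue_specificity_target",
                     "site_mutation_rate_test",
                     "site_mutation_rate_background"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_tissues < 3:
            raise ValueError("n_tissues must be >= 3")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "cancer_types" in data:
            data["cancer_types"] = tuple(data["cancer_types"])
        return cls(**data)
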