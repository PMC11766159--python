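"""Simulation configuration with validation and YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import ConfigError

# Flank half-width (bp) used by breakpoint-motif extraction; chromosome
# lengths must leave room for it around any placed locus.
FLANK_K = 10


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic eccDNA study.

    Defaults emulate a two-condition (infected vs uninfected) Circle-seq
    experiment on a small multi-chromosome genome: locus sizes are drawn
    log-uniformly over the observed 72 bp - 17 kb range so the 100-1000 bp
    size class dominates, junction read counts are negative-binomial, and a
    subset of loci carries an AT-rich motif written into both breakpoint
    flanks.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_lengths: list[int] = field(default_factory=lambda: [400_000, 300_000, 200_000])
    gc_content: float = 0.38  # silkworm-like AT-rich genome
    n_ecc_loci: int = 300
    ecc_size_min: int = 72
    ecc_size_max: int = 17_000
    genic_fraction_target: float = 0.5
    planted_motif: str = "ATATAT"
    planted_motif_fraction: float = 0.0
    n_replicates_per_condition: int = 3
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    count_dispersion: float = 0.1
    base_mean_reads: float = 50.0
    cond_specific_fraction: float = 0.0
    n_genes: int = 100
    exons_per_gene: int = 3
    gene_length: int = 3_000
    # ratio of highest to lowest per-chromosome gene density (genes/Mb);
    # 1.0 gives uniform density, >1 a linear gradient across chromosomes
    gene_density_span: float = 2.0
    circ_shared_fraction: float = 0.3
    n_circ_total: int = 100
    n_circ_extra: int = 0
    n_mirna_precursors: int = 40
    mirna_inside_fraction: float = 0.5
    mirna_length: int = 80
    expr_coupling_rho: float = 0.0
    expr_base_mean: float = 100.0
    expr_dispersion: float = 0.05

    _FRACTIONS = (
        "gc_content",
        "genic_fraction_target",
        "planted_motif_fraction",
        "de_fraction",
        "cond_specific_fraction",
        "circ_shared_fraction",
        "mirna_inside_fraction",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")
        if self.n_chromosomes != len(self.chrom_lengths):
            raise ConfigError(
                f"n_chromosomes={self.n_chromosomes} does not match "
                f"{len(self.chrom_lengths)} chrom_lengths"
            )
        if any(L <= 0 for L in self.chrom_lengths):
            raise ConfigError("chromosome lengths must be positive")
        if not (1 <= self.ecc_size_min < self.ecc_size_max):
            raise ConfigError("require 1 <= ecc_size_min < ecc_size_max")
        if min(self.chrom_lengths) <= self.ecc_size_max + 2 * FLANK_K:
            raise ConfigError(
                "every chromosome must exceed ecc_size_max plus motif flanks; "
                f"min length {min(self.chrom_lengths)} too short for "
                f"ecc_size_max {self.ecc_size_max}"
            )
        if self.count_dispersion < 0:
            raise ConfigError("count_dispersion must be >= 0")
        if self.n_replicates_per_condition < 1:
            raise ConfigError("need at least one replicate per condition")
        if not set(self.planted_motif.upper()) <= set("ACGT"):
            raise ConfigError("planted_motif must be an ACGT string")
        if len(self.planted_motif) > FLANK_K:
            raise ConfigError(
                f"planted_motif longer than the {FLANK_K} bp breakpoint flank"
            )
        if not -1.0 <= self.expr_coupling_rho <= 1.0:
            raise ConfigError("expr_coupling_rho must be in [-1, 1]")
        if self.gene_density_span < 1.0:
            raise ConfigError("gene_density_span must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError(f"{path}: config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
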