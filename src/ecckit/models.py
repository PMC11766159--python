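"""Core in-memory containers shared across the toolkit.

All genomic intervals use a single convention: 0-based, half-open
``[start, end)`` on the forward strand of a named chromosome. On-disk
GFF3 (1-based, closed) is converted at the I/O boundary. eccDNA circles
are strandless; their records carry strand ``"."``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class EccKitError(Exception):
    """Base class for toolkit errors."""


class ConfigError(EccKitError):
    """Invalid configuration value."""


class ParseError(EccKitError):
    """Malformed input file; message names the offending line."""


class Genome:
    """A small genome held fully in memory as upper-case strings.

    Suited to the multi-megabase synthetic genomes this toolkit analyses;
    sequences are fetched by plain slicing, so there is no index overhead.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs: dict[str, str] = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes:
                fh.write(f">{chrom}\n")
                seq = self.seqs[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.seqs.keys())

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return sequence of [start, end); raises KeyError on unknown chrom."""
        if start < 0 or end > len(self.seqs[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        return self.seqs[chrom][start:end]

    def gc_content(self) -> float:
        """Genome-wide GC fraction over all chromosomes."""
        gc = total = 0
        for seq in self.seqs.values():
            gc += seq.count("G") + seq.count("C")
            total += len(seq)
        return gc / total if total else float("nan")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def __len__(self) -> int:
        return len(self.seqs)


@dataclass(frozen=True)
class EccRecord:
    """One called eccDNA locus: junction coordinates plus call support.

    ``circle_score`` is the caller's confidence score; records at or below
    zero are filtered out on read. ``junction_reads`` counts reads spanning
    the head-to-tail junction and serves as the locus abundance.
    """

    chrom: str
    start: int
    end: int
    name: str
    circle_score: float
    junction_reads: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.circle_score <= 0:
            raise ValueError("circle_score must be > 0")
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene with exon structure, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span")
        prev_end = -1
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class CircJunction:
    """circRNA back-spliced junction interval with junction-level coverage."""

    circ_id: str
    chrom: str
    start: int
    end: int
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"circ {self.circ_id}: invalid interval")
        if self.coverage < 0:
            raise ValueError(f"circ {self.circ_id}: negative coverage")


@dataclass(frozen=True)
class MirnaPrecursor:
    """miRNA precursor (hairpin) genomic interval."""

    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"mirna {self.mirna_id}: invalid interval")


@dataclass
class ExpressionMatrix:
    """Raw counts (features x samples) plus an optional normalized view.

    ``normalization`` is "raw", "CPM" or "TPM". CPM columns sum to 1e6.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame | None = None
    normalization: str = "raw"
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("expression counts must be >= 0")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("expression counts must be integers")
        self.counts = counts.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class LocusCatalog:
    """Unified cross-sample eccDNA loci with a per-sample junction-read matrix.

    ``loci`` is a DataFrame indexed by locus_id with columns chrom/start/end;
    ``counts`` shares that index with one column per sample;
    ``conditions`` maps sample_id -> condition label.
    """

    loci: pd.DataFrame
    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.loci.index.equals(self.counts.index):
            raise ValueError("loci and counts must share an index")
        if (self.counts.values < 0).any():
            raise ValueError("catalog counts must be >= 0")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions.values():
            if c not in seen:
                seen.append(c)
        return seen
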