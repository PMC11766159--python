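"""Genome-wide characterization of an eccDNA call set.

Per-chromosome counts and densities, classification of loci by genomic
element (exonic / intronic / intergenic), the size distribution, and a
scaled GC metaprofile of each locus and its flanks against the genome
average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import EccRecord, GeneModel, Genome

logger = logging.getLogger(__name__)

DEFAULT_SIZE_EDGES = (0, 100, 1000, 10_000, 20_000)


def count_per_chromosome(records: Sequence[EccRecord]) -> pd.Series:
    """Number of eccDNA records per chromosome (sorted by chromosome name)."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.chrom] = counts.get(r.chrom, 0) + 1
    return pd.Series(counts, dtype=np.int64).sort_index()


def density_per_mb(
    records: Sequence[EccRecord], chrom_lengths: dict[str, int]
) -> pd.Series:
    """eccDNAs per megabase for every chromosome with a known length."""
    for r in records:
        if r.chrom not in chrom_lengths:
            raise KeyError(f"no length for chromosome {r.chrom!r}")
    counts = count_per_chromosome(records)
    out = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        out[chrom] = counts.get(chrom, 0) / (length / 1e6)
    return pd.Series(out).sort_index()


@dataclass
class ElementSummary:
    """Per-record element class plus the headline fractions."""

    classes: pd.Series  # record index -> exonic|intronic|intergenic
    fractions: dict[str, float]

    @property
    def genic_fraction(self) -> float:
        return self.fractions["exonic"] + self.fractions["intronic"]

    @property
    def intergenic_fraction(self) -> float:
        return self.fractions["intergenic"]


def _build_trees(
    genes: Sequence[GeneModel],
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    gene_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        for es, ee in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(es, ee)
    return gene_trees, exon_trees


def classify_elements(
    records: Sequence[EccRecord],
    genes: Sequence[GeneModel],
    min_overlap: int = 1,
) -> ElementSummary:
    """Classify each record as exonic, intronic or intergenic.

    A record overlapping any gene body by >= min_overlap bp is genic;
    genic records overlapping any exon by >= min_overlap bp are exonic,
    the rest intronic (exon takes priority over intron).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    gene_trees, exon_trees = _build_trees(genes)

    def overlap_bp(tree: IntervalTree | None, start: int, end: int) -> int:
        if tree is None:
            return 0
        return max(
            (min(iv.end, end) - max(iv.begin, start) for iv in tree.overlap(start, end)),
            default=0,
        )

    labels = []
    for r in records:
        if overlap_bp(gene_trees.get(r.chrom), r.start, r.end) >= min_overlap:
            if overlap_bp(exon_trees.get(r.chrom), r.start, r.end) >= min_overlap:
                labels.append("exonic")
            else:
                labels.append("intronic")
        else:
            labels.append("intergenic")
    classes = pd.Series(labels, dtype=object)
    n = max(len(records), 1)
    fractions = {
        k: (classes == k).sum() / n for k in ("exonic", "intronic", "intergenic")
    }
    return ElementSummary(classes=classes, fractions=fractions)


def size_histogram(
    records: Sequence[EccRecord],
    bin_edges: Sequence[int] = DEFAULT_SIZE_EDGES,
) -> pd.Series:
    """Histogram of locus lengths over half-open bins [e_i, e_{i+1}).

    Lengths at or beyond the final edge go to an "overflow" bin (logged).
    """
    edges = np.asarray(bin_edges)
    if len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin_edges must be increasing with >= 2 entries")
    lengths = np.array([r.length for r in records], dtype=np.int64)
    counts, _ = np.histogram(lengths, bins=edges)
    # np.histogram closes the last bin; count exact right-edge hits as overflow
    at_edge = int((lengths == edges[-1]).sum())
    counts[-1] -= at_edge
    overflow = int((lengths >= edges[-1]).sum())
    if overflow:
        logger.warning("%d record(s) beyond final size edge %d", overflow, edges[-1])
    labels = [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 1)]
    out = pd.Series(counts, index=labels, dtype=np.int64)
    out["overflow"] = overflow
    return out


@dataclass
class GcProfile:
    """Mean GC fraction per scaled bin across loci, plus the genome average.

    ``upstream``, ``body`` and ``downstream`` each hold n_bins values in
    [0, 1]; flanks have the same physical length as the locus they flank
    ("scaled" mode), so the profile is comparable across locus sizes.
    """

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    genome_average: float
    n_used: int
    n_skipped: int


def _gc_bins(seq: str, n_bins: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    edges = np.linspace(0, len(arr), n_bins + 1).round().astype(int)
    return np.array(
        [
            is_gc[edges[i] : edges[i + 1]].mean() if edges[i + 1] > edges[i] else np.nan
            for i in range(n_bins)
        ]
    )


def gc_profile(
    records: Sequence[EccRecord],
    genome: Genome,
    n_bins: int = 20,
) -> GcProfile:
    """Scaled GC metaprofile over upstream flank, locus body, downstream flank.

    Each region is rescaled to n_bins bins and averaged across loci. Records
    whose flank (one locus length) would run past a chromosome end are
    skipped and counted.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lengths = genome.lengths
    sums = {k: np.zeros(n_bins) for k in ("up", "body", "down")}
    n_used = n_skipped = 0
    for r in records:
        flank = r.length
        if r.start - flank < 0 or r.end + flank > lengths[r.chrom]:
            n_skipped += 1
            continue
        n_used += 1
        sums["up"] += _gc_bins(genome.fetch(r.chrom, r.start - flank, r.start), n_bins)
        sums["body"] += _gc_bins(genome.fetch(r.chrom, r.start, r.end), n_bins)
        sums["down"] += _gc_bins(genome.fetch(r.chrom, r.end, r.end + flank), n_bins)
    if n_skipped:
        logger.info("gc_profile: skipped %d record(s) near chromosome ends", n_skipped)
    denom = max(n_used, 1)
    return GcProfile(
        upstream=sums["up"] / denom,
        body=sums["body"] / denom,
        downstream=sums["down"] / denom,
        genome_average=genome.gc_content(),
        n_used=n_used,
        n_skipped=n_skipped,
    )


def window_counts(
    records: Sequence[EccRecord],
    chrom_lengths: dict[str, int],
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-window eccDNA counts (hotspot table): chrom, window_start, count."""
    rows = []
    per_chrom: dict[str, np.ndarray] = {
        c: np.zeros(int(np.ceil(L / window)), dtype=np.int64)
        for c, L in chrom_lengths.items()
    }
    for r in records:
        per_chrom[r.chrom][r.start // window] += 1
    for chrom in sorted(per_chrom):
        for i, c in enumerate(per_chrom[chrom]):
            rows.append((chrom, i * window, int(c)))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "count"])
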