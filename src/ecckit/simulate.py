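"""Synthetic eccDNA study generator with known ground truth.

Emulates a two-condition Circle-seq experiment end to end: an i.i.d.
random genome at a chosen GC content, non-overlapping gene models with
exon structure, replicate eccDNA call sets whose junction read counts
follow a negative binomial with planted condition fold changes, an
AT-rich motif written into breakpoint flanks of a chosen locus subset,
plus coupled gene expression, miRNA precursors and circRNA junctions
for the association rules. Every planted feature is recorded in a
:class:`TruthTable` so downstream results can be checked exactly.

Condition-specific loci are created by zeroing counts in the other
condition (the locus stays in the truth table), so presence/absence
logic is testable against truth. Motif planting overwrites the genome
sequence immediately 5' of both junction breakpoints, which makes the
enrichment effect size exactly controllable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import FLANK_K, SimConfig
from .models import (
    CircJunction,
    ConfigError,
    EccRecord,
    ExpressionMatrix,
    GeneModel,
    Genome,
    MirnaPrecursor,
)
from . import io as eio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CONDITION_A = "infected"
CONDITION_B = "uninfected"


@dataclass
class TruthTable:
    """Ground truth for every planted feature of one simulated dataset."""

    loci: pd.DataFrame  # locus_id, chrom, start, end, log2fc, motif_planted, specific_to
    circs: pd.DataFrame  # circ_id, shared_junction
    mirnas: pd.DataFrame  # mirna_id, inside_ecc
    expr_rho_target: float = 0.0
    expr_rho_latent: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loci": self.loci.to_dict(orient="records"),
            "circs": self.circs.to_dict(orient="records"),
            "mirnas": self.mirnas.to_dict(orient="records"),
            "expr_rho_target": self.expr_rho_target,
            "expr_rho_latent": self.expr_rho_latent,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            loci=pd.DataFrame(payload["loci"]),
            circs=pd.DataFrame(payload["circs"]),
            mirnas=pd.DataFrame(payload["mirnas"]),
            expr_rho_target=payload["expr_rho_target"],
            expr_rho_latent=payload["expr_rho_latent"],
        )


@dataclass
class SimDataset:
    """Everything one simulation run produces, in memory."""

    config: SimConfig
    genome: Genome
    genes: list[GeneModel]
    samples: dict[str, list[EccRecord]]
    conditions: dict[str, str]
    circs: list[CircJunction]
    mirnas: list[MirnaPrecursor]
    expr_genes: ExpressionMatrix
    expr_mirna: ExpressionMatrix
    truth: TruthTable


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: SimConfig, rng: np.random.Generator) -> Genome:
    """I.i.d. bases with P(G) + P(C) = gc_content, split equally."""
    g = config.gc_content
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    seqs = {}
    for i, length in enumerate(config.chrom_lengths, start=1):
        if length <= 0:
            raise ConfigError(f"chromosome length must be positive, got {length}")
        draw = rng.choice(_BASES, size=length, p=probs)
        seqs[f"chr{i}"] = draw.tobytes().decode("ascii")
    return Genome(seqs)


# ---------------------------------------------------------------------------
# gene models


def generate_gene_models(
    config: SimConfig, genome: Genome, rng: np.random.Generator
) -> list[GeneModel]:
    """Non-overlapping genes on both strands, each with exons_per_gene exons.

    Genes are apportioned to chromosomes by length times a linear density
    gradient (gene_density_span = highest/lowest genes-per-Mb ratio), so
    chromosomes differ in gene density the way real karyotypes do, then
    placed by the spacing construction (uniform non-overlapping starts).
    """
    lengths = genome.lengths
    chroms = genome.chromosomes
    factors = np.linspace(1.0, config.gene_density_span, len(chroms))
    weight = {c: lengths[c] * factors[i] for i, c in enumerate(chroms)}
    total = sum(weight.values())
    counts = {c: int(round(config.n_genes * weight[c] / total)) for c in chroms}
    # distribute rounding remainder to the largest chromosomes
    diff = config.n_genes - sum(counts.values())
    for c in sorted(chroms, key=lambda c: -lengths[c]):
        if diff == 0:
            break
        counts[c] += 1 if diff > 0 else -1
        diff += -1 if diff > 0 else 1

    genes: list[GeneModel] = []
    gid = 0
    for chrom in chroms:
        n, L, glen = counts[chrom], lengths[chrom], config.gene_length
        if n == 0:
            continue
        if n * glen > L:
            raise ConfigError(
                f"cannot place {n} genes of {glen} bp on {chrom} ({L} bp)"
            )
        # uniform non-overlapping placement: sort gaps then stack
        slack = L - n * glen
        gaps = np.sort(rng.integers(0, slack + 1, size=n))
        starts = gaps + np.arange(n) * glen
        for s in starts:
            gid += 1
            genes.append(
                _make_gene(f"gene{gid:05d}", chrom, int(s), glen,
                           "+" if rng.random() < 0.5 else "-",
                           config.exons_per_gene, rng)
            )
    return genes


def _make_gene(
    gene_id: str, chrom: str, start: int, length: int, strand: str,
    n_exons: int, rng: np.random.Generator,
) -> GeneModel:
    # split the gene body into n_exons equal blocks; the exon fills a random
    # 40-80% prefix of each block, leaving introns between them
    block = length // n_exons
    exons = []
    for i in range(n_exons):
        bs = start + i * block
        elen = max(1, int(block * rng.uniform(0.4, 0.8)))
        exons.append((bs, min(bs + elen, start + length)))
    exons[-1] = (exons[-1][0], start + length)  # last exon reaches gene end
    return GeneModel(gene_id, chrom, strand, start, start + length, tuple(exons))


# ---------------------------------------------------------------------------
# eccDNA call sets


def _overlaps_any(chrom: str, start: int, end: int, genes: Sequence[GeneModel]) -> bool:
    return any(g.chrom == chrom and start < g.end and g.start < end for g in genes)


def _draw_length(config: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = np.log(config.ecc_size_min), np.log(config.ecc_size_max)
    return int(np.clip(round(np.exp(rng.uniform(lo, hi))),
                       config.ecc_size_min, config.ecc_size_max))


def generate_ecc_dataset(
    config: SimConfig,
    genome: Genome,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[dict[str, list[EccRecord]], dict[str, str], TruthTable]:
    """Place loci, plant motifs into the genome, simulate junction reads.

    Mutates ``genome`` in place when planting motifs. Returns per-sample
    record lists, the sample -> condition map, and a truth table whose
    circ/mirna frames are filled in later by
    :func:`generate_associated_features`.
    """
    n = config.n_ecc_loci
    lengths = genome.lengths
    chroms = genome.chromosomes
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    n_genic = int(round(n * config.genic_fraction_target))
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for i in range(n):
        length = _draw_length(config, rng)
        genic = i < n_genic
        chrom, start = _place_locus(
            length, genic, chroms, weights, lengths, genes, genes_by_chrom, rng
        )
        rows.append((f"ecc{i + 1:05d}", chrom, start, start + length))
    loci = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])
    # shuffle so planted flags below are independent of genic placement order
    loci = loci.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )

    # motif planting: overwrite the sequence immediately 5' of each breakpoint
    n_mot = int(round(n * config.planted_motif_fraction))
    motif = config.planted_motif.upper()
    planted = np.zeros(n, dtype=bool)
    planted[:n_mot] = True
    if n_mot:
        _plant_motifs(genome, loci.iloc[:n_mot], motif)

    # differential and condition-specific flags
    n_de = int(round(n * config.de_fraction))
    log2fc = np.zeros(n)
    log2fc[:n_de // 2] = config.de_log2fc
    log2fc[n_de // 2 : n_de] = -config.de_log2fc
    n_cs = int(round(n * config.cond_specific_fraction))
    specific = np.array([""] * n, dtype=object)
    cs_idx = np.arange(n_de, min(n_de + n_cs, n))
    half = len(cs_idx) // 2
    specific[cs_idx[:half]] = CONDITION_A
    specific[cs_idx[half:]] = CONDITION_B

    loci["log2fc"] = log2fc
    loci["motif_planted"] = planted
    loci["specific_to"] = specific

    samples, conditions = _simulate_counts(config, loci, rng)
    truth = TruthTable(
        loci=loci.copy(), circs=pd.DataFrame(), mirnas=pd.DataFrame()
    )
    return samples, conditions, truth


def _place_locus(
    length: int,
    genic: bool,
    chroms: list[str],
    weights: np.ndarray,
    lengths: dict[str, int],
    genes: Sequence[GeneModel],
    genes_by_chrom: dict[str, list[GeneModel]],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> tuple[str, int]:
    margin = FLANK_K  # keep breakpoint flanks extractable
    if genic:
        if not genes:
            raise ConfigError("genic placement requested but no genes exist")
        for _ in range(max_tries):
            g = genes[int(rng.integers(len(genes)))]
            lo = max(margin, g.start - length + 1)
            hi = min(lengths[g.chrom] - length - margin, g.end - 1)
            if lo > hi:
                continue
            return g.chrom, int(rng.integers(lo, hi + 1))
        raise ConfigError(
            f"could not place a {length} bp locus overlapping any gene "
            f"after {max_tries} tries"
        )
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        hi = lengths[chrom] - length - margin
        if hi <= margin:
            continue
        start = int(rng.integers(margin, hi + 1))
        if not _overlaps_any(chrom, start, start + length, genes_by_chrom.get(chrom, [])):
            return chrom, start
    raise ConfigError(
        f"could not place a {length} bp locus outside genes after {max_tries} tries"
    )


def _plant_motifs(genome: Genome, loci: pd.DataFrame, motif: str) -> None:
    m = len(motif)
    buffers = {c: bytearray(s, "ascii") for c, s in genome.seqs.items()}
    mbytes = motif.encode("ascii")
    for row in loci.itertuples():
        buffers[row.chrom][row.start - m : row.start] = mbytes
        buffers[row.chrom][row.end - m : row.end] = mbytes
    genome.seqs = {c: b.decode("ascii") for c, b in buffers.items()}


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _simulate_counts(
    config: SimConfig, loci: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, list[EccRecord]], dict[str, str]]:
    n = len(loci)
    nrep = config.n_replicates_per_condition
    sample_ids = [f"{CONDITION_A}_{r + 1}" for r in range(nrep)] + [
        f"{CONDITION_B}_{r + 1}" for r in range(nrep)
    ]
    conditions = {
        s: CONDITION_A if s.startswith(CONDITION_A) else CONDITION_B
        for s in sample_ids
    }
    lfc = loci["log2fc"].values
    mu = config.base_mean_reads
    mean_a = mu * 2.0 ** (lfc / 2)
    mean_b = mu * 2.0 ** (-lfc / 2)
    counts = np.empty((n, 2 * nrep), dtype=np.int64)
    for r in range(nrep):
        counts[:, r] = _nb_draw(rng, mean_a, config.count_dispersion)
        counts[:, nrep + r] = _nb_draw(rng, mean_b, config.count_dispersion)

    specific = loci["specific_to"].values
    counts[specific == CONDITION_A, nrep:] = 0
    counts[specific == CONDITION_B, :nrep] = 0
    # detection guarantee: every locus must appear in its intended condition(s)
    for cond, cols in ((CONDITION_A, slice(0, nrep)), (CONDITION_B, slice(nrep, 2 * nrep))):
        want = specific != (CONDITION_B if cond == CONDITION_A else CONDITION_A)
        dead = want & (counts[:, cols].sum(axis=1) == 0)
        counts[dead, cols.start] = 1

    scores = rng.uniform(0.5, 50.0, size=n)
    samples: dict[str, list[EccRecord]] = {s: [] for s in sample_ids}
    for j, sid in enumerate(sample_ids):
        for i, row in enumerate(loci.itertuples()):
            if counts[i, j] > 0:
                samples[sid].append(
                    EccRecord(
                        row.chrom, row.start, row.end, row.locus_id,
                        round(float(scores[i]), 3), int(counts[i, j]),
                        sample_id=sid,
                    )
                )
    return samples, conditions


def simulate_count_matrix(
    n_features: int,
    n_replicates: int,
    de_fraction: float,
    de_log2fc: float,
    dispersion: float,
    base_mean: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, str]]:
    """Stand-alone two-condition NB count matrix with planted fold changes.

    The count model is the same one the full generator uses for junction
    reads (condition means split symmetrically around base_mean by
    de_log2fc/2); useful for testing differential calling without
    placing loci on a genome. Returns (counts, true_log2fc, conditions).
    """
    n_de = int(round(n_features * de_fraction))
    lfc = np.zeros(n_features)
    lfc[: n_de // 2] = de_log2fc
    lfc[n_de // 2 : n_de] = -de_log2fc
    mean_a = base_mean * 2.0 ** (lfc / 2)
    mean_b = base_mean * 2.0 ** (-lfc / 2)
    cols = {}
    conditions = {}
    for r in range(n_replicates):
        sid = f"{CONDITION_A}_{r + 1}"
        cols[sid] = _nb_draw(rng, mean_a, dispersion)
        conditions[sid] = CONDITION_A
    for r in range(n_replicates):
        sid = f"{CONDITION_B}_{r + 1}"
        cols[sid] = _nb_draw(rng, mean_b, dispersion)
        conditions[sid] = CONDITION_B
    counts = pd.DataFrame(
        cols, index=[f"f{i + 1:05d}" for i in range(n_features)]
    )
    return counts, lfc, conditions


# ---------------------------------------------------------------------------
# associated features


def generate_associated_features(
    config: SimConfig,
    genome: Genome,
    truth: TruthTable,
    genes: list[GeneModel],
    conditions: dict[str, str],
    rng: np.random.Generator,
) -> tuple[list[CircJunction], list[MirnaPrecursor], ExpressionMatrix, ExpressionMatrix]:
    """circRNA junctions, miRNA precursors, and coupled expression tables."""
    circs = _make_circs(config, genome, truth, rng)
    mirnas = _make_mirnas(config, genome, truth, rng)
    expr_genes = _make_gene_expression(config, truth, genes, conditions, rng)
    expr_mirna = _make_mirna_expression(config, mirnas, conditions, rng)
    return circs, mirnas, expr_genes, expr_mirna


def _make_circs(
    config: SimConfig, genome: Genome, truth: TruthTable, rng: np.random.Generator
) -> list[CircJunction]:
    n_total = config.n_circ_total
    n_shared = int(round(config.circ_shared_fraction * n_total))
    loci = truth.loci
    if n_shared > len(loci):
        raise ConfigError(
            f"circ_shared_fraction requests {n_shared} shared junctions but "
            f"only {len(loci)} eccDNA loci exist"
        )
    ecc_keys = set(zip(loci["chrom"], loci["start"], loci["end"]))
    pick = rng.choice(len(loci), size=n_shared, replace=False)
    circs: list[CircJunction] = []
    flags = []
    for k, i in enumerate(sorted(pick)):
        row = loci.iloc[i]
        circs.append(
            CircJunction(
                f"circ{k + 1:05d}", row["chrom"], int(row["start"]), int(row["end"]),
                coverage=round(float(rng.uniform(1, 20)), 3),
            )
        )
        flags.append(True)
    n_other = n_total - n_shared + config.n_circ_extra
    lengths = genome.lengths
    chroms = genome.chromosomes
    cid = n_shared
    while cid < n_shared + n_other:
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(200, 2000))
        if lengths[chrom] <= length + 1:
            continue
        start = int(rng.integers(0, lengths[chrom] - length))
        if (chrom, start, start + length) in ecc_keys:
            continue  # must not coincide with an eccDNA junction
        cid += 1
        cov = 0.0 if rng.random() < 0.2 else round(float(rng.uniform(1, 20)), 3)
        circs.append(CircJunction(f"circ{cid:05d}", chrom, start, start + length, cov))
        flags.append(False)
    truth.circs = pd.DataFrame(
        {"circ_id": [c.circ_id for c in circs], "shared_junction": flags}
    )
    return circs


def _make_mirnas(
    config: SimConfig, genome: Genome, truth: TruthTable, rng: np.random.Generator
) -> list[MirnaPrecursor]:
    n = config.n_mirna_precursors
    n_inside = int(round(config.mirna_inside_fraction * n))
    mlen = config.mirna_length
    loci = truth.loci
    big = loci[loci["end"] - loci["start"] > mlen]
    if n_inside > 0 and big.empty:
        raise ConfigError(
            f"mirna_length {mlen} exceeds every eccDNA locus; cannot place inside"
        )
    mirnas: list[MirnaPrecursor] = []
    flags = []
    for k in range(n_inside):
        row = big.iloc[int(rng.integers(len(big)))]
        start = int(rng.integers(row["start"], row["end"] - mlen + 1))
        mirnas.append(
            MirnaPrecursor(
                f"mir{k + 1:04d}", row["chrom"],
                "+" if rng.random() < 0.5 else "-", start, start + mlen,
            )
        )
        flags.append(True)
    intervals = [
        (r["chrom"], int(r["start"]), int(r["end"])) for _, r in loci.iterrows()
    ]
    lengths = genome.lengths
    chroms = genome.chromosomes
    k = n_inside
    while k < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, lengths[chrom] - mlen))
        contained = any(
            c == chrom and s <= start and start + mlen <= e for c, s, e in intervals
        )
        if contained:
            continue
        k += 1
        mirnas.append(
            MirnaPrecursor(
                f"mir{k:04d}", chrom, "+" if rng.random() < 0.5 else "-",
                start, start + mlen,
            )
        )
        flags.append(False)
    truth.mirnas = pd.DataFrame(
        {"mirna_id": [m.mirna_id for m in mirnas], "inside_ecc": flags}
    )
    return mirnas


def _per_gene_ecc_counts(loci: pd.DataFrame, genes: Sequence[GeneModel]) -> np.ndarray:
    counts = np.zeros(len(genes), dtype=np.int64)
    for gi, g in enumerate(genes):
        sub = loci[loci["chrom"] == g.chrom]
        counts[gi] = int(
            ((sub["start"] < g.end) & (sub["end"] > g.start)).sum()
        )
    return counts


def _make_gene_expression(
    config: SimConfig,
    truth: TruthTable,
    genes: Sequence[GeneModel],
    conditions: dict[str, str],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Gaussian-copula coupling of mean expression to per-gene eccDNA count.

    The coupling strength on the latent scale is solved by bisection so the
    realized Spearman correlation between eccDNA counts and mean expression
    hits expr_coupling_rho despite ties among the (often zero) counts. If
    ties make the target unreachable the maximum attainable value is used.
    """
    ecc_counts = _per_gene_ecc_counts(truth.loci, genes)
    n = len(genes)
    eps = rng.standard_normal(n)
    midranks = stats.rankdata(ecc_counts, method="average")
    scores = stats.norm.ppf((midranks - 0.375) / (n + 0.25))
    sd = scores.std()
    scores = scores / sd if sd > 0 else np.zeros(n)

    target = config.expr_coupling_rho

    def realized(lam: float) -> float:
        latent = lam * scores + np.sqrt(max(0.0, 1 - lam * lam)) * eps
        return stats.spearmanr(ecc_counts, latent).statistic if n >= 3 else 0.0

    if target == 0 or sd == 0:
        lam = 0.0
    else:
        sign = np.sign(target)
        lo, hi = 0.0, 1.0
        if abs(realized(sign * 1.0)) < abs(target):
            lam = sign * 1.0  # target unreachable under these ties; use max
        else:
            for _ in range(40):
                mid = (lo + hi) / 2
                if abs(realized(sign * mid)) < abs(target):
                    lo = mid
                else:
                    hi = mid
            lam = sign * hi
    latent = lam * scores + np.sqrt(max(0.0, 1 - lam * lam)) * eps
    truth.expr_rho_target = float(target)
    truth.expr_rho_latent = float(realized(lam)) if lam != 0 else 0.0

    mu = config.expr_base_mean * np.exp(0.8 * latent)
    sample_ids = list(conditions)
    counts = np.column_stack(
        [_nb_draw(rng, mu, config.expr_dispersion) for _ in sample_ids]
    )
    df = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=sample_ids)
    return ExpressionMatrix(counts=df)


def _make_mirna_expression(
    config: SimConfig,
    mirnas: Sequence[MirnaPrecursor],
    conditions: dict[str, str],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    mu = config.expr_base_mean * np.exp(0.6 * rng.standard_normal(len(mirnas)))
    sample_ids = list(conditions)
    counts = np.column_stack(
        [_nb_draw(rng, mu, config.expr_dispersion) for _ in sample_ids]
    )
    df = pd.DataFrame(counts, index=[m.mirna_id for m in mirnas], columns=sample_ids)
    return ExpressionMatrix(counts=df)


# ---------------------------------------------------------------------------
# top level


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator; deterministic given config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    genes = generate_gene_models(config, genome, rng)
    samples, conditions, truth = generate_ecc_dataset(config, genome, genes, rng)
    circs, mirnas, expr_genes, expr_mirna = generate_associated_features(
        config, genome, truth, genes, conditions, rng
    )
    return SimDataset(
        config=config, genome=genome, genes=genes, samples=samples,
        conditions=conditions, circs=circs, mirnas=mirnas,
        expr_genes=expr_genes, expr_mirna=expr_mirna, truth=truth,
    )


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every emitted file; byte-identical across reruns of one config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ds.genome.to_fasta(outdir / "genome.fasta")
    paths["genome"] = outdir / "genome.fasta"
    eio.write_gff3_genes(ds.genes, outdir / "genes.gff3")
    paths["genes"] = outdir / "genes.gff3"
    for sid in sorted(ds.samples):
        p = outdir / f"ecc_{sid}.bed"
        eio.write_ecc_table(ds.samples[sid], p)
        paths[f"ecc_{sid}"] = p
    eio.write_circ_junctions(ds.circs, outdir / "circ.bed")
    paths["circ"] = outdir / "circ.bed"
    eio.write_mirna_precursors(ds.mirnas, outdir / "mirna.bed")
    paths["mirna"] = outdir / "mirna.bed"
    eio.write_expression(ds.expr_genes, outdir / "expr_genes.tsv")
    paths["expr_genes"] = outdir / "expr_genes.tsv"
    eio.write_expression(ds.expr_mirna, outdir / "expr_mirna.tsv")
    paths["expr_mirna"] = outdir / "expr_mirna.tsv"
    ds.truth.to_json(outdir / "truth.json")
    paths["truth"] = outdir / "truth.json"
    with open(outdir / "conditions.tsv", "w") as fh:
        fh.write("sample_id\tcondition\n")
        for sid in sorted(ds.conditions):
            fh.write(f"{sid}\t{ds.conditions[sid]}\n")
    paths["conditions"] = outdir / "conditions.tsv"
    ds.config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
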