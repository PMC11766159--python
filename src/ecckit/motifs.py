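"""Breakpoint-flank motif analysis against a randomized-reposition null.

For each eccDNA the 10 bp on either side of the 5' breakpoint (the
locus start) and of the 3' breakpoint (the locus end) are extracted as
two 2k-mers. Position frequency matrices over these windows are
compared with a null built by repeatedly re-placing every locus at a
uniformly random position in the genome (length preserved), which is
the expected composition if circle formation were position-independent.
Circles are treated as strandless: no reverse-complementing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import EccRecord, Genome

ALPHABET = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FlankSet:
    """2k-mer windows centred on each breakpoint, one pair per usable record."""

    five: list[str]
    three: list[str]
    k: int
    n_skipped: int  # records with a breakpoint < k from a chromosome end


@dataclass
class MotifProfile:
    """Observed position frequencies for one breakpoint side plus its null.

    ``freq`` rows (positions) sum to 1 over A,C,G,T; ``z`` is the
    elementwise standardized deviation from the randomized-null mean.
    """

    side: str  # "5prime" | "3prime"
    freq: np.ndarray  # (2k, 4)
    counts: np.ndarray  # (2k, 4) integer tallies
    n_sequences: int
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    z: np.ndarray | None = None
    at_excess: np.ndarray | None = None  # per-position (A+T) obs - null


def extract_flanks(
    records: Sequence[EccRecord], genome: Genome, k: int = 10
) -> FlankSet:
    """Extract genome[start-k : start+k] and genome[end-k : end+k] per record.

    Records whose window would cross a chromosome end are skipped and
    counted; sequences are upper-case by construction of :class:`Genome`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lengths = genome.lengths
    five, three = [], []
    n_skipped = 0
    for r in records:
        L = lengths[r.chrom]
        if r.start - k < 0 or r.start + k > L or r.end - k < 0 or r.end + k > L:
            n_skipped += 1
            continue
        five.append(genome.fetch(r.chrom, r.start - k, r.start + k))
        three.append(genome.fetch(r.chrom, r.end - k, r.end + k))
    return FlankSet(five=five, three=three, k=k, n_skipped=n_skipped)


def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def position_frequency_matrix(flanks: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Tally base frequencies per position; returns (freq, counts).

    All flanks must share one length; characters outside ACGT (e.g. N)
    are excluded from that position's denominator.
    """
    if not flanks:
        raise ValueError("cannot build a PFM from zero sequences")
    if len({len(s) for s in flanks}) != 1:
        raise ValueError("all flank sequences must have the same length")
    mat = _encode(flanks)
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASE_CODES], axis=1)
    denom = counts.sum(axis=1, keepdims=True)
    if (denom == 0).any():
        raise ValueError("a position has no ACGT characters")
    return counts / denom, counts


def randomized_null(
    records: Sequence[EccRecord],
    genome: Genome,
    k: int = 10,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Null PFM mean/sd from uniform random re-placement of each locus.

    Each permutation assigns every record a new start uniform over all
    placeable positions genome-wide (chromosome chosen with probability
    proportional to length - locus_length + 1), then recomputes both
    PFMs. Returns five_mean/five_sd/three_mean/three_sd.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chroms = genome.chromosomes
    chrom_len = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    ecc_len = np.array([r.length for r in records], dtype=np.int64)
    placeable = np.maximum(chrom_len[None, :] - ecc_len[:, None] + 1, 0)  # n x m
    if (placeable.sum(axis=1) == 0).any():
        bad = ecc_len[placeable.sum(axis=1) == 0].max()
        raise ValueError(f"no chromosome can hold a {bad} bp locus")
    cum = np.cumsum(placeable, axis=1)
    totals = cum[:, -1]

    fives = np.empty((n_perm, 2 * k, 4))
    threes = np.empty((n_perm, 2 * k, 4))
    for p in range(n_perm):
        u = rng.random(len(records)) * totals
        chrom_idx = (cum.T < u).sum(axis=0)
        starts = np.empty(len(records), dtype=np.int64)
        for i, ci in enumerate(chrom_idx):
            starts[i] = rng.integers(0, chrom_len[ci] - ecc_len[i] + 1)
        placed = []
        for i, r in enumerate(records):
            placed.append(
                EccRecord(
                    chroms[chrom_idx[i]], int(starts[i]),
                    int(starts[i] + ecc_len[i]), r.name, r.circle_score,
                    r.junction_reads, r.sample_id,
                )
            )
        fl = extract_flanks(placed, genome, k)
        fives[p] = position_frequency_matrix(fl.five)[0]
        threes[p] = position_frequency_matrix(fl.three)[0]
    return {
        "five_mean": fives.mean(axis=0),
        "five_sd": fives.std(axis=0, ddof=1),
        "three_mean": threes.mean(axis=0),
        "three_sd": threes.std(axis=0, ddof=1),
    }


def motif_enrichment(
    freq: np.ndarray,
    null_mean: np.ndarray,
    null_sd: np.ndarray,
    n_sequences: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise z = (obs - null_mean)/sd and per-position AT excess.

    The null sd is floored at 1/(2 n_sequences) so cells the null never
    varies in cannot blow up the statistic.
    """
    if freq.shape != null_mean.shape or freq.shape != null_sd.shape:
        raise ValueError("observed and null matrices must share a shape")
    floor = 1.0 / (2 * n_sequences)
    z = (freq - null_mean) / np.maximum(null_sd, floor)
    a, t = ALPHABET.index("A"), ALPHABET.index("T")
    at_excess = (freq[:, a] + freq[:, t]) - (null_mean[:, a] + null_mean[:, t])
    return z, at_excess


def analyze_breakpoint_motifs(
    records: Sequence[EccRecord],
    genome: Genome,
    k: int = 10,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[MotifProfile, MotifProfile]:
    """Full analysis: flanks, observed PFMs, randomized null, z matrices."""
    fl = extract_flanks(records, genome, k)
    if not fl.five:
        raise ValueError("no record left a usable flank window")
    null = randomized_null(records, genome, k=k, n_perm=n_perm, seed=seed)
    profiles = []
    for side, seqs, mean, sd in (
        ("5prime", fl.five, null["five_mean"], null["five_sd"]),
        ("3prime", fl.three, null["three_mean"], null["three_sd"]),
    ):
        freq, counts = position_frequency_matrix(seqs)
        z, at_excess = motif_enrichment(freq, mean, sd, len(seqs))
        profiles.append(
            MotifProfile(
                side=side, freq=freq, counts=counts, n_sequences=len(seqs),
                null_mean=mean, null_sd=sd, z=z, at_excess=at_excess,
            )
        )
    return profiles[0], profiles[1]


def profile_to_frame(profile: MotifProfile):
    """Long-format table (position, base, freq, null_mean, null_sd, z)."""
    import pandas as pd

    rows = []
    for pos in range(profile.freq.shape[0]):
        for bi, base in enumerate(ALPHABET):
            rows.append(
                {
                    "side": profile.side,
                    "position": pos - profile.freq.shape[0] // 2,
                    "base": base,
                    "freq": profile.freq[pos, bi],
                    "count": int(profile.counts[pos, bi]),
                    "null_mean": None if profile.null_mean is None else profile.null_mean[pos, bi],
                    "null_sd": None if profile.null_sd is None else profile.null_sd[pos, bi],
                    "z": None if profile.z is None else profile.z[pos, bi],
                }
            )
    return pd.DataFrame(rows)
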