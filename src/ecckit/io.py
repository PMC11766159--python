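"""Readers and writers for every on-disk format the pipeline touches.

One coordinate convention everywhere: internal intervals are 0-based
half-open. GFF3 is 1-based closed on disk and converted here at the
boundary. Writers emit records sorted by (chrom, start, end) and say so
in a header comment; gzip is handled transparently by file extension.

eccDNA call tables are a BED6+1 dialect: chrom, start, end, name,
circle_score, strand ("."), junction_reads. Records with circle score
<= 0 are dropped on read (the call-set confidence filter), with the
drop count logged.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from .models import (
    CircJunction,
    EccRecord,
    ExpressionMatrix,
    GeneModel,
    MirnaPrecursor,
    ParseError,
)

logger = logging.getLogger(__name__)

_SORT_NOTE = "# sorted by (chrom, start, end)\n"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _data_lines(path: str | Path):
    """Yield (line_number, stripped_line) skipping comments and blanks."""
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# eccDNA call tables


def read_ecc_table(
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    sample_id: str | None = None,
) -> list[EccRecord]:
    """Parse an eccDNA call table, validating against chromosome lengths.

    Records with circle_score <= 0 are dropped (not an error); structural
    problems (start >= end, unknown chromosome, negative read count) raise
    :class:`ParseError` naming the line.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".bed")
        sample_id = sample_id.removeprefix("ecc_")
    records: list[EccRecord] = []
    n_dropped = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 7:
            raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
        chrom, start_s, end_s, name, score_s, _strand, reads_s = fields[:7]
        try:
            start, end = int(start_s), int(end_s)
            score = float(score_s)
            reads = int(reads_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
        if reads < 0:
            raise ParseError(f"{path}:{lineno}: negative junction_reads")
        if chrom_lengths is not None:
            if chrom not in chrom_lengths:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > chrom_lengths[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: interval end {end} beyond "
                    f"{chrom} length {chrom_lengths[chrom]}"
                )
        if score <= 0:
            n_dropped += 1
            continue
        records.append(
            EccRecord(chrom, start, end, name, score, reads, sample_id=sample_id)
        )
    if n_dropped:
        logger.info(
            "%s: dropped %d record(s) with circle_score <= 0", path, n_dropped
        )
    return records


def write_ecc_table(records: Sequence[EccRecord], path: str | Path) -> None:
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.name))
    with _open_text(path, "wt") as fh:
        fh.write(_SORT_NOTE)
        for r in ordered:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t"
                f"{r.circle_score:g}\t.\t{r.junction_reads}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3.

    GFF3 coordinates are 1-based closed; internal are 0-based half-open,
    so start becomes start-1. A gene without exon children is treated as
    one exon spanning its body (logged).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(g, featuretype="exon")
        )
        if not exons:
            logger.warning("gene %s has no exons; using gene body", g.id)
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.attributes.get("ID", [g.id])[0],
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                start=g.start - 1,
                end=g.end,
                exons=tuple(exons),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_SORT_NOTE)
        for g in ordered:
            fh.write(
                f"{g.chrom}\tecckit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tecckit\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED feature tables (circRNA junctions, miRNA precursors)


def read_circ_junctions(path: str | Path) -> list[CircJunction]:
    """BED6-dialect: chrom, start, end, circ_id, coverage, strand."""
    out: list[CircJunction] = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 5:
            raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
        try:
            out.append(CircJunction(f[3], f[0], int(f[1]), int(f[2]), float(f[4])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.circ_id))
    return out


def write_circ_junctions(circs: Sequence[CircJunction], path: str | Path) -> None:
    ordered = sorted(circs, key=lambda c: (c.chrom, c.start, c.end, c.circ_id))
    with _open_text(path, "wt") as fh:
        fh.write(_SORT_NOTE)
        for c in ordered:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t{c.coverage:g}\t.\n")


def read_mirna_precursors(path: str | Path) -> list[MirnaPrecursor]:
    """BED6-dialect: chrom, start, end, mirna_id, score(unused), strand."""
    out: list[MirnaPrecursor] = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns")
        strand = f[5] if f[5] in "+-" else "+"
        try:
            out.append(MirnaPrecursor(f[3], f[0], strand, int(f[1]), int(f[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    out.sort(key=lambda m: (m.chrom, m.start, m.end, m.mirna_id))
    return out


def write_mirna_precursors(mirnas: Sequence[MirnaPrecursor], path: str | Path) -> None:
    ordered = sorted(mirnas, key=lambda m: (m.chrom, m.start, m.end, m.mirna_id))
    with _open_text(path, "wt") as fh:
        fh.write(_SORT_NOTE)
        for m in ordered:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.mirna_id}\t0\t{m.strand}\n")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(path: str | Path) -> ExpressionMatrix:
    """TSV with feature_id column then one integer-count column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected feature_id plus sample columns")
    df = df.set_index(df.columns[0])
    values = df.values.astype(float)
    if not np.allclose(values, np.round(values)):
        raise ParseError(f"{path}: expression counts must be integers")
    if (values < 0).any():
        raise ParseError(f"{path}: expression counts must be >= 0")
    return ExpressionMatrix(counts=df.astype(np.int64))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.counts.sort_index()
    df.index.name = "feature_id"
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Result tables


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write each result table as <name>.tsv in deterministic column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in sorted(tables):
        dest = outdir / f"{name}.tsv"
        tables[name].to_csv(dest, sep="\t", index=False)
        written[name] = dest
    return written
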