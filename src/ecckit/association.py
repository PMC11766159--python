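"""eccDNA-mRNA, eccDNA-miRNA and eccDNA-circRNA association rules.

Three coordinate predicates drive everything here, all strand-blind
because eccDNA circles are strandless:

* gene association - an eccDNA locus counts toward every gene body it
  overlaps by at least 1 bp;
* containment - a miRNA precursor (or circRNA interval) associates with
  an eccDNA locus that fully covers it (non-strict: equal intervals
  count);
* junction sharing - a circRNA back-spliced junction and an eccDNA
  junction match when both their start and end coordinates agree within
  a tolerance (0 by default; a one-end mode accepts either coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import CircJunction, EccRecord, GeneModel, LocusCatalog, MirnaPrecursor


def _locus_frame(loci: LocusCatalog | pd.DataFrame) -> pd.DataFrame:
    if isinstance(loci, LocusCatalog):
        return loci.loci
    return loci


# ---------------------------------------------------------------------------
# eccDNA per gene and expression coupling


def ecc_per_gene(
    loci: LocusCatalog | pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.Series:
    """Count catalog loci overlapping each gene body by >= 1 bp.

    One locus may count toward several genes it overlaps.
    """
    frame = _locus_frame(loci)
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(frame.itertuples()):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, i)
    out = {}
    for g in genes:
        tree = trees.get(g.chrom)
        out[g.gene_id] = len(tree.overlap(g.start, g.end)) if tree else 0
    return pd.Series(out, dtype=np.int64)


def expression_correlation(
    per_gene_counts: pd.Series,
    normalized_expr: pd.DataFrame,
    sample_ids: Sequence[str],
) -> tuple[float, float]:
    """Spearman correlation of per-gene eccDNA count with mean expression.

    Uses the mean normalized expression over ``sample_ids`` (one
    condition); genes with zero eccDNA stay in; ties are mid-ranked by
    the Spearman statistic itself.
    """
    genes = per_gene_counts.index.intersection(normalized_expr.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes for a correlation")
    x = per_gene_counts.loc[genes].values
    y = normalized_expr.loc[genes, list(sample_ids)].mean(axis=1).values
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def density_correlation(
    loci: LocusCatalog | pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome eccDNAs/Mb vs genes/Mb with their Spearman correlation.

    Chromosomes with zero genes have an undefined density ratio and are
    excluded from the ratio column (NaN) but kept in the table. Returns
    (table, rho, p); rho is computed across chromosomes.
    """
    if len(chrom_lengths) < 3:
        raise ValueError("need >= 3 chromosomes for a density correlation")
    frame = _locus_frame(loci)
    rows = []
    for chrom in sorted(chrom_lengths):
        mb = chrom_lengths[chrom] / 1e6
        n_ecc = int((frame["chrom"] == chrom).sum())
        n_genes = sum(1 for g in genes if g.chrom == chrom)
        ecc_d = n_ecc / mb
        gene_d = n_genes / mb
        rows.append(
            {
                "chrom": chrom,
                "ecc_per_mb": ecc_d,
                "genes_per_mb": gene_d,
                "ratio": ecc_d / gene_d if n_genes else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    res = stats.spearmanr(table["ecc_per_mb"], table["genes_per_mb"])
    return table, float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# containment rules


def _contained_pairs(
    inner: Sequence[tuple[str, str, int, int]],
    loci: pd.DataFrame,
) -> list[tuple[str, str]]:
    """(feature_id, locus_id) for every feature fully inside a locus."""
    trees: dict[str, IntervalTree] = {}
    for locus_id, row in loci.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], locus_id
        )
    pairs = []
    for fid, chrom, start, end in inner:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(start, end):
            if iv.begin <= start and end <= iv.end:
                pairs.append((fid, iv.data))
    pairs.sort()
    return pairs


def mirna_containment(
    precursors: Sequence[MirnaPrecursor], loci: LocusCatalog | pd.DataFrame
) -> pd.DataFrame:
    """miRNA precursors fully covered by an eccDNA locus (strand ignored).

    The biological reading: such an eccDNA has the potential to encode
    the miRNA. Empty inputs give an empty frame.
    """
    frame = _locus_frame(loci)
    pairs = _contained_pairs(
        [(m.mirna_id, m.chrom, m.start, m.end) for m in precursors], frame
    )
    return pd.DataFrame(pairs, columns=["mirna_id", "locus_id"])


def locus_sharing(
    circs: Sequence[CircJunction], loci: LocusCatalog | pd.DataFrame
) -> pd.DataFrame:
    """circRNA intervals fully covered by an eccDNA locus (non-strict)."""
    frame = _locus_frame(loci)
    pairs = _contained_pairs(
        [(c.circ_id, c.chrom, c.start, c.end) for c in circs], frame
    )
    return pd.DataFrame(pairs, columns=["circ_id", "locus_id"])


# ---------------------------------------------------------------------------
# junction sharing


def junction_sharing(
    circs: Sequence[CircJunction],
    loci: LocusCatalog | pd.DataFrame,
    tolerance_bp: int = 0,
    require_both_ends: bool = True,
) -> tuple[pd.DataFrame, int]:
    """circRNA back-spliced junctions matching eccDNA junctions.

    Both-ends mode (default): same chromosome, |circ.start - ecc.start|
    <= tol and |circ.end - ecc.end| <= tol. One-end mode accepts either
    breakpoint matching. Returns (pair table with offsets, number of
    distinct circRNAs with >= 1 match).
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    frame = _locus_frame(loci)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for locus_id, row in frame.iterrows():
        by_chrom.setdefault(row["chrom"], []).append(
            (int(row["start"]), int(row["end"]), locus_id)
        )
    rows = []
    shared_circs: set[str] = set()
    for c in circs:
        for es, ee, locus_id in by_chrom.get(c.chrom, []):
            ds, de = abs(c.start - es), abs(c.end - ee)
            hit = (
                (ds <= tolerance_bp and de <= tolerance_bp)
                if require_both_ends
                else (ds <= tolerance_bp or de <= tolerance_bp)
            )
            if hit:
                rows.append(
                    {
                        "circ_id": c.circ_id,
                        "locus_id": locus_id,
                        "start_offset": c.start - es,
                        "end_offset": c.end - ee,
                    }
                )
                shared_circs.add(c.circ_id)
    table = pd.DataFrame(
        rows, columns=["circ_id", "locus_id", "start_offset", "end_offset"]
    ).sort_values(["circ_id", "locus_id"], kind="mergesort").reset_index(drop=True)
    return table, len(shared_circs)


def circ_expressed_on_locus(coverage: pd.DataFrame) -> pd.Series:
    """Expressed flag per (circ, ecc) pair: coverage strictly > 0.

    ``coverage`` needs a numeric "coverage" column; negative values are
    rejected.
    """
    cov = coverage["coverage"].astype(float)
    if (cov < 0).any():
        raise ValueError("coverage must be >= 0")
    return cov > 0


# ---------------------------------------------------------------------------
# combined report


@dataclass
class AssociationReport:
    per_gene_counts: pd.Series
    expression_rho: dict[str, tuple[float, float]]
    density_table: pd.DataFrame
    density_rho: float
    density_p: float
    mirna_pairs: pd.DataFrame
    junction_pairs: pd.DataFrame
    n_shared_junctions: int
    locus_pairs: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_gene_associations": int((self.per_gene_counts > 0).sum()),
            "expression_rho": {
                k: {"rho": v[0], "p": v[1]} for k, v in self.expression_rho.items()
            },
            "density_rho": self.density_rho,
            "density_p": self.density_p,
            "n_mirna_containments": int(len(self.mirna_pairs)),
            "n_shared_junctions": self.n_shared_junctions,
            "n_locus_sharings": int(len(self.locus_pairs)),
        }


def associate(
    catalog: LocusCatalog,
    genes: Sequence[GeneModel],
    normalized_expr: pd.DataFrame,
    precursors: Sequence[MirnaPrecursor],
    circs: Sequence[CircJunction],
    chrom_lengths: dict[str, int],
    tolerance_bp: int = 0,
) -> AssociationReport:
    """Run every association rule on one catalog and bundle the results."""
    per_gene = ecc_per_gene(catalog, genes)
    expr_rho = {}
    for cond in catalog.condition_labels():
        samples = catalog.samples_for(cond)
        if samples:
            expr_rho[cond] = expression_correlation(per_gene, normalized_expr, samples)
    table, rho, p = density_correlation(catalog, genes, chrom_lengths)
    junction_pairs, n_shared = junction_sharing(circs, catalog, tolerance_bp)
    return AssociationReport(
        per_gene_counts=per_gene,
        expression_rho=expr_rho,
        density_table=table,
        density_rho=rho,
        density_p=p,
        mirna_pairs=mirna_containment(precursors, catalog),
        junction_pairs=junction_pairs,
        n_shared_junctions=n_shared,
        locus_pairs=locus_sharing(circs, catalog),
    )
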