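"""Annotation-term over-representation for any feature set.

The statistic behind GO/KEGG-style analyses: for a query set of n
features drawn from a universe of N, a term annotating K universe
features and hitting k query features gets the hypergeometric upper-tail
p-value P[X >= k], BH-corrected across terms. Term content is supplied
by the caller as a term -> features mapping; no ontology is shipped.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .differential import bh_adjust
from .models import GeneModel


def genes_for_ecc(
    loci, genes: Sequence[GeneModel]
) -> set[str]:
    """Genes a set of eccDNA loci fully or partially covers (>= 1 bp).

    ``loci`` is a DataFrame with chrom/start/end columns (or a catalog's
    ``loci`` attribute).
    """
    frame = loci.loci if hasattr(loci, "loci") else loci
    trees: dict[str, IntervalTree] = {}
    for row in frame.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    hit = set()
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is not None and tree.overlap(g.start, g.end):
            hit.add(g.gene_id)
    return hit


def enrich(
    query_features: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    gate_on: str = "p",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query set.

    Returns a frame sorted by (p, term_id) with columns term_id, k, K,
    n, N, p, q, significant; ``gate_on`` chooses whether the alpha gate
    uses raw p (default) or BH q.
    """
    universe_set = set(universe)
    query = set(query_features)
    stray = query - universe_set
    if stray:
        raise ValueError(
            f"query features outside the universe: {sorted(stray)[:10]}"
        )
    if gate_on not in ("p", "q"):
        raise ValueError("gate_on must be 'p' or 'q'")
    N, n = len(universe_set), len(query)
    rows = []
    for term_id in sorted(term_map):
        members = set(term_map[term_id]) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        # P[X >= k], X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(result):
        result["q"] = bh_adjust(result["p"].values)
        result["significant"] = result[gate_on] <= alpha
        result = result.sort_values(["p", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
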