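"""Cross-sample eccDNA locus catalog, Venn partition, normalization and
differential abundance testing.

Loci are matched across samples by junction coordinates (exact by
default, optional bp tolerance with single-linkage merging). Abundance
is the junction read count. Features are called differentially abundant
when raw p < alpha and |log2 fold change| > lfc_min on mean CPM with a
pseudocount of 1; Benjamini-Hochberg q-values are reported alongside
(and can be made the gate with strict_fdr).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import EccRecord, LocusCatalog


# ---------------------------------------------------------------------------
# catalog construction


def build_locus_catalog(
    sample_sets: dict[str, Sequence[EccRecord]],
    conditions: dict[str, str],
    tolerance_bp: int = 0,
) -> LocusCatalog:
    """Merge per-sample eccDNA records into unified loci.

    Records merge (single linkage per chromosome) when both their starts
    and their ends differ by <= tolerance_bp; a merged locus takes the
    smallest enclosing interval and sums junction reads per sample.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    sample_ids = sorted(sample_sets)
    flat: list[tuple[str, int, int, str, int]] = []
    for sid in sample_ids:
        for r in sample_sets[sid]:
            flat.append((r.chrom, r.start, r.end, sid, r.junction_reads))
    if not flat:
        loci = pd.DataFrame(columns=["chrom", "start", "end"])
        counts = pd.DataFrame(columns=sample_ids)
        return LocusCatalog(loci=loci, counts=counts, conditions=dict(conditions))

    df = pd.DataFrame(flat, columns=["chrom", "start", "end", "sample", "reads"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    # union-find over records; link within a start-sorted sliding window
    parent = np.arange(len(df))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    starts = df["start"].values
    ends = df["end"].values
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1 :]:
                if starts[j] - starts[i] > tolerance_bp:
                    break
                if abs(int(ends[i]) - int(ends[j])) <= tolerance_bp:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri

    roots = np.array([find(i) for i in range(len(df))])
    df["cluster"] = roots
    loci_rows = []
    count_rows = []
    for cluster, sub in df.groupby("cluster", sort=False):
        loci_rows.append(
            (sub["chrom"].iloc[0], int(sub["start"].min()), int(sub["end"].max()))
        )
        count_rows.append(sub.groupby("sample")["reads"].sum())
    loci = pd.DataFrame(loci_rows, columns=["chrom", "start", "end"])
    counts = pd.DataFrame(count_rows).reindex(columns=sample_ids).fillna(0).astype(np.int64)
    counts.index = loci.index

    order = loci.sort_values(["chrom", "start", "end"]).index
    loci = loci.loc[order].reset_index(drop=True)
    counts = counts.loc[order].reset_index(drop=True)
    ids = [
        f"{c}:{s}-{e}" for c, s, e in zip(loci["chrom"], loci["start"], loci["end"])
    ]
    loci.index = pd.Index(ids, name="locus_id")
    counts.index = loci.index
    return LocusCatalog(loci=loci, counts=counts, conditions=dict(conditions))


# ---------------------------------------------------------------------------
# Venn partition


@dataclass
class VennPartition:
    condition_a: str
    condition_b: str
    only_a: list[str]
    only_b: list[str]
    shared: list[str]

    @property
    def sizes(self) -> dict[str, int]:
        return {
            f"only_{self.condition_a}": len(self.only_a),
            f"only_{self.condition_b}": len(self.only_b),
            "shared": len(self.shared),
        }


def venn_partition(catalog: LocusCatalog) -> VennPartition:
    """Presence/absence partition of catalog loci between two conditions.

    A locus is detected in a condition when any replicate has count > 0.
    The three sets are disjoint and cover the catalog.
    """
    labels = catalog.condition_labels()
    if len(labels) != 2:
        raise ValueError(f"venn partition needs exactly 2 conditions, got {labels}")
    a, b = labels
    det_a = catalog.counts[catalog.samples_for(a)].gt(0).any(axis=1)
    det_b = catalog.counts[catalog.samples_for(b)].gt(0).any(axis=1)
    if (~det_a & ~det_b).any():
        raise ValueError("catalog contains loci with no read support in any sample")
    only_a = list(catalog.counts.index[det_a & ~det_b])
    only_b = list(catalog.counts.index[det_b & ~det_a])
    shared = list(catalog.counts.index[det_a & det_b])
    part = VennPartition(a, b, only_a, only_b, shared)
    assert len(only_a) + len(only_b) + len(shared) == catalog.n_loci
    return part


# ---------------------------------------------------------------------------
# normalization


def normalize(
    counts: pd.DataFrame,
    method: Literal["CPM", "TPM"] = "CPM",
    feature_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """CPM (counts per million) or length-aware TPM normalization."""
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s) {list(zero.index)}")
    if method == "CPM":
        return counts * 1e6 / colsums
    if method == "TPM":
        if feature_lengths is None:
            raise ValueError("TPM requires feature_lengths")
        lengths = feature_lengths.reindex(counts.index)
        if lengths.isna().any():
            missing = list(lengths.index[lengths.isna()])[:5]
            raise ValueError(f"missing lengths for features {missing}")
        rate = counts.div(lengths / 1e3, axis=0)
        return rate * 1e6 / rate.sum(axis=0)
    raise ValueError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# BH adjustment


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# differential testing


def _pooled_fisher_p(
    counts: np.ndarray, a_cols: np.ndarray, b_cols: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p per feature on condition-pooled counts."""
    a = counts[:, a_cols].sum(axis=1)
    b = counts[:, b_cols].sum(axis=1)
    ta, tb = int(a.sum()), int(b.sum())
    out = np.empty(len(a))
    for i in range(len(a)):
        out[i] = stats.fisher_exact(
            [[int(a[i]), ta - int(a[i])], [int(b[i]), tb - int(b[i])]]
        )[1]
    return out


def _logcpm_t_p(
    cpm: np.ndarray, a_cols: np.ndarray, b_cols: np.ndarray, equal_var: bool
) -> np.ndarray:
    """Two-sample t on log2(CPM+1). Pooled variance by default: with the
    tiny replicate numbers typical here (n=3 per group) the Satterthwaite
    degrees of freedom of the Welch variant are anticonservative, while the
    pooled test is exact under normality at equal group sizes."""
    x = np.log2(cpm[:, a_cols] + 1)
    y = np.log2(cpm[:, b_cols] + 1)
    res = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue)
    return np.where(np.isnan(p), 1.0, p)


def test_differential(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    method: Literal["pooled-fisher", "logcpm-t", "welch-logcpm"] = "pooled-fisher",
    feature_kind: str = "eccDNA",
    strict_fdr: bool = False,
) -> pd.DataFrame:
    """Differential abundance between the two conditions of ``conditions``.

    Fold change is log2 of mean-CPM ratio with pseudocount 1. The default
    pooled-fisher method tests each feature's pooled counts against the
    remainder of the library in a 2x2 Fisher exact test; logcpm-t is a
    replicate-aware two-sample t (pooled variance) on log2(CPM + 1), and
    welch-logcpm its unequal-variance variant. Direction is "up"/"down"
    when p (or q when strict_fdr) < alpha and |log2fc| > lfc_min, else "ns".
    """
    labels: list[str] = []
    for c in conditions.values():
        if c not in labels:
            labels.append(c)
    if len(labels) != 2:
        raise ValueError("differential testing needs exactly 2 conditions")
    cond_a, cond_b = labels
    cols = list(counts.columns)
    a_cols = np.array([cols.index(s) for s, c in conditions.items() if c == cond_a])
    b_cols = np.array([cols.index(s) for s, c in conditions.items() if c == cond_b])
    if len(a_cols) == 0 or len(b_cols) == 0:
        raise ValueError("each condition needs at least one replicate")

    mat = counts.values.astype(np.int64)
    cpm = normalize(counts, "CPM").values
    mean_a = cpm[:, a_cols].mean(axis=1)
    mean_b = cpm[:, b_cols].mean(axis=1)
    log2fc = np.log2((mean_a + 1) / (mean_b + 1))

    if method == "pooled-fisher":
        p = _pooled_fisher_p(mat, a_cols, b_cols)
    elif method == "logcpm-t":
        p = _logcpm_t_p(cpm, a_cols, b_cols, equal_var=True)
    elif method == "welch-logcpm":
        p = _logcpm_t_p(cpm, a_cols, b_cols, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    q = bh_adjust(p)

    gate = q if strict_fdr else p
    direction = np.where(
        (gate < alpha) & (np.abs(log2fc) > lfc_min),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "kind": feature_kind,
            f"mean_cpm_{cond_a}": mean_a,
            f"mean_cpm_{cond_b}": mean_b,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
        }
    ).set_index("feature_id")
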