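"""Association predicates against brute-force all-pairs oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecckit import association as assoc
from ecckit.models import CircJunction, GeneModel, MirnaPrecursor


def _loci(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end"],
        index=[f"l{i}" for i in range(len(rows))],
    )


class TestEccPerGene:
    GENES = [
        GeneModel("g1", "chr1", "+", 100, 500, ((100, 500),)),
        GeneModel("g2", "chr1", "+", 500, 900, ((500, 900),)),
    ]

    def test_single_containment(self):
        counts = assoc.ecc_per_gene(_loci([("chr1", 200, 300)]), self.GENES)
        assert counts.to_dict() == {"g1": 1, "g2": 0}

    def test_locus_spanning_two_genes_counts_twice(self):
        counts = assoc.ecc_per_gene(_loci([("chr1", 400, 600)]), self.GENES)
        assert counts.to_dict() == {"g1": 1, "g2": 1}

    def test_matches_brute_force(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", s := int(rng.integers(0, 9_000)),
                      s + 500, ((s, s + 500),))
            for i in range(30)
        ]
        loci = _loci([
            ("chr1", s := int(rng.integers(0, 9_500)), s + int(rng.integers(10, 800)))
            for _ in range(200)
        ])
        counts = assoc.ecc_per_gene(loci, genes)
        for g in genes:
            manual = sum(
                (row.start < g.end) and (row.end > g.start)
                for row in loci.itertuples()
            )
            assert counts[g.gene_id] == manual


class TestExpressionCorrelation:
    def test_perfect_rank_agreement(self):
        counts = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        expr = pd.DataFrame({"s1": [10, 20, 30, 40, 50]}, index=list("abcde"))
        rho, _ = assoc.expression_correlation(counts, expr, ["s1"])
        assert rho == pytest.approx(1.0)

    def test_too_few_genes(self):
        counts = pd.Series([1, 2], index=list("ab"))
        expr = pd.DataFrame({"s1": [1, 2]}, index=list("ab"))
        with pytest.raises(ValueError):
            assoc.expression_correlation(counts, expr, ["s1"])

    def test_null_coupling_is_near_zero(self, rng):
        hits = 0
        for _ in range(20):
            counts = pd.Series(rng.poisson(1.0, size=500),
                               index=[f"g{i}" for i in range(500)])
            expr = pd.DataFrame({"s1": rng.poisson(100, size=500)}, index=counts.index)
            rho, _ = assoc.expression_correlation(counts, expr, ["s1"])
            hits += abs(rho) < 0.1
        assert hits >= 19


class TestDensityCorrelation:
    def test_hand_computed_toy(self):
        genes = [
            GeneModel(f"g{i}", c, "+", 0, 100, ((0, 100),))
            for i, c in enumerate(["chr1", "chr1", "chr2"])
        ]
        loci = _loci([("chr1", 0, 50), ("chr1", 60, 90), ("chr2", 0, 50), ("chr3", 0, 9)])
        lengths = {"chr1": 1_000_000, "chr2": 2_000_000, "chr3": 500_000}
        table, rho, p = assoc.density_correlation(loci, genes, lengths)
        t = table.set_index("chrom")
        assert t.loc["chr1", "ecc_per_mb"] == pytest.approx(2.0)
        assert t.loc["chr1", "genes_per_mb"] == pytest.approx(2.0)
        assert t.loc["chr1", "ratio"] == pytest.approx(1.0)
        assert t.loc["chr2", "ecc_per_mb"] == pytest.approx(0.5)
        assert np.isnan(t.loc["chr3", "ratio"])  # zero genes -> undefined

    def test_generator_gradient_yields_positive_rho(self, dataset):
        # genic eccDNA placement follows the gene-density gradient, so
        # eccDNAs/Mb and genes/Mb must correlate positively
        table, rho, _ = assoc.density_correlation(
            dataset.truth.loci, dataset.genes, dataset.genome.lengths
        )
        assert rho > 0

    def test_needs_three_chromosomes(self):
        with pytest.raises(ValueError):
            assoc.density_correlation(_loci([]), [], {"chr1": 100, "chr2": 100})


class TestContainment:
    LOCI = _loci([("chr1", 100, 300)])

    def test_full_containment_reported(self):
        m = MirnaPrecursor("m1", "chr1", "+", 150, 220)
        pairs = assoc.mirna_containment([m], self.LOCI)
        assert pairs.values.tolist() == [["m1", "l0"]]

    def test_partial_overlap_not_reported(self):
        m = MirnaPrecursor("m1", "chr1", "+", 250, 350)
        assert len(assoc.mirna_containment([m], self.LOCI)) == 0

    def test_exact_equality_is_contained(self):
        c = CircJunction("c1", "chr1", 100, 300)
        assert len(assoc.locus_sharing([c], self.LOCI)) == 1

    def test_containment_is_antisymmetric(self):
        # circ strictly inside the locus: the reverse containment must fail
        inner = _loci([("chr1", 150, 250)])
        outer = CircJunction("c1", "chr1", 100, 300)
        assert len(assoc.locus_sharing([outer], inner)) == 0

    def test_matches_brute_force_all_pairs(self, rng):
        loci = _loci([
            ("chr1", s := int(rng.integers(0, 50_000)), s + int(rng.integers(100, 3_000)))
            for _ in range(300)
        ])
        mirnas = [
            MirnaPrecursor(f"m{i}", "chr1", "+", s := int(rng.integers(0, 52_000)), s + 80)
            for i in range(300)
        ]
        pairs = set(map(tuple, assoc.mirna_containment(mirnas, loci).values))
        brute = {
            (m.mirna_id, locus_id)
            for m in mirnas
            for locus_id, row in loci.iterrows()
            if row["start"] <= m.start and m.end <= row["end"]
        }
        assert pairs == brute


class TestJunctionSharing:
    LOCI = _loci([("chr1", 100, 300)])

    def test_exact_match(self):
        table, n = assoc.junction_sharing(
            [CircJunction("c1", "chr1", 100, 300)], self.LOCI, 0
        )
        assert n == 1 and table["start_offset"].iloc[0] == 0

    def test_tolerance_boundary(self):
        circ = [CircJunction("c1", "chr1", 101, 300)]
        assert assoc.junction_sharing(circ, self.LOCI, 0)[1] == 0
        assert assoc.junction_sharing(circ, self.LOCI, 1)[1] == 1

    def test_one_end_mode(self):
        circ = [CircJunction("c1", "chr1", 100, 999)]
        assert assoc.junction_sharing(circ, self.LOCI, 0)[1] == 0
        assert assoc.junction_sharing(circ, self.LOCI, 0, require_both_ends=False)[1] == 1

    def test_circ_counted_once_despite_multiple_matches(self):
        loci = _loci([("chr1", 100, 300), ("chr1", 100, 300)])
        _, n = assoc.junction_sharing([CircJunction("c1", "chr1", 100, 300)], loci, 0)
        assert n == 1

    def test_predicate_symmetry_at_zero_tolerance(self, rng):
        coords = [
            ("chr1", s := int(rng.integers(0, 10_000)), s + int(rng.integers(50, 500)))
            for _ in range(100)
        ]
        circs = [CircJunction(f"c{i}", *coords[i]) for i in range(50)]
        loci = _loci(coords[30:])
        pairs, _ = assoc.junction_sharing(circs, loci, 0)
        for row in pairs.itertuples():
            c = next(c for c in circs if c.circ_id == row.circ_id)
            locus = loci.loc[row.locus_id]
            assert (c.chrom, c.start, c.end) == (
                locus["chrom"], locus["start"], locus["end"]
            )


class TestCircExpressed:
    def test_rule_boundary(self):
        cov = pd.DataFrame({"coverage": [0.0, 0.01, 5.0]})
        assert assoc.circ_expressed_on_locus(cov).tolist() == [False, True, True]

    def test_negative_coverage_is_error(self):
        with pytest.raises(ValueError):
            assoc.circ_expressed_on_locus(pd.DataFrame({"coverage": [-1.0]}))

    def test_matches_threshold_oracle(self, rng):
        vals = rng.uniform(0, 1, size=100) * (rng.random(100) > 0.3)
        cov = pd.DataFrame({"coverage": vals})
        assert (assoc.circ_expressed_on_locus(cov).values == (vals > 0)).all()


def test_generator_truth_round_trip(dataset):
    """Shared-junction and containment counts equal the generator's flags."""
    _, n_shared = assoc.junction_sharing(dataset.circs, dataset.truth.loci, 0)
    assert n_shared == int(dataset.truth.circs["shared_junction"].sum())
    pairs = assoc.mirna_containment(dataset.mirnas, dataset.truth.loci)
    inside = set(dataset.truth.mirnas.loc[dataset.truth.mirnas["inside_ecc"], "mirna_id"])
    assert set(pairs["mirna_id"]) == inside
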