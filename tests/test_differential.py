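"""Catalog construction, Venn logic, normalization, testing and BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecckit import differential as diff
from ecckit import simulate as sim
from ecckit.models import EccRecord


def _rec(chrom, start, end, reads=5, sample="s1"):
    return EccRecord(chrom, start, end, f"{chrom}:{start}", 1.0, reads, sample)


COND2 = {"a1": "A", "b1": "B"}


class TestCatalog:
    def test_exact_match_merges(self):
        cat = diff.build_locus_catalog(
            {"a1": [_rec("chr1", 100, 300, 4)], "b1": [_rec("chr1", 100, 300, 7)]},
            COND2,
        )
        assert cat.n_loci == 1
        assert cat.counts.iloc[0].to_dict() == {"a1": 4, "b1": 7}

    def test_tolerance_controls_merging(self):
        sets = {
            "a1": [_rec("chr1", 100, 300)],
            "b1": [_rec("chr1", 105, 302)],
        }
        assert diff.build_locus_catalog(sets, COND2, tolerance_bp=0).n_loci == 2
        cat = diff.build_locus_catalog(sets, COND2, tolerance_bp=10)
        assert cat.n_loci == 1
        assert cat.loci.iloc[0][["start", "end"]].tolist() == [100, 302]

    def test_negative_tolerance_is_error(self):
        with pytest.raises(ValueError):
            diff.build_locus_catalog({}, {}, tolerance_bp=-1)

    def test_catalog_matches_truth_exactly(self, dataset):
        cat = diff.build_locus_catalog(dataset.samples, dataset.conditions, 0)
        truth_keys = set(
            zip(dataset.truth.loci["chrom"], dataset.truth.loci["start"],
                dataset.truth.loci["end"])
        )
        cat_keys = set(zip(cat.loci["chrom"], cat.loci["start"], cat.loci["end"]))
        assert cat_keys == truth_keys

    def test_every_record_lands_in_one_locus(self, dataset):
        cat = diff.build_locus_catalog(dataset.samples, dataset.conditions, 0)
        total_reads = sum(
            r.junction_reads for recs in dataset.samples.values() for r in recs
        )
        assert int(cat.counts.values.sum()) == total_reads


class TestVenn:
    def _catalog(self, counts_a, counts_b):
        n = len(counts_a)
        loci = pd.DataFrame(
            {"chrom": ["chr1"] * n, "start": range(n), "end": range(1, n + 1)},
            index=[f"l{i}" for i in range(n)],
        )
        counts = pd.DataFrame(
            {"a1": counts_a, "b1": counts_b}, index=loci.index
        )
        return diff.LocusCatalog(loci=loci, counts=counts, conditions=COND2)

    def test_only_and_shared(self):
        venn = diff.venn_partition(self._catalog([1, 1, 0], [0, 2, 5]))
        assert venn.only_a == ["l0"] and venn.shared == ["l1"] and venn.only_b == ["l2"]

    def test_partition_is_exhaustive(self, dataset):
        cat = diff.build_locus_catalog(dataset.samples, dataset.conditions, 0)
        venn = diff.venn_partition(cat)
        assert sum(venn.sizes.values()) == cat.n_loci
        assert not (set(venn.only_a) & set(venn.only_b))
        assert not (set(venn.shared) & (set(venn.only_a) | set(venn.only_b)))

    def test_specific_loci_counted(self, dataset):
        cat = diff.build_locus_catalog(dataset.samples, dataset.conditions, 0)
        venn = diff.venn_partition(cat)
        truth = dataset.truth.loci
        n_a = (truth["specific_to"] == sim.CONDITION_A).sum()
        n_b = (truth["specific_to"] == sim.CONDITION_B).sum()
        assert len(venn.only_a) == n_a and len(venn.only_b) == n_b


class TestNormalize:
    def test_single_feature_cpm(self):
        df = pd.DataFrame({"s": [5]}, index=["f"])
        assert diff.normalize(df, "CPM").iloc[0, 0] == 1e6

    def test_two_equal_features(self):
        df = pd.DataFrame({"s": [5, 5]}, index=["f", "g"])
        assert (diff.normalize(df, "CPM")["s"] == 5e5).all()

    def test_cpm_columns_sum_to_million(self, rng):
        df = pd.DataFrame(rng.integers(1, 100, size=(30, 4)))
        assert np.allclose(diff.normalize(df, "CPM").sum(axis=0), 1e6)

    def test_zero_colsum_names_sample(self):
        df = pd.DataFrame({"ok": [1], "empty": [0]}, index=["f"])
        with pytest.raises(ValueError, match="empty"):
            diff.normalize(df, "CPM")

    def test_tpm_matches_two_pass_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 200, size=(10, 3)),
            index=[f"g{i}" for i in range(10)], columns=list("abc"),
        )
        counts.iloc[0] += 1  # avoid all-zero columns
        lengths = pd.Series(rng.integers(200, 5000, size=10), index=counts.index)
        tpm = diff.normalize(counts, "TPM", feature_lengths=lengths)
        for col in counts:
            rpk = counts[col] / (lengths / 1e3)
            expected = rpk / rpk.sum() * 1e6
            assert np.allclose(tpm[col], expected)
        assert np.allclose(tpm.sum(axis=0), 1e6)


class TestBH:
    def test_hand_computation(self):
        assert np.allclose(diff.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert diff.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])

    def test_matches_reference_step_up(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            ours = diff.bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_order_invariance(self, ps, rnd):
        shuffled = list(ps)
        rnd.shuffle(shuffled)
        ours = diff.bh_adjust(ps)
        theirs = diff.bh_adjust(shuffled)
        assert sorted(np.round(ours, 12)) == sorted(np.round(theirs, 12))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_at_least_p_over_rank_bound(self, ps):
        q = diff.bh_adjust(ps)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(ps) / len(ps))


class TestDifferential:
    def test_identical_groups_are_ns(self):
        counts = pd.DataFrame(
            {"a1": [10, 90], "a2": [10, 90], "b1": [10, 90], "b2": [10, 90]},
            index=["f", "rest"],
        )
        conds = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = diff.test_differential(counts, conds)
        assert (res["log2fc"] == 0).all() and (res["direction"] == "ns").all()

    def test_stated_pseudocount_arithmetic(self):
        # library sizes exactly 1e6 so CPM equals raw counts
        counts = pd.DataFrame(
            {
                "a1": [100, 1_000_000 - 100],
                "a2": [100, 1_000_000 - 100],
                "a3": [100, 1_000_000 - 100],
                "b1": [25, 1_000_000 - 25],
                "b2": [25, 1_000_000 - 25],
                "b3": [25, 1_000_000 - 25],
            },
            index=["f", "rest"],
        )
        conds = {s: ("A" if s.startswith("a") else "B") for s in counts}
        res = diff.test_differential(counts, conds)
        assert res.loc["f", "log2fc"] == pytest.approx(np.log2(101 / 26))

    def test_unknown_method(self):
        counts = pd.DataFrame({"a1": [1], "b1": [1]}, index=["f"])
        with pytest.raises(ValueError, match="method"):
            diff.test_differential(counts, COND2, method="deseq")

    def test_planted_lfc_recovered(self, rng):
        counts, lfc, conds = sim.simulate_count_matrix(
            400, 3, 0.2, 2.0, 0.1, 50.0, rng
        )
        res = diff.test_differential(counts, conds)
        planted_up = lfc == 2.0
        bias = res["log2fc"].values[planted_up].mean() - 2.0
        assert abs(bias) < 0.5

    def test_alpha_monotonicity(self, rng):
        counts, _, conds = sim.simulate_count_matrix(300, 3, 0.2, 2.0, 0.1, 50.0, rng)
        strict = diff.test_differential(counts, conds, alpha=0.01)
        loose = diff.test_differential(counts, conds, alpha=0.05)
        de_strict = set(strict.index[strict["direction"] != "ns"])
        de_loose = set(loose.index[loose["direction"] != "ns"])
        assert de_strict <= de_loose
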