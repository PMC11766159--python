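"""Generator contracts: composition, determinism, planted ground truth."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from ecckit import simulate as sim
from ecckit.characterize import classify_elements
from ecckit.config import SimConfig
from ecckit.models import ConfigError


def _cfg(**kw):
    defaults = dict(seed=5, chrom_lengths=[120_000], n_chromosomes=1,
                    n_ecc_loci=50, n_genes=10, ecc_size_max=5_000)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenome:
    def test_gc_concentration(self):
        cfg = SimConfig(seed=1, n_chromosomes=1, chrom_lengths=[1_000_000])
        cfg.gc_content = 0.5
        g = sim.generate_genome(cfg, np.random.default_rng(1))
        assert abs(g.gc_content() - 0.5) < 3 * np.sqrt(0.25 / 1e6)

    def test_zero_gc_is_all_at(self):
        cfg = _cfg()
        cfg.gc_content = 0.0
        g = sim.generate_genome(cfg, np.random.default_rng(0))
        assert set(g.seqs["chr1"]) <= {"A", "T"}

    def test_seed_determinism(self):
        cfg = _cfg()
        a = sim.generate_genome(cfg, np.random.default_rng(1)).seqs["chr1"]
        b = sim.generate_genome(cfg, np.random.default_rng(1)).seqs["chr1"]
        c = sim.generate_genome(cfg, np.random.default_rng(2)).seqs["chr1"]
        assert a == b
        assert a != c


class TestGeneModels:
    def test_density_and_exon_count(self):
        cfg = SimConfig(seed=2, n_chromosomes=1, chrom_lengths=[1_000_000],
                        n_genes=10, exons_per_gene=3)
        rng = np.random.default_rng(2)
        genome = sim.generate_genome(cfg, rng)
        genes = sim.generate_gene_models(cfg, genome, rng)
        assert len(genes) == 10  # 10 genes / 1 Mb
        assert all(len(g.exons) == 3 for g in genes)

    def test_non_overlapping(self, dataset):
        by_chrom = {}
        for g in dataset.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start

    def test_infeasible_density_raises(self):
        cfg = _cfg(n_genes=10)
        cfg.n_genes, cfg.gene_length = 50, 30_000  # 1.5 Mb of genes on 120 kb
        rng = np.random.default_rng(0)
        genome = sim.generate_genome(cfg, rng)
        with pytest.raises(ConfigError, match="cannot place"):
            sim.generate_gene_models(cfg, genome, rng)


class TestEccDataset:
    def test_null_config_has_zero_lfc(self):
        cfg = _cfg(de_fraction=0.0, count_dispersion=0.0)
        ds = sim.simulate_dataset(cfg)
        assert (ds.truth.loci["log2fc"] == 0).all()
        # realized mean |log2fc| stays near 0 under Poisson noise at mean 50
        from ecckit.differential import build_locus_catalog, test_differential

        cat = build_locus_catalog(ds.samples, ds.conditions)
        res = test_differential(cat.counts, cat.conditions)
        assert abs(res["log2fc"].mean()) < 0.1

    def test_planted_motif_written_at_flanks(self):
        cfg = _cfg(planted_motif_fraction=1.0, planted_motif="ATATAT")
        ds = sim.simulate_dataset(cfg)
        for row in ds.truth.loci.itertuples():
            up5 = ds.genome.fetch(row.chrom, row.start - 6, row.start)
            up3 = ds.genome.fetch(row.chrom, row.end - 6, row.end)
            assert up5 == "ATATAT" and up3 == "ATATAT"

    def test_genic_fraction_recovered(self):
        cfg = SimConfig(seed=9, n_ecc_loci=200, genic_fraction_target=0.5,
                        n_genes=60, ecc_size_max=3_000)
        ds = sim.simulate_dataset(cfg)
        summary = classify_elements(_truth_records(ds), ds.genes)
        assert abs(summary.genic_fraction - 0.5) <= 0.1

    def test_condition_specific_loci_zeroed(self, dataset):
        truth = dataset.truth.loci
        from ecckit.differential import build_locus_catalog

        cat = build_locus_catalog(dataset.samples, dataset.conditions)
        for row in truth[truth["specific_to"] != ""].itertuples():
            locus_id = f"{row.chrom}:{row.start}-{row.end}"
            other = [
                c for c in cat.condition_labels() if c != row.specific_to
            ][0]
            assert cat.counts.loc[locus_id, cat.samples_for(other)].sum() == 0
            assert cat.counts.loc[locus_id, cat.samples_for(row.specific_to)].sum() > 0

    def test_all_scores_positive(self, dataset):
        for recs in dataset.samples.values():
            assert all(r.circle_score > 0 for r in recs)

    def test_size_range_respected(self, dataset):
        lengths = dataset.truth.loci["end"] - dataset.truth.loci["start"]
        assert lengths.between(
            dataset.config.ecc_size_min, dataset.config.ecc_size_max
        ).all()


def _truth_records(ds):
    from ecckit.models import EccRecord

    return [
        EccRecord(r.chrom, r.start, r.end, r.locus_id, 1.0, 1)
        for r in ds.truth.loci.itertuples()
    ]


class TestAssociatedFeatures:
    def test_full_sharing_construction(self):
        cfg = _cfg(circ_shared_fraction=1.0, n_circ_total=30, n_circ_extra=0)
        ds = sim.simulate_dataset(cfg)
        from ecckit.association import junction_sharing

        _, n_shared = junction_sharing(ds.circs, ds.truth.loci, tolerance_bp=0)
        assert n_shared == len(ds.circs) == 30

    def test_no_inside_mirnas(self):
        cfg = _cfg(mirna_inside_fraction=0.0, n_mirna_precursors=20)
        ds = sim.simulate_dataset(cfg)
        from ecckit.association import mirna_containment

        assert len(mirna_containment(ds.mirnas, ds.truth.loci)) == 0

    def test_copula_recovers_target_rho(self):
        # Monte-Carlo over independent seeds; the generator calibrates the
        # latent coupling against count ties, so the realized correlation
        # between eccDNA-per-gene and mean expression should track 0.6
        rhos = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_ecc_loci=400, n_genes=120,
                            genic_fraction_target=0.7, ecc_size_max=4_000,
                            expr_coupling_rho=0.6)
            ds = sim.simulate_dataset(cfg)
            counts = sim._per_gene_ecc_counts(ds.truth.loci, ds.genes)
            mean_expr = ds.expr_genes.counts.mean(axis=1).values
            rhos.append(stats.spearmanr(counts, mean_expr).statistic)
        assert abs(np.mean(rhos) - 0.6) < 0.15


class TestDeterminism:
    def test_byte_identical_reruns(self, base_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sim.write_dataset(sim.simulate_dataset(base_config), d1)
        sim.write_dataset(sim.simulate_dataset(base_config), d2)
        files = sorted(p.name for p in d1.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
        assert mismatch == [] and errors == []

    def test_truth_json_round_trip(self, dataset, tmp_path):
        p = tmp_path / "truth.json"
        dataset.truth.to_json(p)
        back = sim.TruthTable.from_json(p)
        assert back.loci["locus_id"].tolist() == dataset.truth.loci["locus_id"].tolist()
        assert back.circs["shared_junction"].sum() == dataset.truth.circs["shared_junction"].sum()
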