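"""End-to-end orchestration: simulate -> characterize -> motifs ->
differential -> associate -> enrich, with a reproducibility manifest.

A run is driven by one YAML config. Input data come either from the
built-in simulator (``simulate:`` section) or from an existing directory
laid out like the simulator's output (``data_dir:``). All stage outputs
are deterministic given the seed; the manifest records the config
snapshot, input checksums and output paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import characterize as char
from . import differential as diff
from . import enrichment as enr
from . import io as eio
from . import motifs as mot
from . import simulate as sim
from .config import SimConfig
from .models import ConfigError, Genome

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "characterize", "motifs", "differential", "associate", "enrich")

DEFAULTS: dict[str, dict[str, Any]] = {
    "motifs": {"k": 10, "n_perm": 100},
    "differential": {"alpha": 0.05, "lfc_min": 1.0, "method": "pooled-fisher",
                     "tolerance_bp": 0, "strict_fdr": False},
    "associate": {"tolerance_bp": 0, "de_only": False},
    "enrich": {"alpha": 0.05, "gate_on": "p", "term_map": None},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{config_path}: top level must be a mapping")
    if "simulate" not in cfg and "data_dir" not in cfg:
        raise ConfigError(
            f"{config_path}: need a 'simulate' section or a 'data_dir'"
        )
    unknown = set(cfg) - {"seed", "outdir", "stages", "data_dir", *ALL_STAGES}
    if unknown:
        raise ConfigError(f"{config_path}: unknown sections {sorted(unknown)}")
    return cfg


def _stage_params(cfg: dict, stage: str) -> dict:
    params = dict(DEFAULTS.get(stage, {}))
    params.update(cfg.get(stage) or {})
    return params


class PipelineData:
    """Loaded inputs shared by the analysis stages."""

    def __init__(self, data_dir: Path):
        self.dir = data_dir
        self.genome = Genome.from_fasta(data_dir / "genome.fasta")
        self.genes = eio.read_gff3_genes(data_dir / "genes.gff3")
        self.conditions = {}
        cond_path = data_dir / "conditions.tsv"
        if not cond_path.exists():
            raise ConfigError(f"missing {cond_path}")
        for line in cond_path.read_text().splitlines()[1:]:
            sid, cond = line.split("\t")
            self.conditions[sid] = cond
        lengths = self.genome.lengths
        self.samples = {
            sid: eio.read_ecc_table(data_dir / f"ecc_{sid}.bed", lengths, sid)
            for sid in self.conditions
        }
        self.circs = eio.read_circ_junctions(data_dir / "circ.bed")
        self.mirnas = eio.read_mirna_precursors(data_dir / "mirna.bed")
        self.expr_genes = eio.read_expression(data_dir / "expr_genes.tsv")
        self.expr_mirna = eio.read_expression(data_dir / "expr_mirna.tsv")


def run_pipeline(
    config_path: str | Path,
    outdir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    cfg = _load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_seed = seed if seed is not None else int(cfg.get("seed", 0))
    wanted = list(stages or cfg.get("stages") or ALL_STAGES)
    for s in wanted:
        if s not in ALL_STAGES:
            raise ConfigError(f"unknown stage {s!r}")

    manifest: dict[str, Any] = {
        "tool": "ecckit",
        "version": __version__,
        "seed": run_seed,
        "config": cfg,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # --- inputs: simulate or load -----------------------------------------
    if "simulate" in cfg and "simulate" in wanted:
        sim_cfg = SimConfig(**{**(cfg.get("simulate") or {}), "seed": run_seed})
        dataset = sim.simulate_dataset(sim_cfg)
        data_dir = outdir / "data"
        paths = sim.write_dataset(dataset, data_dir)
        manifest["stages"]["simulate"] = {
            "outputs": {k: str(p) for k, p in sorted(paths.items())},
            "config": asdict(sim_cfg),
        }
    else:
        data_dir = Path(cfg["data_dir"])
        if not data_dir.exists():
            raise ConfigError(f"data_dir {data_dir} does not exist")
    data = PipelineData(data_dir)
    manifest["inputs"] = {
        p.name: _sha256(p) for p in sorted(data_dir.iterdir()) if p.is_file()
    }

    results_dir = outdir / "results"
    results_dir.mkdir(exist_ok=True)
    all_records = [r for recs in data.samples.values() for r in recs]
    catalog = None

    def need_catalog():
        nonlocal catalog
        if catalog is None:
            tol = _stage_params(cfg, "differential")["tolerance_bp"]
            catalog = diff.build_locus_catalog(data.samples, data.conditions, tol)
        return catalog

    # --- characterize ------------------------------------------------------
    if "characterize" in wanted:
        tables = {}
        counts = char.count_per_chromosome(all_records)
        tables["chrom_counts"] = counts.rename("count").rename_axis("chrom").reset_index()
        dens = char.density_per_mb(all_records, data.genome.lengths)
        tables["chrom_density"] = dens.rename("ecc_per_mb").rename_axis("chrom").reset_index()
        summary = char.classify_elements(all_records, data.genes)
        tables["element_fractions"] = pd.DataFrame(
            [summary.fractions | {"genic": summary.genic_fraction}]
        )
        hist = char.size_histogram(all_records)
        tables["size_histogram"] = hist.rename("count").rename_axis("size_bin").reset_index()
        prof = char.gc_profile(all_records, data.genome)
        tables["gc_profile"] = pd.DataFrame(
            {
                "bin": range(len(prof.body)),
                "upstream": prof.upstream,
                "body": prof.body,
                "downstream": prof.downstream,
                "genome_average": prof.genome_average,
            }
        )
        tables["window_counts"] = char.window_counts(all_records, data.genome.lengths)
        written = eio.write_results(tables, results_dir)
        manifest["stages"]["characterize"] = {
            "outputs": {k: str(p) for k, p in written.items()},
            "n_records": len(all_records),
        }

    # --- motifs ------------------------------------------------------------
    if "motifs" in wanted:
        params = _stage_params(cfg, "motifs")
        cat = need_catalog()
        loci_records = _catalog_records(cat)
        five, three = mot.analyze_breakpoint_motifs(
            loci_records, data.genome, k=params["k"],
            n_perm=params["n_perm"], seed=run_seed,
        )
        table = pd.concat(
            [mot.profile_to_frame(five), mot.profile_to_frame(three)],
            ignore_index=True,
        )
        written = eio.write_results({"breakpoint_motifs": table}, results_dir)
        manifest["stages"]["motifs"] = {
            "outputs": {k: str(p) for k, p in written.items()},
            "n_sequences": five.n_sequences,
        }

    # --- differential -------------------------------------------------------
    de_loci_ids: list[str] | None = None
    if "differential" in wanted:
        params = _stage_params(cfg, "differential")
        cat = need_catalog()
        venn = diff.venn_partition(cat)
        res = diff.test_differential(
            cat.counts, cat.conditions, alpha=params["alpha"],
            lfc_min=params["lfc_min"], method=params["method"],
            strict_fdr=params["strict_fdr"],
        )
        de_loci_ids = list(res.index[res["direction"] != "ns"])
        tables = {
            "catalog": cat.loci.join(cat.counts).reset_index(),
            "venn": pd.DataFrame(
                [{"set": k, "size": v} for k, v in venn.sizes.items()]
            ),
            "differential_ecc": res.reset_index(),
        }
        gene_res = diff.test_differential(
            data.expr_genes.counts, data.conditions, alpha=params["alpha"],
            lfc_min=params["lfc_min"], method="logcpm-t", feature_kind="gene",
        )
        mirna_res = diff.test_differential(
            data.expr_mirna.counts, data.conditions, alpha=params["alpha"],
            lfc_min=params["lfc_min"], method="logcpm-t", feature_kind="miRNA",
        )
        tables["differential_genes"] = gene_res.reset_index()
        tables["differential_mirna"] = mirna_res.reset_index()
        written = eio.write_results(tables, results_dir)
        manifest["stages"]["differential"] = {
            "outputs": {k: str(p) for k, p in written.items()},
            "venn": venn.sizes,
            "n_up": int((res["direction"] == "up").sum()),
            "n_down": int((res["direction"] == "down").sum()),
        }

    # --- associate ----------------------------------------------------------
    if "associate" in wanted:
        params = _stage_params(cfg, "associate")
        cat = need_catalog()
        norm_expr = diff.normalize(data.expr_genes.counts, "CPM")
        report = assoc.associate(
            cat, data.genes, norm_expr, data.mirnas, data.circs,
            data.genome.lengths, tolerance_bp=params["tolerance_bp"],
        )
        tables = {
            "ecc_per_gene": report.per_gene_counts.rename("n_ecc")
            .rename_axis("gene_id").reset_index(),
            "density_table": report.density_table,
            "mirna_associations": report.mirna_pairs,
            "junction_sharing": report.junction_pairs,
            "locus_sharing": report.locus_pairs,
        }
        written = eio.write_results(tables, results_dir)
        with open(results_dir / "association_summary.json", "w") as fh:
            json.dump(report.summary(), fh, indent=1, sort_keys=True)
        manifest["stages"]["associate"] = {
            "outputs": {k: str(p) for k, p in written.items()},
            "summary": report.summary(),
        }

    # --- enrich --------------------------------------------------------------
    if "enrich" in wanted:
        params = _stage_params(cfg, "enrich")
        term_path = params.get("term_map")
        if term_path:
            term_map: dict[str, list[str]] = {}
            tm = pd.read_csv(term_path, sep="\t", names=["term_id", "feature_id"],
                             comment="#")
            for term, sub in tm.groupby("term_id"):
                term_map[str(term)] = list(sub["feature_id"])
            cat = need_catalog()
            loci = cat.loci
            if de_loci_ids is not None:
                loci = loci.loc[[i for i in de_loci_ids if i in loci.index]]
            query = enr.genes_for_ecc(loci, data.genes)
            universe = [g.gene_id for g in data.genes]
            result = enr.enrich(query, term_map, universe,
                                alpha=params["alpha"], gate_on=params["gate_on"])
            written = eio.write_results({"enrichment": result}, results_dir)
            manifest["stages"]["enrich"] = {
                "outputs": {k: str(p) for k, p in written.items()},
                "n_query": len(query),
                "n_significant": int(result["significant"].sum()) if len(result) else 0,
            }
        else:
            manifest["stages"]["enrich"] = {"skipped": "no term_map configured"}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _catalog_records(catalog) -> list:
    """Represent catalog loci as records for motif extraction."""
    from .models import EccRecord

    out = []
    for locus_id, row in catalog.loci.iterrows():
        reads = int(catalog.counts.loc[locus_id].sum())
        out.append(
            EccRecord(row["chrom"], int(row["start"]), int(row["end"]),
                      str(locus_id), 1.0, reads, sample_id="catalog")
        )
    return out
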