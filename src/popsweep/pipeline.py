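"""End-to-end orchestration: simulate -> filter -> annotate -> scan ->
structure -> expression, with a manifest of hashed artifacts.

A single configuration (YAML mapping or dict) drives every stage; all
randomness flows from one root seed so a rerun with the same configuration
reproduces byte-identical outputs.  Exactly one input source is allowed:
either a ``simdata`` block (synthetic dataset generated on the fly) or an
``inputs`` block with paths to an existing VCF / FASTA / GFF3 / population
map / Ct table.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from popsweep import annotate as ann_mod
from popsweep import expression as expr_mod
from popsweep import simdata as sim_mod
from popsweep import structure as struct_mod
from popsweep import sweepscan as sweep_mod
from popsweep import variants as var_mod

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "demo", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate(config: dict) -> None:
    has_sim = "simdata" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        raise PipelineError(
            "configuration must contain exactly one of 'simdata' or 'inputs'")
    if has_inputs:
        for key in ("vcf", "fasta", "gff3", "pops"):
            p = config["inputs"].get(key)
            if p is None or not Path(p).exists():
                raise PipelineError(f"inputs.{key} missing or does not exist: {p}")


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    The manifest maps artifact names to paths and SHA-256 hashes and
    records the parameters of each stage.
    """
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    artifacts: dict[str, Path] = {}

    # stage 1: inputs --------------------------------------------------------
    try:
        if "simdata" in config:
            sim_cfg = sim_mod.SimConfig(**{**config["simdata"], "seed": seed})
            dataset = sim_mod.simulate_populations(sim_cfg)
            sim_paths = sim_mod.write_dataset(dataset, out / "simdata")
            vcf_path, fasta_path, gff_path = (sim_paths["vcf"],
                                              sim_paths["ref"],
                                              sim_paths["gff3"])
            pops = {name: pop for name, pop in
                    zip(dataset.sample_names, dataset.sample_pop)}
            expr_cfg = config.get("expression", {})
            effects = expr_cfg.get("effect_sizes", {
                "immune_like": {"LP": 0.25},
                "osmo_like": {"LP": 4.0},
            })
            ct = sim_mod.simulate_qpcr(
                groups=list(sim_cfg.pop_names),
                target_genes=sorted(effects),
                effect_sizes=effects,
                seed=seed + 1,
            )
            ct_path = _write_tsv(ct, out / "simdata" / "ct_table.tsv")
            artifacts.update({k: v for k, v in sim_paths.items()})
            artifacts["ct_table"] = ct_path
        else:
            inputs = config["inputs"]
            vcf_path, fasta_path, gff_path = (Path(inputs["vcf"]),
                                              Path(inputs["fasta"]),
                                              Path(inputs["gff3"]))
            pops_df = pd.read_csv(inputs["pops"], sep="\t", header=None,
                                  names=["sample", "pop"])
            pops = dict(zip(pops_df["sample"], pops_df["pop"]))
            ct_path = Path(inputs["ct"]) if inputs.get("ct") else None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'inputs' failed: {exc}") from exc

    # stage 2: filtering and summaries --------------------------------------
    try:
        records = var_mod.read_vcf(vcf_path)
        fcfg = var_mod.FilterConfig(**config.get("filter", {}))
        passing, removals = var_mod.apply_hard_filters(records, fcfg)
        annotation = ann_mod.load_annotation(gff_path, fasta_path)
        contigs = {c: len(s) for c, s in annotation.sequences.items()}
        artifacts["filtered_vcf"] = var_mod.write_vcf(
            passing, out / "filtered.vcf", contigs)
        artifacts["removals"] = _write_tsv(
            pd.DataFrame([(r.chrom, r.pos, reason) for r, reason in removals],
                         columns=["chrom", "pos", "reason"]),
            out / "removals.tsv")
        snps = var_mod.VariantList((r for r in passing if r.is_snp),
                                   samples=passing.samples)
        indels = [r for r in passing if r.is_indel]
        snp_sum = var_mod.summarize_snps(snps)
        ind_sum = var_mod.summarize_indels(indels)
        cds_sum = var_mod.summarize_indels(indels, annotation, scope="CDS")
        artifacts["snp_summary"] = _write_tsv(pd.DataFrame([{
            "n_snps": len(snps),
            "n_transitions": snp_sum.n_transitions,
            "n_transversions": snp_sum.n_transversions,
            "ti_tv": snp_sum.ti_tv,
            "n_het": snp_sum.n_het, "n_hom": snp_sum.n_hom,
            "het_ratio_pct": snp_sum.het_ratio,
        }]), out / "snp_summary.tsv")
        artifacts["indel_summary"] = _write_tsv(pd.DataFrame([
            {"scope": s.scope, "n_insertions": s.n_insertions,
             "n_deletions": s.n_deletions, "n_het": s.n_het, "n_hom": s.n_hom,
             "length_spectrum": json.dumps(
                 {str(k): v for k, v in sorted(s.length_spectrum.items())})}
            for s in (ind_sum, cds_sum)
        ]), out / "indel_summary.tsv")
        artifacts["per_chromosome"] = _write_tsv(
            var_mod.per_chromosome_counts(passing), out / "per_chromosome.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'variants' failed on {vcf_path}: {exc}") from exc

    # stage 3: annotation ----------------------------------------------------
    try:
        calls = [ann_mod.annotate_variant(r, annotation) for r in passing]
        artifacts["effects"] = _write_tsv(pd.DataFrame(
            [(c.chrom, c.pos, c.ref, c.alt, c.region, c.cds_effect or "",
              c.gene_id or "", c.transcript_id or "") for c in calls],
            columns=["chrom", "pos", "ref", "alt", "region", "cds_effect",
                     "gene_id", "transcript_id"]), out / "effects.tsv")
        snp_calls = [c for c, r in zip(calls, passing) if r.is_snp]
        indel_calls = [c for c, r in zip(calls, passing) if r.is_indel]
        artifacts["snp_effect_table"] = _write_tsv(
            ann_mod.effect_table(snp_calls), out / "snp_effect_table.tsv")
        artifacts["indel_effect_table"] = _write_tsv(
            ann_mod.effect_table(indel_calls), out / "indel_effect_table.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'annotate' failed on {gff_path}: {exc}") from exc

    # stage 4: sweep scan ----------------------------------------------------
    try:
        scfg = sweep_mod.SweepConfig(**config.get("sweep", {}))
        samples = snps.samples
        unknown = [s for s in samples if s not in pops]
        if unknown:
            raise ValueError(f"samples with no population assignment: {unknown}")
        pop_names = sorted(set(pops.values()))
        pop_idx = {p: [i for i, s in enumerate(samples) if pops[s] == p]
                   for p in pop_names}
        by_chrom: dict[str, list[var_mod.VariantRecord]] = {}
        for r in snps:
            by_chrom.setdefault(r.chrom, []).append(r)
        comparisons = [tuple(c) for c in config.get(
            "comparisons",
            [list(p) for p in itertools.combinations(pop_names, 2)])]
        window_rows, region_rows, gene_rows = [], [], []
        gene_sets: dict[str, set[str]] = {}
        for pa, pb in comparisons:
            comp = f"{pa}_vs_{pb}"
            regions_all = []
            for chrom, recs in by_chrom.items():
                g = np.vstack([r.genotypes for r in recs]).T
                positions = np.array([r.pos for r in recs])
                stats = sweep_mod.scan(g, positions, chrom, contigs[chrom],
                                       pop_idx[pa], pop_idx[pb], scfg)
                for w in stats:
                    window_rows.append((comp, w.chrom, w.start, w.end,
                                        w.n_sites, w.pi_a, w.pi_b,
                                        w.fst if w.fst is not None else "",
                                        w.pi_ratio if w.pi_ratio is not None else "",
                                        int(w.eligible), int(w.selected)))
                regions_all.extend(sweep_mod.call_selected_regions(stats, scfg))
            regions_all, genes = sweep_mod.intersect_genes(regions_all, annotation)
            gene_sets[comp] = genes
            for reg in regions_all:
                direction_pop = pb if reg.direction == "B" else pa
                region_rows.append((comp, reg.chrom, reg.start, reg.end,
                                    direction_pop, reg.n_windows))
                for gid in reg.gene_ids:
                    gene_rows.append((comp, reg.chrom, reg.start, reg.end, gid))
        artifacts["windows"] = _write_tsv(pd.DataFrame(
            window_rows, columns=["comparison", "chrom", "start", "end",
                                  "n_sites", "pi_a", "pi_b", "fst", "pi_ratio",
                                  "eligible", "selected"]), out / "windows.tsv")
        with open(out / "regions.bed", "w") as fh:
            for comp, chrom, start, end, pop, nwin in region_rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{comp}|low_pi={pop}\t{nwin}\t.\n")
        artifacts["regions"] = out / "regions.bed"
        artifacts["region_genes"] = _write_tsv(pd.DataFrame(
            gene_rows, columns=["comparison", "chrom", "start", "end",
                                "gene_id"]), out / "region_genes.tsv")
        venn = {}
        if len(gene_sets) >= 2:
            venn = {" & ".join(k): v for k, v in
                    sweep_mod.venn_counts(gene_sets).items()}
        dedup = sorted(set().union(*gene_sets.values())) if gene_sets else []
        with open(out / "selected_genes.json", "w") as fh:
            json.dump({"per_comparison": {k: sorted(v) for k, v in gene_sets.items()},
                       "venn_exclusive_counts": venn,
                       "deduplicated_total": len(dedup)}, fh, indent=1)
        artifacts["selected_genes"] = out / "selected_genes.json"
    except Exception as exc:
        raise PipelineError(f"stage 'sweepscan' failed: {exc}") from exc

    # stage 5: population structure -----------------------------------------
    try:
        tcfg = config.get("structure", {})
        g_all = np.vstack([r.genotypes for r in snps]).T
        k = int(tcfg.get("n_components", 2))
        pca = struct_mod.genotype_pca(g_all, k=k)
        pca_df = pd.DataFrame(pca.coordinates,
                              columns=[f"PC{i + 1}" for i in range(k)])
        pca_df.insert(0, "pop", [pops[s] for s in samples])
        pca_df.insert(0, "sample", samples)
        artifacts["pca"] = _write_tsv(pca_df, out / "pca.tsv")
        np.savetxt(out / "eigenval.txt", pca.eigenvalues, fmt="%.6g")
        artifacts["eigenval"] = out / "eigenval.txt"
        tree = struct_mod.bootstrap_tree(
            g_all, samples, n_reps=int(tcfg.get("bootstrap", 100)),
            seed=seed + 2)
        artifacts["tree"] = struct_mod.write_newick(tree, out / "tree.nwk")
    except Exception as exc:
        raise PipelineError(f"stage 'structure' failed: {exc}") from exc

    # stage 6: expression ----------------------------------------------------
    try:
        if ct_path is not None:
            expr_cfg = config.get("expression", {})
            ct_table = pd.read_csv(ct_path, sep="\t")
            hk = tuple(expr_cfg.get("housekeeping", ("actb", "rn18s", "gapdh")))
            result = expr_mod.ddct(ct_table, hk,
                                   expr_cfg.get("calibrator"))
            artifacts["expression_rq"] = _write_tsv(result.per_sample,
                                                    out / "expression_rq.tsv")
            artifacts["expression_summary"] = _write_tsv(
                expr_mod.group_summary(result), out / "expression_summary.tsv")
    except Exception as exc:
        raise PipelineError(f"stage 'expression' failed on {ct_path}: {exc}") from exc

    manifest = {
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "artifacts": {name: {"path": str(p.relative_to(out)),
                             "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest


DEMO_CONFIG = {
    "simdata": {
        "n_chromosomes": 2,
        "chrom_length": 400_000,
        "samples_per_pop": 10,
        "drift_F": (0.02, 0.25, 0.03),
        "snp_density": 0.004,
        "indel_fraction": 0.37,
        "n_genes": 16,
        "sweep_intervals": [("chr1", 150_000, 250_000, "LP"),
                            ("chr2", 100_000, 200_000, "AP")],
    },
    "sweep": {"window_bp": 100_000, "step_bp": 10_000},
    "structure": {"bootstrap": 100, "n_components": 2},
    "expression": {"calibrator": "AP"},
}


def demo(out_dir: str | Path, seed: int = 7) -> dict:
    """Run the full pipeline on a small synthetic dataset (single CPU,
    well under five minutes); returns the manifest."""
    config = json.loads(json.dumps(DEMO_CONFIG))   # deep copy
    config["simdata"]["sweep_intervals"] = [
        tuple(x) for x in config["simdata"]["sweep_intervals"]]
    config["simdata"]["drift_F"] = tuple(config["simdata"]["drift_F"])
    config["seed"] = seed
    return run_pipeline(config, out_dir)
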