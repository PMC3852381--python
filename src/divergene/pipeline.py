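"""End-to-end orchestration of the synthetic-study pipeline.

``run_pipeline`` simulates a study (strain genomes with private SNPs,
RNA-seq counts, hybrid allele counts, growth curves, Ct tables), runs
every analysis stage in dependency order, writes each stage's outputs
as text tables under a run directory, and records a provenance
manifest (configuration hash, seed, package version) so a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

import divergene
from divergene import ase, expression, growth, io, molevo, qpcr, regulon, synthetic, variants

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "de", "regulon_test", "kaks", "ase", "growth", "qpcr")


@dataclass
class PipelineConfig:
    """Knobs of a full pipeline run.

    Statistical defaults: significance cutoff ``alpha`` 0.05 and
    ``n_perm`` 10,000 resampled gene groups, the settings of the
    analyses this pipeline reproduces; desk-scale runs may lower
    ``n_perm``.
    """

    outdir: str = "divergene_run"
    stages: Tuple[str, ...] = ALL_STAGES
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 10_000
    statistic_mode: str = "sign_sum"
    kaks_correction: str = "jc"
    growth_window_points: int = 5
    trend_blend: float = 0.5
    sim: synthetic.SimConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.statistic_mode not in regulon.MODES:
            raise ValueError(f"statistic_mode must be one of {regulon.MODES}")
        if self.kaks_correction not in ("jc", "raw"):
            raise ValueError("kaks_correction must be 'jc' or 'raw'")
        if self.sim is None:
            self.sim = synthetic.SimConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples of tuples -> lists for stable JSON
        return json.loads(json.dumps(d, default=str, sort_keys=True))


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the requested stages; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    manifest: Dict[str, object] = {
        "package": "divergene",
        "version": divergene.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "stages_run": [],
        "outputs": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages_run"].append(stage)
        manifest["outputs"][stage] = [p.name for p in paths]

    # --- simulate -----------------------------------------------------
    genomes = synthetic.simulate_strain_genomes(cfg)
    counts = synthetic.simulate_counts(cfg)
    if "simulate" in config.stages:
        written = []
        for strain, seqs in genomes.strain_sequences.items():
            p = out / f"strain_{strain}.fasta"
            io.write_fasta(p, seqs)
            written.append(p)
        p_anc = out / "ancestral.fasta"
        io.write_fasta(p_anc, genomes.ancestral)
        p_vcf = out / "snps.vcf"
        io.write_vcf(p_vcf, genomes.snps,
                     {g: len(s) for g, s in genomes.ancestral.items()})
        p_pop = out / "population_map.tsv"
        io.write_population_map(p_pop, genomes.population_map)
        p_counts = out / "counts.tsv"
        io.write_counts_tsv(p_counts, counts.counts)
        p_gmt = out / "regulons.gmt"
        io.write_gmt(p_gmt, cfg.gene_sets())
        p_truth = out / "truth.json"
        io.write_json(
            p_truth,
            {
                "snps": genomes.truth.to_dict(orient="records"),
                "planted_log2fc": cfg.planted_log2fc,
                "regulons": {n: sorted(m) for n, m in cfg.regulon_definitions},
            },
        )
        record("simulate", p_anc, p_vcf, p_pop, p_counts, p_gmt, p_truth, *written)

    # --- differential expression -------------------------------------
    popmap = genomes.population_map
    pops = list(popmap.populations)
    group_a = [s for s in counts.counts.columns if popmap.strain_to_population[s] == pops[0]]
    group_b = [s for s in counts.counts.columns if popmap.strain_to_population[s] == pops[1]]
    uq = expression.upper_quartile_factors(counts)
    scaled = counts.counts / uq
    scaled = scaled.round().astype(int)
    corrected = expression.gc_correct(scaled, counts.gene_gc).round().astype(int)
    de = expression.nb_test(corrected, group_a, group_b, trend_blend=config.trend_blend)
    if "de" in config.stages:
        p_de = out / "de_results.tsv"
        de.to_csv(p_de, sep="\t")
        record("de", p_de)

    # --- directional regulon screen -----------------------------------
    if "regulon_test" in config.stages:
        results = regulon.screen_gene_sets(
            de, cfg.gene_sets(), alpha=config.alpha, mode=config.statistic_mode,
            n_perm=config.n_perm, seed=config.seed,
        )
        table = regulon.results_table(results, pops[0], pops[1])
        p_reg = out / "directional_divergence.tsv"
        table.to_csv(p_reg, sep="\t", index=False)
        record("regulon_test", p_reg)

    # --- Ka/Ks --------------------------------------------------------
    if "kaks" in config.stages:
        labels = [variants.classify_private_fixed(s, popmap) for s in genomes.snps]
        by_pop_gene: Dict[Tuple[str, str], List[variants.SnpRecord]] = {}
        for lab in labels:
            if lab.status == "private_fixed":
                by_pop_gene.setdefault((lab.population, lab.snp.gene_id), []).append(lab.snp)
        summaries = []
        all_records = []
        rng = np.random.default_rng(config.seed)
        for pop in pops:
            records = [
                molevo.kaks_gene(genomes.ancestral[g], by_pop_gene.get((pop, g), []),
                                 pop, gene=g, correction=config.kaks_correction)
                for g in cfg.genes()
                if (pop, g) in by_pop_gene
            ]
            all_records.extend(records)
            focal = cfg.gene_sets()[-1] if cfg.gene_sets() else None
            if focal is not None and any(
                r.ratio is not None and r.gene in focal.members for r in records
            ):
                res = molevo.regulon_kaks_test(records, focal, n_perm=config.n_perm,
                                               seed=rng)
                summaries.append(
                    {"population": pop, "regulon": focal.id,
                     "regulon_mean": res.regulon_mean, "genome_mean": res.genome_mean,
                     "p_empirical": res.p_empirical,
                     "n_regulon_genes": res.n_regulon_genes,
                     "n_universe_genes": res.n_universe_genes}
                )
        p_kaks = out / "kaks_per_gene.tsv"
        molevo.kaks_table(all_records).to_csv(p_kaks, sep="\t", index=False)
        p_sum = out / "kaks_regulon_summary.tsv"
        pd.DataFrame(summaries).to_csv(p_sum, sep="\t", index=False)
        record("kaks", p_kaks, p_sum)

    # --- allele-specific expression -----------------------------------
    if "ase" in config.stages:
        allele_counts = synthetic.simulate_allele_counts(cfg)
        ase_res = ase.ase_test(allele_counts)
        screen = ase.ase_directional_screen(
            ase_res, cfg.gene_sets(), alpha=config.alpha,
            mode=config.statistic_mode, n_perm=config.n_perm, seed=config.seed,
        )
        p_tab = out / "allele_counts.tsv"
        allele_counts.to_csv(p_tab, sep="\t")
        p_res = out / "ase_results.tsv"
        ase_res.to_csv(p_res, sep="\t")
        p_scr = out / "ase_directional.tsv"
        regulon.results_table(screen, "parent1", "parent2").to_csv(
            p_scr, sep="\t", index=False
        )
        record("ase", p_tab, p_res, p_scr)

    # --- growth -------------------------------------------------------
    if "growth" in config.stages:
        table = synthetic.simulate_growth_curves(cfg)
        curves = synthetic.growth_curves_from_table(table)
        fits = [growth.fit_growth(c, window_points=config.growth_window_points)
                for c in curves]
        fit_rows = [
            {"strain": f.strain, "condition": f.condition, "replicate": f.replicate,
             "lag_min": f.lag_min, "max_rate_per_hr": f.max_rate_per_hr,
             "doubling_time_min": f.doubling_time_min, "efficiency": f.efficiency,
             "grew": f.grew}
            for f in fits
        ]
        strains_by_pop = {p: [s for s in cfg.strains()
                              if popmap.strain_to_population[s] == p] for p in pops}
        contrasts = []
        if len(pops) >= 2:
            a0, b0 = strains_by_pop[pops[0]][0], strains_by_pop[pops[1]][0]
            contrasts.append((f"{pops[0]}_vs_{pops[1]}", a0, b0))
        report = growth.hemizygote_report(fits, contrasts) if contrasts else pd.DataFrame()
        p_curves = out / "growth_curves.csv"
        table.to_csv(p_curves, index=False)
        p_fits = out / "growth_fits.tsv"
        pd.DataFrame(fit_rows).to_csv(p_fits, sep="\t", index=False)
        p_rep = out / "growth_comparisons.tsv"
        report.to_csv(p_rep, sep="\t", index=False)
        record("growth", p_curves, p_fits, p_rep)

    # --- qPCR ---------------------------------------------------------
    if "qpcr" in config.stages:
        ct = synthetic.simulate_ct_table(cfg)
        rel = qpcr.ddct(ct, "ACT1", pops[1] if len(pops) > 1 else pops[0])
        rel = qpcr.median_center_table(rel, by=["gene"])
        wilcox_rows = []
        genos = list(dict.fromkeys(rel["genotype"]))
        if len(genos) >= 2:
            mean_by = rel.groupby(["genotype", "gene"])["log2_value"].mean()
            for focal in cfg.gene_sets():
                p = qpcr.regulon_wilcoxon(mean_by.loc[genos[0]], mean_by.loc[genos[1]],
                                          focal)
                wilcox_rows.append({"regulon": focal.id,
                                    "genotype_a": genos[0], "genotype_b": genos[1],
                                    "p_value": p})
        p_ct = out / "ct_table.csv"
        ct.to_csv(p_ct, index=False)
        p_rel = out / "relative_expression.tsv"
        rel.to_csv(p_rel, sep="\t", index=False)
        p_wil = out / "qpcr_regulon_tests.tsv"
        pd.DataFrame(wilcox_rows).to_csv(p_wil, sep="\t", index=False)
        record("qpcr", p_ct, p_rel, p_wil)

    io.write_json(out / "manifest.json", manifest)
    return out
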