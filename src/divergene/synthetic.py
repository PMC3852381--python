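"""Synthetic study generator with known ground truth.

Emulates the data structures of a two-population yeast comparison so
every downstream stage of the pipeline can be exercised and validated
without sequencing data: homozygous strain panels carrying
population-private fixed coding SNPs at controlled nonsynonymous :
synonymous proportions, negative-binomial RNA-seq counts with coherent
log2-fold-change shifts planted in designated regulons, hybrid
allele-count tables, logistic growth curves with genotype x condition
effects, and qPCR Ct tables with gene- and genotype-level shifts.

Every generator records what it planted (the *truth*), so tests can
ask whether the analysis modules recover it exactly (SNP labels) or
statistically (fold changes, doubling-time ratios, power).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from divergene._rng import substream
from divergene.expression import CountMatrix
from divergene.growth import GrowthCurve
from divergene.regulon import GeneSet
from divergene.variants import PopulationMap, SnpRecord, translate_codon

__all__ = [
    "SimConfig",
    "GrowthParams",
    "SimulatedGenomes",
    "simulate_strain_genomes",
    "simulate_counts",
    "default_design",
    "simulate_allele_counts",
    "simulate_growth_curves",
    "simulate_ct_table",
]

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if translate_codon(a + b + c) != "*"
]


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth of one strain in one condition.

    ``rate_per_hr`` is the maximal specific growth rate (natural-log
    scale, per hour), so the log-phase doubling time in minutes is
    60 ln 2 / rate_per_hr.
    """

    carrying_capacity: float = 1.2
    rate_per_hr: float = 60.0 * math.log(2) / 90.0  # 90-min doubling
    lag_min: float = 120.0
    initial_od: float = 0.01

    def __post_init__(self) -> None:
        if self.carrying_capacity <= self.initial_od:
            raise ValueError("carrying capacity must exceed the initial OD")
        if self.rate_per_hr <= 0:
            raise ValueError("growth rate must be positive")
        if self.initial_od <= 0 or self.lag_min < 0:
            raise ValueError("initial OD must be > 0 and lag >= 0")

    @property
    def doubling_min(self) -> float:
        return 60.0 * math.log(2) / self.rate_per_hr


def _default_regulons(n_genes: int) -> List[Tuple[str, Tuple[str, ...]]]:
    """Three 20-gene regulons over the tail of the gene universe,
    mirroring the iron-metabolism gene groups of the study design."""
    if n_genes < 60:
        return []
    genes = [f"g{i:04d}" for i in range(n_genes)]
    return [
        ("iron_starvation_aft1", tuple(genes[-60:-40])),
        ("iron_ion_transport", tuple(genes[-40:-20])),
        ("iron_toxicity_response", tuple(genes[-20:])),
    ]


def _default_planted(regulons: Sequence[Tuple[str, Tuple[str, ...]]]) -> Dict[str, float]:
    planted = {}
    for name, _ in regulons:
        if name == "iron_toxicity_response":
            planted[name] = 1.0  # elevated in the first population
        elif name in ("iron_starvation_aft1", "iron_ion_transport"):
            planted[name] = -1.0  # repressed in the first population
        else:
            planted[name] = 0.0
    return planted


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the comparative design the pipeline targets: two
    populations of homozygous strains (3 vs 2 isolates), ~100-codon
    genes, population-private fixed coding SNPs at a 50:50
    nonsynonymous:synonymous proportion, NB counts (dispersion 0.05)
    with unit-magnitude log2 shifts planted in three 20-gene
    iron-metabolism-style regulons, triplicate logistic growth curves
    with a 1.7x doubling-time defect of the first population under the
    stress condition, and duplicate two-genotype Ct tables.
    """

    n_populations: int = 2
    strains_per_population: Tuple[int, ...] = (3, 2)
    population_labels: Tuple[str, ...] = ("Malaysian", "WineEuropean")
    n_genes: int = 200
    cds_length_codons: int = 100
    private_snps_per_population: int = 100
    fraction_nonsynonymous: float = 0.5
    fraction_nonsynonymous_by_regulon: Optional[Mapping[str, float]] = None
    regulon_definitions: Optional[List[Tuple[str, Tuple[str, ...]]]] = None
    planted_log2fc: Optional[Dict[str, float]] = None
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    baseline_log_sd: float = 1.0
    library_sizes: Optional[Mapping[str, float]] = None
    growth_params: Optional[Mapping[Tuple[str, str], GrowthParams]] = None
    growth_conditions: Tuple[str, ...] = ("SC", "SC+5mM FeSO4")
    growth_replicates: int = 3
    growth_noise_sd: float = 0.005
    growth_noise_model: str = "additive"  # or "proportional"
    growth_duration_min: float = 1440.0
    growth_interval_min: float = 30.0
    stress_doubling_factor: float = 1.7
    ct_effects: Optional[Mapping[Tuple[str, str], float]] = None
    ct_noise_sd: float = 0.1
    ct_bio_replicates: int = 2
    ct_tech_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if len(self.strains_per_population) != self.n_populations:
            raise ValueError("strains_per_population length must match n_populations")
        if any(n < 1 for n in self.strains_per_population):
            raise ValueError("every population needs at least one strain")
        if len(self.population_labels) != self.n_populations:
            raise ValueError("population_labels length must match n_populations")
        if self.n_genes < 1 or self.cds_length_codons < 1:
            raise ValueError("n_genes and cds_length_codons must be >= 1")
        if not 0.0 <= self.fraction_nonsynonymous <= 1.0:
            raise ValueError("fraction_nonsynonymous must lie in [0, 1]")
        if self.private_snps_per_population < 0:
            raise ValueError("private_snps_per_population must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        total_sites = self.n_genes * self.cds_length_codons * 3
        if self.private_snps_per_population * self.n_populations > total_sites:
            raise ValueError(
                f"requested {self.private_snps_per_population * self.n_populations} "
                f"private SNPs but only {total_sites} coding sites exist"
            )
        if self.regulon_definitions is None:
            self.regulon_definitions = _default_regulons(self.n_genes)
        universe = set(self.genes())
        for name, members in self.regulon_definitions:
            extra = set(members) - universe
            if extra:
                raise ValueError(f"regulon {name!r} has members outside the gene universe")
        if self.planted_log2fc is None:
            self.planted_log2fc = _default_planted(self.regulon_definitions)
        known = {name for name, _ in self.regulon_definitions}
        unknown = set(self.planted_log2fc) - known
        if unknown:
            raise ValueError(f"planted_log2fc refers to undefined regulons: {sorted(unknown)}")
        if self.library_sizes is not None and any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")
        if self.growth_noise_model not in ("additive", "proportional"):
            raise ValueError("growth_noise_model must be 'additive' or 'proportional'")
        if self.fraction_nonsynonymous_by_regulon:
            names = {name for name, _ in self.regulon_definitions}
            for reg, frac in self.fraction_nonsynonymous_by_regulon.items():
                if reg not in names:
                    raise ValueError(f"nonsynonymous-fraction override for undefined regulon {reg!r}")
                if not 0.0 <= frac <= 1.0:
                    raise ValueError("per-regulon nonsynonymous fractions must lie in [0, 1]")

    # -- derived vocabulary -------------------------------------------------
    def genes(self) -> List[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def strains(self) -> List[str]:
        out = []
        for pop, n in zip(self.population_labels, self.strains_per_population):
            out.extend(f"{pop}_{i + 1}" for i in range(n))
        return out

    def population_map(self) -> PopulationMap:
        mapping = {}
        for pop, n in zip(self.population_labels, self.strains_per_population):
            for i in range(n):
                mapping[f"{pop}_{i + 1}"] = pop
        return PopulationMap(mapping, tuple(self.population_labels))

    def gene_sets(self) -> List[GeneSet]:
        return [GeneSet(name, members) for name, members in self.regulon_definitions]

    def gene_log2fc(self) -> pd.Series:
        """Planted per-gene log2 fold change (first population / rest)."""
        lfc = pd.Series(0.0, index=self.genes())
        for name, members in self.regulon_definitions:
            shift = self.planted_log2fc.get(name, 0.0)
            if shift:
                lfc.loc[list(members)] = shift
        return lfc


# ---------------------------------------------------------------------------
# genomes and SNPs
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenomes:
    """Output of :func:`simulate_strain_genomes`.

    ``truth`` has one row per planted SNP: gene, pos (1-based), ref,
    alt, population (the SNP is private to and fixed in it) and effect
    (synonymous / nonsynonymous).
    """

    ancestral: Dict[str, str]
    strain_sequences: Dict[str, Dict[str, str]]
    snps: List[SnpRecord]
    truth: pd.DataFrame
    population_map: PopulationMap


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"] + list(rng.choice(_SENSE_CODONS, size=n_codons - 1))
    return "".join(codons)


def _substitution_effect(codon: str, offset: int, alt: str) -> str:
    mutant = codon[:offset] + alt + codon[offset + 1 :]
    aa_ref, aa_alt = translate_codon(codon), translate_codon(mutant)
    if aa_alt == "*":
        return "nonsense"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def simulate_strain_genomes(cfg: SimConfig) -> SimulatedGenomes:
    """Generate ancestral CDS and strain panels with planted private SNPs.

    Every planted SNP is fixed in exactly one population (all its
    strains carry the alternate allele) and absent elsewhere, never
    creates a stop codon, and is recorded with its truth labels.  The
    per-population counts of nonsynonymous sites planted equal
    ``round(private_snps_per_population * fraction_nonsynonymous)``.
    """
    rng = substream(cfg.seed, "genomes")
    genes = cfg.genes()
    ancestral = {g: _random_cds(rng, cfg.cds_length_codons) for g in genes}
    popmap = cfg.population_map()
    strains = cfg.strains()

    # zones: genes grouped by their nonsynonymous-fraction setting (a
    # background zone plus one zone per overridden regulon); the SNP
    # budget is split across zones proportionally to gene counts
    overrides = cfg.fraction_nonsynonymous_by_regulon or {}
    zones: List[Tuple[List[str], float]] = []
    zoned: set = set()
    for name, members in cfg.regulon_definitions or []:
        if name in overrides:
            zone_genes = [g for g in members if g not in zoned]
            zones.append((zone_genes, overrides[name]))
            zoned.update(zone_genes)
    background = [g for g in genes if g not in zoned]
    if background or not zones:
        zones.append((background or genes, cfg.fraction_nonsynonymous))

    n_per_pop = cfg.private_snps_per_population
    quotas = [round(n_per_pop * len(z) / len(genes)) for z, _ in zones]
    quotas[-1] = n_per_pop - sum(quotas[:-1])

    used_sites: set = set()
    snps: List[SnpRecord] = []
    truth_rows = []
    for pop in cfg.population_labels:
        for (zone_genes, frac), quota in zip(zones, quotas):
            n_nonsyn = round(quota * frac)
            need = {"nonsynonymous": n_nonsyn, "synonymous": quota - n_nonsyn}
            attempts = 0
            max_attempts = 1000 + 500 * max(quota, 1)
            while any(v > 0 for v in need.values()):
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError(
                        f"could not place the requested private SNPs for {pop}; "
                        "too few mutable sites for the requested composition"
                    )
                gene = zone_genes[rng.integers(len(zone_genes))]
                pos = int(rng.integers(len(ancestral[gene]))) + 1
                if (gene, pos) in used_sites:
                    continue
                ref = ancestral[gene][pos - 1]
                codon_start = 3 * ((pos - 1) // 3)
                codon = ancestral[gene][codon_start : codon_start + 3]
                offset = (pos - 1) % 3
                candidates = [
                    b
                    for b in _BASES
                    if b != ref and _substitution_effect(codon, offset, b) in need
                    and need[_substitution_effect(codon, offset, b)] > 0
                ]
                if not candidates:
                    continue
                alt = candidates[int(rng.integers(len(candidates)))]
                effect = _substitution_effect(codon, offset, alt)
                used_sites.add((gene, pos))
                need[effect] -= 1
                genotypes = {
                    s: ("alt" if popmap.strain_to_population[s] == pop else "ref")
                    for s in strains
                }
                snps.append(
                    SnpRecord(gene, pos, ref, alt, genotypes=genotypes, quality=99.0)
                )
                truth_rows.append(
                    {"gene": gene, "pos": pos, "ref": ref, "alt": alt,
                     "population": pop, "effect": effect}
                )

    strain_sequences: Dict[str, Dict[str, str]] = {}
    snps_by_pop_gene: Dict[Tuple[str, str], List[SnpRecord]] = {}
    for snp, row in zip(snps, truth_rows):
        snps_by_pop_gene.setdefault((row["population"], snp.gene_id), []).append(snp)
    from divergene.variants import apply_snps

    for s in strains:
        pop = popmap.strain_to_population[s]
        seqs = {}
        for g in genes:
            gene_snps = snps_by_pop_gene.get((pop, g), [])
            seqs[g] = apply_snps(ancestral[g], gene_snps) if gene_snps else ancestral[g]
        strain_sequences[s] = seqs

    truth = pd.DataFrame(
        truth_rows, columns=["gene", "pos", "ref", "alt", "population", "effect"]
    )
    if len(truth):
        truth = truth.sort_values(["gene", "pos"], ignore_index=True)
    return SimulatedGenomes(ancestral, strain_sequences, snps, truth, popmap)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def default_design(cfg: SimConfig) -> pd.DataFrame:
    """One RNA-seq library per strain, grouped by population."""
    popmap = cfg.population_map()
    rows = []
    for s in cfg.strains():
        size = 1.0 if cfg.library_sizes is None else cfg.library_sizes.get(s, 1.0)
        rows.append({"sample": s, "group": popmap.strain_to_population[s],
                     "library_size": size})
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))


def simulate_counts(
    cfg: SimConfig, design: Optional[pd.DataFrame] = None, stream: str = "counts"
) -> CountMatrix:
    """NB-distributed gene x sample counts with planted regulon shifts.

    Mean of gene g in sample j:
    ``baseline_g * library_size_j * 2^(planted_log2fc_g)`` when sample
    j belongs to the first population and g sits in a shifted regulon,
    ``baseline_g * library_size_j`` otherwise; variance follows
    mu + dispersion * mu^2.  GC content per gene is taken from the
    ancestral CDS when genomes are simulated separately, so here a
    uniform 0.25-0.65 draw stands in.
    """
    if design is None:
        design = default_design(cfg)
    if (design["library_size"] <= 0).any():
        raise ValueError("library sizes must be positive")
    rng = substream(cfg.seed, stream)
    genes = cfg.genes()
    baseline = cfg.baseline_mean * np.exp(
        rng.normal(0.0, cfg.baseline_log_sd, size=len(genes))
        - cfg.baseline_log_sd**2 / 2.0
    )
    lfc = cfg.gene_log2fc().to_numpy()
    first_pop = cfg.population_labels[0]
    cols = {}
    for _, row in design.iterrows():
        mu = baseline * float(row["library_size"])
        if row["group"] == first_pop:
            mu = mu * 2.0**lfc
        cols[row["sample"]] = _nb_draw(rng, mu, cfg.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    meta = design.set_index("sample")
    gc = pd.Series(rng.uniform(0.25, 0.65, size=len(genes)), index=counts.index)
    return CountMatrix(counts, sample_meta=meta, gene_gc=gc)


def simulate_allele_counts(
    cfg: SimConfig,
    n_hybrids: int = 3,
    planted_cis_log2fc: Optional[pd.Series] = None,
    mean_depth: float = 100.0,
) -> pd.DataFrame:
    """Per-gene parental allele counts for hybrid ASE analysis.

    Each hybrid contributes a parent1 and a parent2 library; a planted
    cis effect multiplies the parent1 allele's mean by 2^lfc.  Null by
    default (no cis effects), matching the study's finding of no
    coherent cis signal.
    """
    if n_hybrids < 1:
        raise ValueError("need at least one hybrid")
    rng = substream(cfg.seed, "ase")
    genes = cfg.genes()
    baseline = mean_depth * np.exp(
        rng.normal(0.0, cfg.baseline_log_sd, size=len(genes))
        - cfg.baseline_log_sd**2 / 2.0
    )
    lfc = (
        planted_cis_log2fc.reindex(genes).fillna(0.0).to_numpy()
        if planted_cis_log2fc is not None
        else np.zeros(len(genes))
    )
    data = {}
    for h in range(1, n_hybrids + 1):
        data[f"hybrid{h}__parent1"] = _nb_draw(rng, baseline * 2.0**lfc, cfg.nb_dispersion)
        data[f"hybrid{h}__parent2"] = _nb_draw(rng, baseline, cfg.nb_dispersion)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def logistic_od(t_min: np.ndarray, params: GrowthParams) -> np.ndarray:
    """Logistic OD(t) with a lag offset: flat at the initial OD until
    the lag ends, then K*N0*e^{rt'} / (K + N0*(e^{rt'} - 1))."""
    r = params.rate_per_hr / 60.0
    tt = np.maximum(np.asarray(t_min, dtype=float) - params.lag_min, 0.0)
    K, n0 = params.carrying_capacity, params.initial_od
    # equivalent to K*n0*e^{rt} / (K + n0*(e^{rt}-1)), stable for large t
    return K / (1.0 + (K - n0) / n0 * np.exp(-r * tt))


def default_growth_params(cfg: SimConfig) -> Dict[Tuple[str, str], GrowthParams]:
    """Per strain x condition logistic parameters.

    All strains share a 90-min doubling in the control condition; in
    the stress condition, strains of the first population double
    ``stress_doubling_factor`` times slower (and plateau lower).
    """
    base = GrowthParams()
    out = {}
    first_pop = cfg.population_labels[0]
    popmap = cfg.population_map()
    for s in cfg.strains():
        out[(s, cfg.growth_conditions[0])] = base
        if len(cfg.growth_conditions) > 1:
            if popmap.strain_to_population[s] == first_pop:
                out[(s, cfg.growth_conditions[1])] = GrowthParams(
                    carrying_capacity=0.96,
                    rate_per_hr=base.rate_per_hr / cfg.stress_doubling_factor,
                    lag_min=base.lag_min,
                )
            else:
                out[(s, cfg.growth_conditions[1])] = base
    return out


def simulate_growth_curves(cfg: SimConfig) -> pd.DataFrame:
    """Long-format growth-curve table (strain, condition, replicate,
    time_min, od600) from logistic curves plus truncated Gaussian
    plate-reader noise, sampled every ``growth_interval_min``.

    Noise is additive on OD by default (``growth_noise_sd`` in OD
    units); the ``proportional`` model scales the noise with the
    reading (``growth_noise_sd`` as a fraction).
    """
    params = cfg.growth_params or default_growth_params(cfg)
    rng = substream(cfg.seed, "growth")
    t = np.arange(0.0, cfg.growth_duration_min + 1e-9, cfg.growth_interval_min)
    rows = []
    for (strain, condition), p in params.items():
        for rep in range(1, cfg.growth_replicates + 1):
            od = logistic_od(t, p)
            if cfg.growth_noise_sd > 0:
                eps = rng.normal(0.0, cfg.growth_noise_sd, size=len(t))
                if cfg.growth_noise_model == "proportional":
                    od = np.maximum(od * (1.0 + eps), 0.0)
                else:
                    od = np.maximum(od + eps, 0.0)
            for ti, oi in zip(t, od):
                rows.append(
                    {"strain": strain, "condition": condition,
                     "replicate": f"r{rep}", "time_min": ti, "od600": oi}
                )
    return pd.DataFrame(rows)


def growth_curves_from_table(table: pd.DataFrame) -> List[GrowthCurve]:
    """Split a long-format growth table into GrowthCurve objects."""
    curves = []
    for (strain, cond, rep), grp in table.groupby(
        ["strain", "condition", "replicate"], sort=False
    ):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(strain, cond, rep,
                        grp["time_min"].to_numpy(), grp["od600"].to_numpy())
        )
    return curves


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def default_ct_effects(cfg: SimConfig) -> Dict[Tuple[str, str], float]:
    """Planted log2 expression shifts per (gene, genotype).

    The genes of the last defined regulon are shifted by its planted
    log2 fold change in the first population's genotype; the reference
    gene and the calibrator genotype carry no shift.
    """
    effects: Dict[Tuple[str, str], float] = {}
    first_pop = cfg.population_labels[0]
    for name, members in cfg.regulon_definitions or []:
        shift = (cfg.planted_log2fc or {}).get(name, 0.0)
        if shift:
            for g in members:
                effects[(g, first_pop)] = shift
    return effects


def simulate_ct_table(
    cfg: SimConfig,
    genes: Optional[Sequence[str]] = None,
    genotypes: Optional[Sequence[str]] = None,
    reference_gene: str = "ACT1",
) -> pd.DataFrame:
    """Long-format Ct table with planted genotype effects.

    Ct = per-gene baseline - planted log2 shift + Gaussian noise; the
    reference gene has no planted shift anywhere, so 2^-ddCt recovers
    the planted relative expression.  Columns: genotype, gene,
    replicate (biological), tech_rep, ct.
    """
    effects = cfg.ct_effects if cfg.ct_effects is not None else default_ct_effects(cfg)
    if genotypes is None:
        genotypes = list(cfg.population_labels)
    if genes is None:
        planted_genes = sorted({g for g, _ in effects})
        genes = planted_genes or cfg.genes()[: min(10, cfg.n_genes)]
    rng = substream(cfg.seed, "qpcr")
    baseline = {g: float(rng.normal(22.0, 1.5)) for g in genes}
    baseline[reference_gene] = 16.0
    rows = []
    for geno in genotypes:
        for rep in range(1, cfg.ct_bio_replicates + 1):
            for g in list(genes) + [reference_gene]:
                shift = 0.0 if g == reference_gene else effects.get((g, geno), 0.0)
                for tech in range(1, cfg.ct_tech_replicates + 1):
                    noise = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else 0.0
                    rows.append(
                        {"genotype": geno, "gene": g, "replicate": f"b{rep}",
                         "tech_rep": f"t{tech}", "ct": baseline[g] - shift + noise}
                    )
    return pd.DataFrame(rows)
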