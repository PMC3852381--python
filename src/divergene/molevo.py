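"""Ka/Ks from population-private fixed SNPs.

Site counting follows the counting (Nei-Gojobori style) approach: each
codon position contributes fractional synonymous/nonsynonymous site
counts equal to the fraction of its three possible single-nucleotide
substitutions that are synonymous/nonsynonymous (substitutions creating
a stop codon count as nonsynonymous), so N + S = 3 x codon count
exactly.  Proportions of observed substitutions per site are converted
to rates with the Jukes-Cantor correction d(p) = -(3/4) ln(1 - 4p/3);
a raw-proportion mode is available for sensitivity analysis.

The regulon-level enrichment test asks whether the mean Ka/Ks of a gene
set exceeds what random gene groups of the same size achieve, by a
one-sided (upper tail) resampling test over all genes with SNP data.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from divergene.regulon import GeneSet
from divergene.variants import SnpRecord, annotate_codon_effect, translate_codon

__all__ = [
    "KaKsRecord",
    "RegulonKaKsResult",
    "count_syn_nonsyn_sites",
    "kaks_gene",
    "kaks_table",
    "regulon_kaks_test",
    "jukes_cantor",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class KaKsRecord:
    """Per-gene Ka/Ks for SNPs private to and fixed in one population.

    ``ratio`` is None when Ks = 0 (undefined).
    """

    gene: str
    population: str
    n_nonsyn_snps: int
    n_syn_snps: int
    nonsyn_sites: float
    syn_sites: float
    ka: float
    ks: float
    ratio: Optional[float]


@dataclass(frozen=True)
class RegulonKaKsResult:
    population: str
    regulon_mean: float
    genome_mean: float
    p_empirical: float
    n_regulon_genes: int
    n_universe_genes: int
    n_excluded_undefined: int


@functools.lru_cache(maxsize=None)
def _codon_sites(codon: str) -> Tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon."""
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no defined site counts")
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if translate_codon(mutant) == aa:  # a stop is never equal to a sense aa
                syn += 1
    return 3.0 - syn / 3.0, syn / 3.0


def count_syn_nonsyn_sites(cds: str) -> Tuple[float, float]:
    """Nonsynonymous (N) and synonymous (S) site counts of a CDS.

    A trailing stop codon is permitted and excluded from the counts;
    an internal stop raises, naming the codon index (0-based).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    N = S = 0.0
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if translate_codon(codon) == "*":
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon at codon index {i}")
        n, s = _codon_sites(codon)
        N += n
        S += s
    return N, S


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d(p) = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("substitution proportion must be >= 0")
    if p >= 0.75:
        raise ValueError(
            f"substitution proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def kaks_gene(
    cds: str,
    private_snps: Sequence[SnpRecord],
    population: str,
    gene: Optional[str] = None,
    correction: str = "jc",
) -> KaKsRecord:
    """Ka, Ks and their ratio for one gene in one population.

    ``private_snps`` are the SNPs already classified as private to and
    fixed in ``population``; each is annotated against the reference
    CDS for its codon effect (nonsense substitutions are counted as
    nonsynonymous).  ``correction`` is ``"jc"`` (Jukes-Cantor, default)
    or ``"raw"`` (plain proportions).
    """
    if correction not in ("jc", "raw"):
        raise ValueError(f"unknown correction {correction!r}; expected 'jc' or 'raw'")
    N, S = count_syn_nonsyn_sites(cds)
    n_nonsyn = n_syn = 0
    for snp in private_snps:
        effect = annotate_codon_effect(cds, snp)
        if effect == "synonymous":
            n_syn += 1
        else:
            n_nonsyn += 1
    d = jukes_cantor if correction == "jc" else (lambda p: p)
    ka = d(n_nonsyn / N) if N > 0 else 0.0
    ks = d(n_syn / S) if S > 0 else 0.0
    ratio = ka / ks if ks > 0 else None
    if gene is None:
        gene = private_snps[0].gene_id if private_snps else ""
    return KaKsRecord(gene, population, n_nonsyn, n_syn, N, S, ka, ks, ratio)


def kaks_table(records: Iterable[KaKsRecord]) -> pd.DataFrame:
    """Records as a DataFrame (one row per gene x population)."""
    rows = [
        {
            "gene": r.gene,
            "population": r.population,
            "n_nonsyn_snps": r.n_nonsyn_snps,
            "n_syn_snps": r.n_syn_snps,
            "nonsyn_sites": r.nonsyn_sites,
            "syn_sites": r.syn_sites,
            "Ka": r.ka,
            "Ks": r.ks,
            "ratio": r.ratio,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def regulon_kaks_test(
    records: Sequence[KaKsRecord],
    regulon: GeneSet,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> RegulonKaKsResult:
    """One-sided resampling test for elevated mean Ka/Ks in a regulon.

    The universe is every gene in ``records`` with a defined ratio
    (Ks > 0); genes with undefined ratios are excluded from the means
    and the draw, and their number is reported.  The empirical p is
    ``(1 + #{null mean >= observed mean}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pops = {r.population for r in records}
    if len(pops) > 1:
        raise ValueError(f"records mix populations: {sorted(pops)}")
    population = next(iter(pops)) if pops else ""
    defined = {r.gene: r.ratio for r in records if r.ratio is not None}
    n_excluded = sum(1 for r in records if r.ratio is None)
    in_regulon = sorted(set(defined) & regulon.members)
    k = len(in_regulon)
    if k == 0:
        raise ValueError(
            f"regulon {regulon.id!r} has no gene with a defined Ka/Ks ratio"
        )
    ratios = np.array([defined[g] for g in defined], dtype=float)
    observed = float(np.mean([defined[g] for g in in_regulon]))
    genome_mean = float(ratios.mean())
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = rng.choice(ratios, size=k, replace=False).mean()
    # ties at the boundary count as "as extreme"; the tiny tolerance
    # keeps summation-order floating-point noise from breaking them
    p = (1.0 + np.count_nonzero(null >= observed - 1e-12)) / (n_perm + 1.0)
    return RegulonKaKsResult(
        population, observed, genome_mean, p, k, len(defined), n_excluded
    )
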