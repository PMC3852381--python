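"""SNP handling on coding sequences.

Applies called SNPs to reference CDS ("genome amendment"), classifies
each SNP by population privacy/fixation, and annotates its codon-level
effect under the standard nuclear genetic code.

Coordinates: user-facing positions (``SnpRecord.pos``, error messages,
TSV/VCF output) are 1-based within the CDS, matching VCF convention;
indexing into Python strings is 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from Bio.Data import CodonTable

__all__ = [
    "SnpRecord",
    "PopulationMap",
    "PrivacyLabel",
    "MISSING",
    "apply_snps",
    "classify_private_fixed",
    "annotate_codon_effect",
    "translate_codon",
]

_NUCLEOTIDES = frozenset("ACGT")

#: sentinel genotype for a missing call
MISSING = "."

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for a stop codon."""
    codon = codon.upper()
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP in CDS space with per-strain genotype calls.

    ``genotypes`` maps strain name to ``"ref"``, ``"alt"`` or
    :data:`MISSING`.
    """

    gene_id: str
    pos: int  # 1-based position within the CDS
    ref_allele: str
    alt_allele: str
    genotypes: Mapping[str, str] = field(default_factory=dict)
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.gene_id}: SNP position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele not in _NUCLEOTIDES:
                raise ValueError(
                    f"{self.gene_id} pos {self.pos}: {name} allele {allele!r} "
                    "is not a single A/C/G/T base (multi-allelic and indel "
                    "records are not supported)"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"{self.gene_id} pos {self.pos}: ref and alt alleles are identical"
            )
        for strain, call in self.genotypes.items():
            if call not in ("ref", "alt", MISSING):
                raise ValueError(
                    f"{self.gene_id} pos {self.pos}: strain {strain!r} has "
                    f"invalid genotype {call!r}"
                )


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of strains to populations.

    Every strain belongs to exactly one population; ``populations``
    fixes a stable ordering for output.
    """

    strain_to_population: Mapping[str, str]
    populations: Sequence[str]

    def __post_init__(self) -> None:
        pops = set(self.populations)
        if len(pops) != len(self.populations):
            raise ValueError("duplicate population labels")
        for strain, pop in self.strain_to_population.items():
            if pop not in pops:
                raise ValueError(
                    f"strain {strain!r} assigned to unlisted population {pop!r}"
                )

    def strains_of(self, population: str) -> List[str]:
        return [s for s, p in self.strain_to_population.items() if p == population]


@dataclass(frozen=True)
class PrivacyLabel:
    """Population privacy/fixation status of one SNP.

    ``status`` is one of ``private_fixed`` (with ``population`` naming
    the single population fixed for the alternate allele), ``shared``,
    ``polymorphic_within`` or ``uninformative``.
    """

    snp: SnpRecord
    status: str
    population: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("private_fixed", "shared", "polymorphic_within", "uninformative"):
            raise ValueError(f"unknown privacy status {self.status!r}")
        if (self.status == "private_fixed") != (self.population is not None):
            raise ValueError("private_fixed labels (and only those) name a population")


def apply_snps(reference_cds: str, snps: Iterable[SnpRecord]) -> str:
    """Amend a reference CDS with the alternate alleles of ``snps``.

    Every SNP's reference allele must match the sequence at its
    position, and positions must be unique; violations raise
    ``ValueError`` naming the gene and (1-based) position.
    """
    seq = list(reference_cds.upper())
    seen: Dict[int, SnpRecord] = {}
    for snp in snps:
        if snp.pos > len(seq):
            raise ValueError(
                f"{snp.gene_id}: SNP position {snp.pos} beyond CDS length {len(seq)}"
            )
        if snp.pos in seen:
            raise ValueError(
                f"{snp.gene_id}: duplicate SNP at position {snp.pos}"
            )
        seen[snp.pos] = snp
        found = seq[snp.pos - 1]
        if found != snp.ref_allele:
            raise ValueError(
                f"{snp.gene_id}: reference-allele mismatch at position {snp.pos}: "
                f"SNP claims ref {snp.ref_allele!r} but sequence has {found!r}"
            )
        seq[snp.pos - 1] = snp.alt_allele
    return "".join(seq)


def classify_private_fixed(snp: SnpRecord, popmap: PopulationMap) -> PrivacyLabel:
    """Classify a SNP as private and fixed to one population, or not.

    A SNP is ``private_fixed`` to population P when every non-missing
    strain of P carries the alternate allele and every non-missing
    strain of every other population carries the reference allele.
    Populations with only missing calls are skipped; if every
    population is fully missing the SNP is ``uninformative``.
    """
    calls_by_pop: Dict[str, List[str]] = {}
    for pop in popmap.populations:
        calls = [
            snp.genotypes.get(s, MISSING)
            for s in popmap.strains_of(pop)
        ]
        calls = [c for c in calls if c != MISSING]
        if calls:
            calls_by_pop[pop] = calls
    if not calls_by_pop:
        return PrivacyLabel(snp, "uninformative")
    if any(len(set(calls)) > 1 for calls in calls_by_pop.values()):
        return PrivacyLabel(snp, "polymorphic_within")
    alt_pops = [pop for pop, calls in calls_by_pop.items() if calls[0] == "alt"]
    if len(alt_pops) == 1 and len(calls_by_pop) > 1:
        return PrivacyLabel(snp, "private_fixed", alt_pops[0])
    if len(alt_pops) >= 1:
        return PrivacyLabel(snp, "shared")
    # alt allele seen nowhere: carries no population signal
    return PrivacyLabel(snp, "uninformative")


def annotate_codon_effect(cds: str, snp: SnpRecord) -> str:
    """Effect of substituting the alternate allele into its codon.

    Returns ``"synonymous"``, ``"nonsynonymous"`` or ``"nonsense"``
    (the substitution creates a stop codon).  All positions other than
    the SNP are taken from the reference.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"{snp.gene_id}: CDS length {len(cds)} not divisible by 3")
    if snp.pos > len(cds):
        raise ValueError(
            f"{snp.gene_id}: SNP position {snp.pos} beyond CDS length {len(cds)}"
        )
    idx = snp.pos - 1
    codon_start = 3 * (idx // 3)
    codon = cds[codon_start : codon_start + 3]
    if codon[idx % 3] != snp.ref_allele:
        raise ValueError(
            f"{snp.gene_id}: reference-allele mismatch at position {snp.pos}: "
            f"SNP claims ref {snp.ref_allele!r} but sequence has {codon[idx % 3]!r}"
        )
    mutant = codon[: idx % 3] + snp.alt_allele + codon[idx % 3 + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(mutant)
    if aa_alt == "*" and aa_ref != "*":
        return "nonsense"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"
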