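"""Allele-specific expression in interspecific hybrids.

Reads from a hybrid are assigned to parental alleles through the
diagnostic SNPs that distinguish the two parents' coding sequences: a
read informs allele-specific expression only if it covers at least one
diagnostic site and matches one parent's sequence exactly over its full
span (mirroring a no-mismatch unique-mapping rule against concatenated
parental genomes).  Per-allele counts across hybrids then feed the same
negative-binomial machinery used for between-population differential
expression, with hybrids as replicates, and regulon-level directional
screens reuse the resampling test on allelic log2 ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from divergene import expression, regulon as regulon_mod
from divergene.variants import SnpRecord

__all__ = [
    "AlignedReadStub",
    "assign_read_allele",
    "build_allele_counts",
    "ase_test",
    "ase_directional_screen",
]

ASSIGNMENTS = ("parent1", "parent2", "ambiguous", "discordant")


@dataclass(frozen=True)
class AlignedReadStub:
    """An error-free single-end read placed on one gene's CDS
    (``start`` is 1-based inclusive)."""

    gene_id: str
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("read start must be >= 1")
        if not self.sequence:
            raise ValueError("read sequence is empty")

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + len(self.sequence) - 1


def assign_read_allele(
    read: AlignedReadStub,
    parent1_cds: str,
    parent2_cds: str,
    diagnostic_snps: Sequence[SnpRecord],
) -> str:
    """Assign one read to a parental allele.

    Returns ``parent1``/``parent2`` when the read covers at least one
    diagnostic SNP and matches that parent exactly over its whole span,
    ``ambiguous`` when it covers no diagnostic site, and ``discordant``
    when it matches neither parent exactly (dropped downstream, like
    reads with mismatches).
    """
    if len(parent1_cds) != len(parent2_cds):
        raise ValueError("parental CDS lengths differ; sequences must be coordinate-consistent")
    if read.end > len(parent1_cds):
        raise ValueError(
            f"read on {read.gene_id} spans {read.start}-{read.end}, beyond CDS "
            f"length {len(parent1_cds)}"
        )
    covered = [
        s for s in diagnostic_snps
        if s.gene_id == read.gene_id and read.start <= s.pos <= read.end
    ]
    if not covered:
        return "ambiguous"
    lo = read.start - 1
    seq = read.sequence.upper()
    match1 = seq == parent1_cds[lo : lo + len(seq)].upper()
    match2 = seq == parent2_cds[lo : lo + len(seq)].upper()
    if match1 and not match2:
        return "parent1"
    if match2 and not match1:
        return "parent2"
    # parents differ at every covered diagnostic site, so matching both
    # is impossible; matching neither means an off-SNP mismatch
    return "discordant"


def build_allele_counts(
    reads_by_hybrid: Mapping[str, Iterable[AlignedReadStub]],
    parent1_seqs: Mapping[str, str],
    parent2_seqs: Mapping[str, str],
    diagnostic_snps: Sequence[SnpRecord],
) -> pd.DataFrame:
    """Tally per-gene parental-allele counts for each hybrid.

    Returns a gene-indexed DataFrame with two columns per hybrid,
    ``<hybrid>__parent1`` and ``<hybrid>__parent2``; only genes with at
    least one diagnostic SNP appear.  Ambiguous and discordant reads
    are counted internally but excluded from the table.
    """
    snps_by_gene: Dict[str, List[SnpRecord]] = {}
    for s in diagnostic_snps:
        snps_by_gene.setdefault(s.gene_id, []).append(s)
    genes = sorted(snps_by_gene)
    data = {}
    for hybrid, reads in reads_by_hybrid.items():
        c1 = {g: 0 for g in genes}
        c2 = {g: 0 for g in genes}
        for read in reads:
            g = read.gene_id
            if g not in snps_by_gene:
                continue
            call = assign_read_allele(
                read, parent1_seqs[g], parent2_seqs[g], snps_by_gene[g]
            )
            if call == "parent1":
                c1[g] += 1
            elif call == "parent2":
                c2[g] += 1
        data[f"{hybrid}__parent1"] = pd.Series(c1)
        data[f"{hybrid}__parent2"] = pd.Series(c2)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def _split_allele_columns(table: pd.DataFrame) -> Tuple[List[str], List[str]]:
    cols1 = [c for c in table.columns if c.endswith("__parent1")]
    cols2 = [c for c in table.columns if c.endswith("__parent2")]
    hybrids1 = {c[: -len("__parent1")] for c in cols1}
    hybrids2 = {c[: -len("__parent2")] for c in cols2}
    if hybrids1 != hybrids2:
        raise ValueError("allele count table has unpaired hybrid columns")
    return sorted(cols1), sorted(cols2)


def ase_test(table: pd.DataFrame) -> pd.DataFrame:
    """Allelic-imbalance test across hybrids (parent1 vs parent2).

    ``table`` is a :func:`build_allele_counts`-style frame; the two
    allele columns of each hybrid act as paired libraries and hybrids
    as replicates (>= 2 required).  Delegates to
    :func:`divergene.expression.nb_test`; log2 fold changes are
    oriented parent1 / parent2.
    """
    cols1, cols2 = _split_allele_columns(table)
    if len(cols1) < 2:
        raise ValueError(f"need >= 2 hybrids for the allelic test, got {len(cols1)}")
    return expression.nb_test(table, cols1, cols2)


def ase_directional_screen(
    ase_results: pd.DataFrame,
    gene_sets: Sequence[regulon_mod.GeneSet],
    alpha: float = 0.05,
    mode: str = "sign_sum",
    n_perm: int = 10_000,
    seed: int = 0,
) -> List[regulon_mod.DirectionalResult]:
    """Directional resampling screen on allelic log2 ratios.

    Identical to the between-population regulon screen, with per-gene
    allelic log2 ratios (cis effects) in place of population fold
    changes.
    """
    return regulon_mod.screen_gene_sets(
        ase_results, gene_sets, alpha=alpha, mode=mode, n_perm=n_perm, seed=seed
    )
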