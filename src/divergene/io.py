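"""Readers and writers for the pipeline's on-disk formats.

Sequences travel as FASTA (gene IDs as headers), SNPs as VCF 4.2 in
CDS space (CHROM = gene ID, POS = 1-based position within the CDS,
sample genotypes 0 = reference, 1 = alternate), gene sets as GMT, and
tabular data (counts, population maps, growth curves, Ct tables,
results) as UTF-8 tab- or comma-separated text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from divergene.regulon import GeneSet
from divergene.variants import MISSING, PopulationMap, SnpRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_gmt",
    "write_gmt",
    "read_population_map",
    "write_population_map",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_snp_tsv",
    "write_snp_tsv",
]


# -- FASTA ------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    """Gene ID -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- VCF (CDS space) --------------------------------------------------------

_GT_TO_CALL = {(0, 0): "ref", (1, 1): "alt", (None, None): MISSING,
               (0,): "ref", (1,): "alt", (None,): MISSING}


def write_vcf(
    path,
    snps: Sequence[SnpRecord],
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write SNPs as VCF 4.2 with homozygous diploid genotypes.

    CHROM is the gene ID; strains in the genotype maps become sample
    columns.  ``contig_lengths`` (gene -> CDS length) is optional but
    recommended so downstream VCF tooling sees proper contig headers.
    """
    strains: List[str] = []
    for snp in snps:
        for s in snp.genotypes:
            if s not in strains:
                strains.append(s)
    genes: List[str] = []
    for snp in snps:
        if snp.gene_id not in genes:
            genes.append(snp.gene_id)
    lines = ["##fileformat=VCFv4.2"]
    for g in genes:
        if contig_lengths and g in contig_lengths:
            lines.append(f"##contig=<ID={g},length={contig_lengths[g]}>")
        else:
            lines.append(f"##contig=<ID={g}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + strains
    lines.append("\t".join(header))
    code = {"ref": "0/0", "alt": "1/1", MISSING: "./."}
    for snp in sorted(snps, key=lambda s: (s.gene_id, s.pos)):
        qual = "." if snp.quality is None else f"{snp.quality:g}"
        row = [snp.gene_id, str(snp.pos), ".", snp.ref_allele, snp.alt_allele,
               qual, "PASS", ".", "GT"]
        row += [code[snp.genotypes.get(s, MISSING)] for s in strains]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vcf(path, min_quality: Optional[float] = None) -> List[SnpRecord]:
    """Parse a CDS-space VCF into SnpRecords.

    Multi-allelic records and non-SNP alleles raise; heterozygous
    genotypes are treated as missing (the strain panels analyzed are
    homozygous).  ``min_quality`` drops records below a genotype
    quality threshold (e.g. 99 to mirror a maximal-confidence filter).
    """
    snps: List[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: only biallelic SNP records are supported"
                )
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"{rec.chrom}:{rec.pos}: indel records are not supported")
            if min_quality is not None and (rec.qual is None or rec.qual < min_quality):
                continue
            genotypes = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                calls = set(a for a in (gt or ()) if a is not None)
                if not calls or (gt and None in gt):
                    genotypes[s] = MISSING
                elif calls == {0}:
                    genotypes[s] = "ref"
                elif calls == {1}:
                    genotypes[s] = "alt"
                else:
                    genotypes[s] = MISSING  # heterozygous or other allele
            snps.append(
                SnpRecord(rec.chrom, rec.pos, ref, alt, genotypes=genotypes,
                          quality=rec.qual)
            )
    return snps


# -- SNP TSV dialect --------------------------------------------------------


def write_snp_tsv(path, snps: Sequence[SnpRecord]) -> None:
    """TSV equivalent of the CDS-space VCF (gene, pos, ref, alt, then
    one column per strain with ref/alt/. calls)."""
    strains: List[str] = []
    for snp in snps:
        for s in snp.genotypes:
            if s not in strains:
                strains.append(s)
    rows = []
    for snp in snps:
        row = {"gene": snp.gene_id, "pos": snp.pos, "ref": snp.ref_allele,
               "alt": snp.alt_allele,
               "quality": "" if snp.quality is None else snp.quality}
        for s in strains:
            row[s] = snp.genotypes.get(s, MISSING)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_snp_tsv(path) -> List[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["gene", "pos", "ref", "alt", "quality"]
    missing = [c for c in fixed[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"SNP TSV missing columns: {missing}")
    strains = [c for c in df.columns if c not in fixed]
    snps = []
    for _, row in df.iterrows():
        qual = row.get("quality")
        quality = float(qual) if isinstance(qual, str) and qual else None
        genotypes = {s: (row[s] if row[s] in ("ref", "alt") else MISSING) for s in strains}
        snps.append(
            SnpRecord(row["gene"], int(row["pos"]), row["ref"], row["alt"],
                      genotypes=genotypes, quality=quality)
        )
    return snps


# -- GMT --------------------------------------------------------------------


def read_gmt(path) -> List[GeneSet]:
    sets = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT lines need id, annotation and >= 1 gene")
        sets.append(GeneSet(fields[0], fields[2:], annotation=fields[1]))
    return sets


def write_gmt(path, gene_sets: Iterable[GeneSet]) -> None:
    lines = [
        "\t".join([gs.id, gs.annotation] + sorted(gs.members)) for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- population map ---------------------------------------------------------


def read_population_map(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["strain", "population"]:
        raise ValueError("population map needs 'strain' and 'population' columns")
    populations = list(dict.fromkeys(df["population"]))
    return PopulationMap(dict(zip(df["strain"], df["population"])), populations)


def write_population_map(path, popmap: PopulationMap) -> None:
    rows = [{"strain": s, "population": p} for s, p in popmap.strain_to_population.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- counts -----------------------------------------------------------------


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes-as-rows count matrix (first column = gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_counts_tsv(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t")


# -- JSON helpers -----------------------------------------------------------


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
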