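"""Allele assignment, allele-count tables, and the allelic imbalance test."""

import numpy as np
import pandas as pd
import pytest

from divergene import ase, synthetic
from divergene.ase import AlignedReadStub, assign_read_allele, build_allele_counts
from divergene.regulon import GeneSet
from divergene.variants import SnpRecord, apply_snps

P1 = "ATGTTTGGTCTTAAAGAT"
SNPS = [SnpRecord("g", 6, "T", "C"), SnpRecord("g", 13, "A", "G")]
P2 = apply_snps(P1, SNPS)


class TestAssignReadAllele:
    def test_read_matching_parent1_at_diagnostic_site(self):
        read = AlignedReadStub("g", 4, P1[3:9])
        assert assign_read_allele(read, P1, P2, SNPS) == "parent1"

    def test_read_matching_parent2_at_diagnostic_site(self):
        read = AlignedReadStub("g", 4, P2[3:9])
        assert assign_read_allele(read, P1, P2, SNPS) == "parent2"

    def test_read_covering_no_diagnostic_snp_is_ambiguous(self):
        read = AlignedReadStub("g", 7, P1[6:12])  # sites 7-12, SNPs at 6 and 13
        assert assign_read_allele(read, P1, P2, SNPS) == "ambiguous"

    def test_read_with_off_snp_mismatch_is_discordant(self):
        seq = list(P1[3:9])
        seq[0] = "C" if seq[0] != "C" else "G"  # non-SNP mismatch to both parents
        read = AlignedReadStub("g", 4, "".join(seq))
        assert assign_read_allele(read, P1, P2, SNPS) == "discordant"

    def test_read_outside_gene_bounds_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            assign_read_allele(AlignedReadStub("g", 16, "AAAA"), P1, P2, SNPS)

    def test_conflicting_diagnostic_sites_discordant(self):
        # covers both SNPs: first base from parent1, second from parent2
        chim = list(P1[5:13])
        chim[-1] = P2[12]
        read = AlignedReadStub("g", 6, "".join(chim))
        assert assign_read_allele(read, P1, P2, SNPS) == "discordant"

    def test_label_symmetry_under_parent_swap(self):
        for start, length in [(1, 8), (4, 6), (7, 6), (10, 9)]:
            read = AlignedReadStub("g", start, P1[start - 1 : start - 1 + length])
            a = assign_read_allele(read, P1, P2, SNPS)
            b = assign_read_allele(read, P2, P1, SNPS)
            swap = {"parent1": "parent2", "parent2": "parent1",
                    "ambiguous": "ambiguous", "discordant": "discordant"}
            assert b == swap[a]

    def test_equivalence_with_exact_matching_against_both_parents(self):
        """The SNP-overlap rule equals unique exact-match assignment
        against the two parental sequences, for every possible read."""
        L = 6
        for start in range(1, len(P1) - L + 2):
            for source in (P1, P2):
                read = AlignedReadStub("g", start, source[start - 1 : start - 1 + L])
                got = assign_read_allele(read, P1, P2, SNPS)
                m1 = read.sequence == P1[start - 1 : start - 1 + L]
                m2 = read.sequence == P2[start - 1 : start - 1 + L]
                if m1 and m2:
                    assert got == "ambiguous"
                elif m1:
                    assert got == "parent1"
                elif m2:
                    assert got == "parent2"
                else:
                    assert got == "discordant"


class TestBuildAlleleCounts:
    def test_counts_and_conservation(self):
        rng = np.random.default_rng(0)
        reads = []
        n1 = n2 = 0
        for _ in range(60):
            start = int(rng.integers(1, len(P1) - 5))
            src = rng.random() < 0.5
            seq = (P1 if src else P2)[start - 1 : start + 5]
            reads.append(AlignedReadStub("g", start, seq))
        table = build_allele_counts({"h1": reads}, {"g": P1}, {"g": P2}, SNPS)
        assigned = table.loc["g", "h1__parent1"] + table.loc["g", "h1__parent2"]
        calls = [ase.assign_read_allele(r, P1, P2, SNPS) for r in reads]
        assert assigned == sum(c in ("parent1", "parent2") for c in calls)
        assert len(calls) == assigned + sum(c in ("ambiguous", "discordant") for c in calls)

    def test_only_genes_with_diagnostic_snps_appear(self):
        table = build_allele_counts({"h1": []}, {"g": P1}, {"g": P2}, SNPS)
        assert list(table.index) == ["g"]


class TestAseTest:
    def test_single_hybrid_rejected(self):
        cfg = synthetic.SimConfig(n_genes=60, seed=1)
        table = synthetic.simulate_allele_counts(cfg, n_hybrids=1)
        with pytest.raises(ValueError, match="2 hybrids"):
            ase.ase_test(table)

    def test_balanced_alleles_yield_null_results(self):
        cfg = synthetic.SimConfig(n_genes=300, nb_dispersion=0.005, seed=2,
                                  planted_log2fc={}, regulon_definitions=[])
        table = synthetic.simulate_allele_counts(cfg, n_hybrids=3,
                                                 mean_depth=1000.0)
        res = ase.ase_test(table)
        assert res["log2FoldChange"].abs().median() < 0.1
        assert (res["pvalue"] < 0.05).mean() < 0.12

    def test_planted_cis_effect_recovered(self):
        """Thirty genes with a 2-fold cis effect across 3 hybrids are
        mostly recovered at padj < 0.05 at dispersion 0.02."""
        cfg = synthetic.SimConfig(n_genes=300, nb_dispersion=0.02, seed=3,
                                  planted_log2fc={}, regulon_definitions=[])
        planted = pd.Series(1.0, index=[f"g{i:04d}" for i in range(30)])
        table = synthetic.simulate_allele_counts(cfg, n_hybrids=3,
                                                 planted_cis_log2fc=planted,
                                                 mean_depth=300.0)
        res = ase.ase_test(table)
        hits = (res.loc[planted.index, "padj"] < 0.05).mean()
        assert hits >= 0.8
        assert res.loc[planted.index, "log2FoldChange"].median() == pytest.approx(1.0, abs=0.3)

    def test_parent_swap_negates_log2fc(self):
        cfg = synthetic.SimConfig(n_genes=100, seed=4, planted_log2fc={},
                                  regulon_definitions=[])
        table = synthetic.simulate_allele_counts(cfg, n_hybrids=2)
        swapped = table.rename(
            columns=lambda c: c.replace("__parent1", "__tmp")
            .replace("__parent2", "__parent1")
            .replace("__tmp", "__parent2")
        )
        r1, r2 = ase.ase_test(table), ase.ase_test(swapped)
        ok = (r1["flag"] == "") & (r2["flag"] == "")
        assert np.allclose(
            r1.loc[ok, "log2FoldChange"], -r2.loc[ok, "log2FoldChange"]
        )


class TestAseDirectionalScreen:
    def test_empty_set_list(self):
        cfg = synthetic.SimConfig(n_genes=60, seed=5)
        res = ase.ase_test(synthetic.simulate_allele_counts(cfg))
        assert ase.ase_directional_screen(res, []) == []

    def test_planted_coherent_cis_shift_flagged_with_direction(self):
        cfg = synthetic.SimConfig(n_genes=200, nb_dispersion=0.02, seed=6,
                                  planted_log2fc={}, regulon_definitions=[])
        members = tuple(f"g{i:04d}" for i in range(25))
        # coherent cis-shift in the regulon, plus incoherent cis effects
        # elsewhere so the significant-gene null has directional contrast
        rng = np.random.default_rng(1)
        planted = pd.Series(-1.5, index=list(members))
        others = [f"g{i:04d}" for i in range(25, 85)]
        planted = pd.concat([planted, pd.Series(rng.choice([-1.5, 1.5], len(others)), index=others)])
        table = synthetic.simulate_allele_counts(cfg, n_hybrids=3,
                                                 planted_cis_log2fc=planted)
        res = ase.ase_test(table)
        screen = ase.ase_directional_screen(res, [GeneSet("cis_down", members)],
                                            n_perm=1000, seed=0)
        assert screen[0].direction == "up_in_b"
        assert screen[0].p_adjusted < 0.05
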