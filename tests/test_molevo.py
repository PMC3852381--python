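"""Ka/Ks site counting, per-gene rates, and the regulon enrichment test."""

import itertools

import numpy as np
import pytest

from divergene import molevo, synthetic
from divergene.molevo import KaKsRecord, count_syn_nonsyn_sites, jukes_cantor, kaks_gene
from divergene.regulon import GeneSet
from divergene.variants import SnpRecord, translate_codon

_BASES = "ACGT"
SENSE_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if translate_codon(a + b + c) != "*"
]


def brute_force_sites(codon):
    """Classify all 9 single-nucleotide mutants of a codon."""
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if translate_codon(mut) == translate_codon(codon):
                syn += 1
    return 3 - syn / 3, syn / 3


class TestSiteCounting:
    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_every_sense_codon_matches_enumeration(self, codon):
        assert count_syn_nonsyn_sites(codon) == pytest.approx(brute_force_sites(codon))

    def test_known_values(self):
        assert count_syn_nonsyn_sites("TTT") == pytest.approx((8 / 3, 1 / 3))
        assert count_syn_nonsyn_sites("TGG") == pytest.approx((3.0, 0.0))

    def test_additivity_over_codons(self):
        n1, s1 = count_syn_nonsyn_sites("TTT")
        n2, s2 = count_syn_nonsyn_sites("TGG")
        assert count_syn_nonsyn_sites("TTTTGG") == pytest.approx((n1 + n2, s1 + s2))

    def test_total_sites_is_three_per_codon(self):
        rng = np.random.default_rng(0)
        cds = "".join(rng.choice(SENSE_CODONS, 40))
        N, S = count_syn_nonsyn_sites(cds)
        assert N + S == pytest.approx(3 * 40, abs=1e-9)

    def test_internal_stop_names_codon(self):
        with pytest.raises(ValueError, match="codon index 1"):
            count_syn_nonsyn_sites("ATGTAAAAA")

    def test_trailing_stop_allowed(self):
        N, S = count_syn_nonsyn_sites("ATGTAA")
        assert N + S == pytest.approx(3.0)


class TestKaksGene:
    def test_no_snps_gives_zero_rates_undefined_ratio(self):
        rec = kaks_gene("ATGTTTGGG", [], "P", gene="g")
        assert rec.ka == 0.0 and rec.ks == 0.0 and rec.ratio is None

    def test_hand_computation_two_nonsyn_one_syn(self):
        cds = "".join(["ATG", "TTT", "GGT", "CTT", "AAA", "GAT"])
        N, S = count_syn_nonsyn_sites(cds)
        snps = [
            SnpRecord("g", 4, "T", "A"),   # TTT->ATT nonsyn
            SnpRecord("g", 7, "G", "A"),   # GGT->AGT nonsyn
            SnpRecord("g", 12, "T", "C"),  # CTT->CTC syn
        ]
        rec = kaks_gene(cds, snps, "P", gene="g")
        ka_hand = -0.75 * np.log(1 - 4 * (2 / N) / 3)
        ks_hand = -0.75 * np.log(1 - 4 * (1 / S) / 3)
        assert rec.n_nonsyn_snps == 2 and rec.n_syn_snps == 1
        assert rec.ka == pytest.approx(ka_hand)
        assert rec.ks == pytest.approx(ks_hand)
        assert rec.ratio == pytest.approx(ka_hand / ks_hand)

    def test_raw_mode_skips_correction(self):
        cds = "ATGTTTGGTCTTAAAGAT"
        snps = [SnpRecord("g", 4, "T", "A")]
        rec = kaks_gene(cds, snps, "P", gene="g", correction="raw")
        N, _ = count_syn_nonsyn_sites(cds)
        assert rec.ka == pytest.approx(1 / N)

    def test_monotone_in_snp_count(self):
        cds = "".join(["ATG"] + ["TTT"] * 20)
        one = kaks_gene(cds, [SnpRecord("g", 4, "T", "A")], "P", gene="g")
        two = kaks_gene(
            cds, [SnpRecord("g", 4, "T", "A"), SnpRecord("g", 7, "T", "A")], "P", gene="g"
        )
        assert two.ka > one.ka

    def test_jc_rejects_saturated_proportion(self):
        with pytest.raises(ValueError, match="3/4"):
            jukes_cantor(0.8)

    def test_planted_nonsyn_fraction_recovered_genomewide(self):
        """Mean Ka/Ks across genes tracks the value implied by the
        planted 0.75 nonsynonymous proportion at the simulated sites."""
        cfg = synthetic.SimConfig(
            n_genes=60, cds_length_codons=100, private_snps_per_population=300,
            fraction_nonsynonymous=0.75, strains_per_population=(3, 3), seed=31,
        )
        g = synthetic.simulate_strain_genomes(cfg)
        pop = cfg.population_labels[0]
        truth = g.truth
        ratios = []
        expected = []
        for gene in cfg.genes():
            sub = truth[(truth.gene == gene) & (truth.population == pop)]
            if not len(sub):
                continue
            gene_snps = [s for s in g.snps
                         if s.gene_id == gene and s.genotypes[f"{pop}_1"] == "alt"]
            rec = kaks_gene(g.ancestral[gene], gene_snps, pop, gene=gene)
            if rec.ratio is not None:
                ratios.append(rec.ratio)
                N, S = rec.nonsyn_sites, rec.syn_sites
                ka = jukes_cantor(rec.n_nonsyn_snps / N)
                ks = jukes_cantor(rec.n_syn_snps / S)
                expected.append(ka / ks)
        assert len(ratios) > 10
        assert np.mean(ratios) == pytest.approx(np.mean(expected), rel=1e-12)
        # 3:1 nonsyn:syn SNPs on ~1:3 nonsyn:syn site ratio implies
        # a mean ratio near 3 * S/N ~ 0.95-1.1 at these sequences
        assert 0.5 < np.mean(ratios) < 2.0


class TestRegulonKaksTest:
    def records(self, ratios):
        return [
            KaKsRecord(f"g{i}", "P", 1, 1, 200.0, 100.0, 0.01, 0.01, r)
            for i, r in enumerate(ratios)
        ]

    def test_regulon_equals_universe_p_one(self):
        recs = self.records([0.1, 0.2, 0.3])
        res = molevo.regulon_kaks_test(recs, GeneSet("r", ["g0", "g1", "g2"]), n_perm=99, seed=0)
        assert res.p_empirical == 1.0
        assert res.regulon_mean == pytest.approx(res.genome_mean)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        ratios = rng.uniform(0, 0.5, 8)
        recs = self.records(ratios)
        obs = ratios[:3].mean()
        null = [ratios[list(c)].mean() for c in itertools.combinations(range(8), 3)]
        p_exact = np.mean([m >= obs - 1e-12 for m in null])
        res = molevo.regulon_kaks_test(recs, GeneSet("r", ["g0", "g1", "g2"]),
                                       n_perm=100_000, seed=3)
        assert abs(res.p_empirical - p_exact) < 0.02

    def test_undefined_ratios_excluded_and_counted(self):
        recs = self.records([0.1, 0.2]) + [
            KaKsRecord("g9", "P", 1, 0, 200.0, 100.0, 0.01, 0.0, None)
        ]
        res = molevo.regulon_kaks_test(recs, GeneSet("r", ["g0"]), n_perm=99, seed=0)
        assert res.n_excluded_undefined == 1
        assert res.n_universe_genes == 2

    def test_mixed_population_records_rejected(self):
        recs = self.records([0.1]) + [
            KaKsRecord("g5", "Q", 1, 1, 200.0, 100.0, 0.01, 0.01, 0.2)
        ]
        with pytest.raises(ValueError, match="mix"):
            molevo.regulon_kaks_test(recs, GeneSet("r", ["g0"]), n_perm=9, seed=0)

    def test_elevated_regulon_detected(self):
        """A regulon with clearly elevated ratios earns a small upper-tail p."""
        rng = np.random.default_rng(4)
        ratios = list(rng.uniform(0.05, 0.2, 80)) + list(rng.uniform(0.5, 0.9, 10))
        recs = self.records(ratios)
        reg = GeneSet("hot", [f"g{i}" for i in range(80, 90)])
        res = molevo.regulon_kaks_test(recs, reg, n_perm=2000, seed=5)
        assert res.p_empirical < 0.01
        assert res.regulon_mean > res.genome_mean
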