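"""Substitution classes, spectra, gene-context annotation, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import passagemut as pm
from passagemut.genome import COMPLEMENT, GenomeModel, SyntheticReference
from passagemut.spectra import (
    LOCATION_CATEGORIES,
    Gene,
    GeneModel,
    annotate_location,
    genomic_footprints,
    random_gene_model,
    read_bed12,
    write_bed12,
)
from passagemut.sim import SUBSTITUTION_CLASSES


class TestSubstitutionClass:
    def test_pyrimidine_identity(self):
        assert pm.substitution_class("C", "A") == "C>A"

    def test_purine_complement_collapse(self):
        assert pm.substitution_class("G", "T") == "C>A"

    def test_all_twelve_pairs_map_two_per_class(self):
        counts = {}
        for ref, alt in itertools.permutations("ACGT", 2):
            counts.setdefault(pm.substitution_class(ref, alt), []).append((ref, alt))
        assert set(counts) == set(SUBSTITUTION_CLASSES)
        assert all(len(v) == 2 for v in counts.values())

    def test_reverse_complement_invariance(self):
        for ref, alt in itertools.permutations("ACGT", 2):
            assert pm.substitution_class(ref, alt) == pm.substitution_class(
                COMPLEMENT[ref], COMPLEMENT[alt]
            )

    @pytest.mark.parametrize("bad", [("N", "A"), ("C", "C"), ("CA", "C")])
    def test_invalid_input_raises(self, bad):
        with pytest.raises(ValueError):
            pm.substitution_class(*bad)


class TestSpectrumFractions:
    def test_small_enumeration(self):
        snvs = pd.DataFrame(
            {"passage": 1, "ref": list("CGAT"), "alt": list("ATGC")}
        )  # C>A, G>T(=C>A), A>G(=T>C), T>C
        frac = pm.spectrum_fractions(snvs)
        assert frac.loc[1, "C>A"] == 0.5
        assert frac.loc[1, "T>C"] == 0.5
        assert frac.loc[1].sum() == pytest.approx(1.0)

    def test_singleton(self):
        frac = pm.spectrum_fractions(pd.DataFrame({"passage": [9], "ref": ["G"], "alt": ["T"]}))
        assert frac.loc[9, "C>A"] == 1.0

    def test_missing_passage_warns(self):
        snvs = pd.DataFrame({"passage": [1], "ref": ["C"], "alt": ["A"]})
        with pytest.warns(UserWarning, match="passage 3"):
            frac = pm.spectrum_fractions(snvs, passages=[1, 3])
        assert list(frac.index) == [1]

    def test_rows_sum_to_one(self, default_run):
        spectrum = default_run["spectrum"]
        assert np.allclose(spectrum.sum(axis=1), 1.0)

    def test_late_spectrum_recovered_from_simulator(self, default_run):
        """C>A weight of the late process is recovered in the burst class."""
        matrix, labels = default_run["matrix"], default_run["labels"]
        keys = [k for k in matrix.maf.index if labels[k] == "P9" and matrix.is_snv(k)]
        snvs = pd.DataFrame(
            [{"passage": 9, "ref": matrix.variants[k].ref, "alt": matrix.variants[k].alt}
             for k in keys]
        )
        assert len(snvs) >= 300
        frac = pm.spectrum_fractions(snvs).loc[9, "C>A"]
        assert frac == pytest.approx(0.6, abs=0.05)


@pytest.fixture(scope="module")
def toy_annotation():
    """Hand-built two-gene model on a miniature genome with known codons."""
    genome = GenomeModel(n_chromosomes=1, chromosome_length=100_000, reference_seed=11)
    reference = SyntheticReference(genome)
    # plus-strand coding gene: exons [1000,1300) and [2000,2600); CDS 600 bp
    plus = Gene("plus", "chr1", "+", 1000, 3000,
                exons=((1000, 1300), (2000, 2600)),
                cds=((1100, 1300), (2000, 2400)))
    minus = Gene("minus", "chr1", "-", 10000, 12000,
                 exons=((10000, 10600), (11400, 12000)),
                 cds=((10150, 10600), (11400, 11949)))
    nc = Gene("lnc", "chr1", "+", 20000, 24000, exons=((20000, 24000),))
    model = GeneModel([plus, minus, nc])
    return genome, reference, model


class TestAnnotateLocation:
    def test_codon_categories_plus_strand(self, toy_annotation):
        genome, reference, model = toy_annotation
        gene = model.genes[0]
        # walk CDS and find one silent, one missense, one nonsense change
        from Bio.Seq import Seq

        seen = {}
        cds_seq = "".join(reference.fetch("chr1", s, e) for s, e in gene.cds)
        positions = [p for s, e in gene.cds for p in range(s, e)]
        for idx, pos0 in enumerate(positions):
            codon_i, off = divmod(idx, 3)
            codon = cds_seq[3 * codon_i: 3 * codon_i + 3]
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 2 - 1:] if off < 2 else codon[:2] + alt
                ref_aa = str(Seq(codon).translate())
                alt_aa = str(Seq(mutated).translate())
                expect = ("exonic-silent" if alt_aa == ref_aa
                          else "exonic-nonsense" if alt_aa == "*" else "exonic-missense")
                got = annotate_location("chr1", pos0 + 1, codon[off], alt, model, reference)
                assert got == expect
                seen.setdefault(expect, 0)
                seen[expect] += 1
            if len(seen) == 3 and min(seen.values()) >= 2:
                break
        assert set(seen) == {"exonic-silent", "exonic-missense", "exonic-nonsense"}

    def test_minus_strand_nonsense_detected(self, toy_annotation):
        """Strand-aware codon lookup: generated stop codons on the minus strand."""
        genome, reference, model = toy_annotation
        gene = model.genes[1]
        from passagemut.genome import revcomp
        from Bio.Seq import Seq

        cds_seq_g = "".join(reference.fetch("chr1", s, e) for s, e in gene.cds)
        positions = [p for s, e in gene.cds for p in range(s, e)]
        cds_seq = revcomp(cds_seq_g)
        found = 0
        for idx_g, pos0 in enumerate(positions):
            idx = len(cds_seq) - 1 - idx_g
            codon_i, off = divmod(idx, 3)
            codon = cds_seq[3 * codon_i: 3 * codon_i + 3]
            for alt_tx in "ACGT":
                if alt_tx == codon[off]:
                    continue
                mutated = codon[:off] + alt_tx + codon[off + 1:]
                if str(Seq(mutated).translate()) == "*" != str(Seq(codon).translate()):
                    got = annotate_location(
                        "chr1", pos0 + 1, COMPLEMENT[codon[off]], COMPLEMENT[alt_tx],
                        model, reference,
                    )
                    assert got == "exonic-nonsense"
                    found += 1
        assert found > 0

    def test_splice_intron_utr_tss_intergenic(self, toy_annotation):
        genome, reference, model = toy_annotation
        ref_at = lambda pos: reference.base("chr1", pos)

        def ann(pos, alt="A"):
            r = ref_at(pos)
            alt = "G" if r == "A" else "A"
            return annotate_location("chr1", pos, r, alt, model, reference,
                                     tss_window=1000, splice_window=2)

        assert ann(1302) == "splicing"  # 2 bp into the intron from exon 1 end
        assert ann(1999) == "splicing"  # 1 bp before exon 2 start
        assert ann(1500) == "intronic"
        assert ann(1050) == "UTR"  # exon 1 before CDS start
        assert ann(2550) == "UTR"  # exon 2 after CDS end
        assert ann(2700) == "intronic"  # inside span, after last exon block? -> intronic
        assert ann(500) == "TSS-proximal"  # upstream of plus-strand TSS
        assert ann(20500) == "TSS-proximal"  # inside the ncRNA but near its TSS
        assert ann(22500) == "ncRNA"
        assert ann(50000) == "intergenic"

    def test_off_genome_raises(self, toy_annotation):
        genome, reference, model = toy_annotation
        with pytest.raises(ValueError, match="off the genome"):
            annotate_location("chr9", 100, "C", "A", model, reference)

    def test_total_function_on_random_positions(self, toy_annotation):
        """Every position maps to exactly one category."""
        genome, reference, model = toy_annotation
        rng = np.random.default_rng(5)
        cats = set()
        for pos in rng.integers(1, genome.chromosome_length + 1, size=400):
            r = reference.base("chr1", int(pos))
            alt = "A" if r != "A" else "C"
            cat = annotate_location("chr1", int(pos), r, alt, model, reference)
            assert cat in LOCATION_CATEGORIES
            cats.add(cat)
        assert "intergenic" in cats


class TestGeneModelIO:
    def test_bed12_roundtrip(self, tmp_path):
        model = random_gene_model(GenomeModel(), n_genes=40, rng=3)
        path = tmp_path / "genes.bed"
        write_bed12(path, model)
        back = read_bed12(path)
        assert len(back) == len(model)
        for g1, g2 in zip(model.genes, back.genes):
            assert (g1.chrom, g1.tx_start, g1.tx_end, g1.strand) == (
                g2.chrom, g2.tx_start, g2.tx_end, g2.strand)
            assert g1.exons == g2.exons
            assert g1.cds == g2.cds

    def test_footprints_sum(self):
        genome = GenomeModel()
        model = random_gene_model(genome, n_genes=100, rng=4)
        foot = genomic_footprints(model, genome)
        assert foot["genic"] + foot["intergenic"] == pytest.approx(1.0)
        assert foot["exonic"] + foot["intronic"] == pytest.approx(foot["genic"])
        assert 0 < foot["intronic"] < foot["intergenic"]


class TestEnrichment:
    def test_null_case(self):
        res = pm.intronic_intergenic_enrichment(10, 10, 0.2, 0.2)
        assert res.ratio == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_threefold_enrichment_closed_form(self):
        res = pm.intronic_intergenic_enrichment(30, 10, 0.2, 0.2)
        assert res.ratio == pytest.approx(3.0)
        expect = stats.binomtest(30, 40, 0.5, alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(expect)

    def test_zero_footprint_raises(self):
        with pytest.raises(ValueError):
            pm.intronic_intergenic_enrichment(1, 1, 0.0, 0.2)

    def test_type_i_error_bounded_under_uniform_null(self):
        """Exact type-I error of the test at nominal 0.05 is <= 0.06.

        Computed by enumerating the binomial null (equivalent to the
        2000-replicate simulation, without its Monte-Carlo noise).
        """
        n, p0 = 40, 0.35
        reject_mass = 0.0
        for k in range(n + 1):
            pval = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
            if pval < 0.05:
                reject_mass += stats.binom.pmf(k, n, p0)
        assert reject_mass <= 0.06

    def test_uniform_placement_gives_unit_ratio(self):
        """Mutations placed uniformly: density ratio converges to 1."""
        genome = GenomeModel()
        model = random_gene_model(genome, n_genes=150, rng=9)
        reference = SyntheticReference(genome)
        foot = genomic_footprints(model, genome)
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(20):
            n_i = n_g = 0
            for chrom, pos in genome.random_sites(rng, 400):
                r = reference.base(chrom, pos)
                alt = "A" if r != "A" else "C"
                cat = annotate_location(chrom, pos, r, alt, model, reference)
                n_i += cat == "intronic"
                n_g += cat == "intergenic"
            res = pm.intronic_intergenic_enrichment(
                n_i, n_g, foot["intronic"], foot["intergenic"]
            )
            ratios.append(res.ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.12)
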