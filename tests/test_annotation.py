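"""Genic-context classification and synonymous/nonsynonymous calls."""

import numpy as np
import pytest
from Bio.Seq import Seq

from nilscan.annotation import (
    Context,
    GeneModel,
    classify_context,
    coding_effect,
    load_gene_models,
    primary_context,
)


def gene(gene_id="g1", chrom="chr1", strand="+", start=5000, end=8000,
         exons=((5000, 5999), (7000, 8000)), cds=None):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
        exons=tuple(exons), cds=tuple(cds if cds is not None else exons),
    )


class TestContext:
    def test_promoter_upstream_of_plus_strand_gene(self):
        hits = classify_context("chr1", 4500, [gene()])
        assert hits[0].context is Context.PROMOTER and hits[0].gene_id == "g1"

    def test_promoter_upstream_of_minus_strand_gene(self):
        g = gene(strand="-")
        assert classify_context("chr1", 8500, [g])[0].context is Context.PROMOTER
        # literal-coordinate mode keeps the promoter at the lower coordinate
        assert (
            classify_context("chr1", 4500, [g], strand_aware=False)[0].context
            is Context.PROMOTER
        )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (5500, Context.EXON),
            (6500, Context.INTRON),
            (4200, Context.PROMOTER),
            (3500, Context.INTERGENIC),
            (9500, Context.INTERGENIC),
        ],
    )
    def test_context_by_position(self, pos, expected):
        assert classify_context("chr1", pos, [gene()])[0].context is expected

    def test_out_of_bounds_position_rejected(self):
        with pytest.raises(ValueError):
            classify_context("chr1", 200_001, [gene()], chrom_length=200_000)

    def test_snp_in_two_genes_reports_both_with_exon_precedence(self):
        g1 = gene("g1", exons=((5000, 8000),))
        g3 = gene("g3", start=7400, end=7600, exons=((7400, 7450),))
        hits = classify_context("chr1", 7500, [g1, g3])
        contexts = {(h.gene_id, h.context) for h in hits}
        assert ("g1", Context.EXON) in contexts
        assert ("g3", Context.INTRON) in contexts
        assert primary_context(hits).context is Context.EXON

    def test_constructed_count_table_reproduces_exactly(self):
        """Promoter/exon/intron tallies on a fixture built to known counts."""
        rng = np.random.default_rng(13)
        genes = [
            gene(f"g{i}", start=s, end=s + 2999,
                 exons=((s, s + 999), (s + 2000, s + 2999)))
            for i, s in enumerate(range(10_000, 310_000, 6000))
        ]
        want = {"exon": 105, "intron": 42, "promoter": 30, "intergenic": 23}
        positions = {"exon": [], "intron": [], "promoter": [], "intergenic": []}
        for g in genes:
            positions["exon"].extend([g.start + 5, g.start + 500, g.start + 2500])
            positions["intron"].append(g.start + 1500)
            positions["promoter"].append(g.start - 500)
            positions["intergenic"].append(g.end + 1500)
        counts = dict.fromkeys(want, 0)
        for kind, want_n in want.items():
            chosen = positions[kind][:want_n]
            assert len(chosen) == want_n
            for pos in rng.permutation(chosen):
                top = primary_context(classify_context("chr1", int(pos), genes))
                counts[top.context.value] += 1
        # intergenic gaps are 2 kb (6 kb spacing - 3 kb gene - 1 kb promoter)
        assert counts["exon"] == want["exon"]
        assert counts["intron"] == want["intron"]
        assert counts["promoter"] == want["promoter"]
        assert counts["intergenic"] == want["intergenic"]


def make_reference(seq, chrom="chr1"):
    return {chrom: seq}


class TestCodingEffect:
    def test_synonymous_gaa_to_gag(self):
        # gene 1..6: codons GAA GAA; SNP at pos 3 A>G keeps Glu
        ref = make_reference("GAAGAA")
        g = gene(start=1, end=6, exons=((1, 6),))
        eff = coding_effect("chr1", 3, "A", "G", g, ref)
        assert (eff.ref_codon, eff.alt_codon) == ("GAA", "GAG")
        assert eff.effect == "SYNONYMOUS"

    def test_nonsynonymous_aaa_to_gaa(self):
        ref = make_reference("AAAGGG")
        g = gene(start=1, end=6, exons=((1, 6),))
        eff = coding_effect("chr1", 1, "A", "G", g, ref)
        assert (eff.ref_aa, eff.alt_aa) == ("K", "E")
        assert eff.effect == "NONSYNONYMOUS"

    def test_minus_strand_third_codon_base(self):
        # coding strand GAG (E); genome holds reverse complement CTC
        ref = make_reference("CTC")
        g = gene(strand="-", start=1, end=3, exons=((1, 3),))
        # genomic C>T at pos 1 is coding-strand G>A at codon base 3: GAG->GAA
        eff = coding_effect("chr1", 1, "C", "T", g, ref)
        assert (eff.ref_codon, eff.alt_codon) == ("GAG", "GAA")
        assert eff.effect == "SYNONYMOUS"

    def test_snp_outside_cds_rejected(self):
        ref = make_reference("A" * 100)
        g = gene(start=1, end=30, exons=((1, 30),))
        with pytest.raises(ValueError, match="not in the CDS"):
            coding_effect("chr1", 50, "A", "G", g, ref)

    def test_reference_mismatch_detected(self):
        ref = make_reference("GAAGAA")
        g = gene(start=1, end=6, exons=((1, 6),))
        with pytest.raises(ValueError, match="mismatch"):
            coding_effect("chr1", 2, "C", "G", g, ref)

    def test_strand_flip_invariance_on_random_toy_genes(self):
        """Reversing strand + reverse-complementing the chromosome preserves
        the synonymous/nonsynonymous class of every substitution."""
        rng = np.random.default_rng(14)
        bases = "ACGT"
        for _ in range(100):
            n_codons = int(rng.integers(4, 11))
            L = 3 * n_codons
            seq = "".join(bases[i] for i in rng.integers(0, 4, L))
            pos = int(rng.integers(1, L + 1))
            ref_b = seq[pos - 1]
            alt_b = bases[int(rng.integers(0, 4))]
            while alt_b == ref_b:
                alt_b = bases[int(rng.integers(0, 4))]
            g_plus = gene(start=1, end=L, exons=((1, L),))
            eff_plus = coding_effect("chr1", pos, ref_b, alt_b, g_plus,
                                     make_reference(seq))
            # mirrored chromosome: same gene read from the minus strand
            rc = str(Seq(seq).reverse_complement())
            comp = dict(zip("ACGT", "TGCA"))
            g_minus = gene(strand="-", start=1, end=L, exons=((1, L),))
            eff_minus = coding_effect(
                "chr1", L - pos + 1, comp[ref_b], comp[alt_b], g_minus,
                make_reference(rc),
            )
            assert eff_plus.effect == eff_minus.effect
            assert eff_plus.ref_codon == eff_minus.ref_codon

    def test_spliced_minus_strand_gene_translates_in_order(self):
        # minus-strand CDS over two exons; coding sequence is revcomp of
        # concatenated genomic exons
        genome = "TTACGGCTAAGGCCAGT"
        g = gene(strand="-", start=3, end=15, exons=((3, 8), (13, 15)))
        from nilscan.annotation import cds_sequence

        expected = str(Seq(genome[2:8] + genome[12:15]).reverse_complement())
        assert cds_sequence(g, make_reference(genome)) == expected


class TestGffLoading:
    def test_load_gene_models_from_gff3(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t400\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\tmRNA\t100\t400\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
            "chr1\tsrc\texon\t100\t199\t.\t+\t.\tID=e1;Parent=geneA.1\n"
            "chr1\tsrc\texon\t300\t400\t.\t+\t.\tID=e2;Parent=geneA.1\n"
            "chr1\tsrc\tCDS\t100\t199\t.\t+\t0\tID=c1;Parent=geneA.1\n"
            "chr1\tsrc\tCDS\t300\t400\t.\t+\t2\tID=c2;Parent=geneA.1\n"
        )
        models = load_gene_models(gff)
        assert len(models) == 1
        g = models[0]
        assert g.gene_id == "geneA" and g.strand == "+"
        assert g.exons == ((100, 199), (300, 400))
        assert g.cds_length == 201 and g.cds_ok

    def test_cds_not_multiple_of_three_flagged(self, tmp_path, caplog):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=geneB\n"
            "chr1\tsrc\tCDS\t100\t200\t.\t+\t0\tID=c;Parent=geneB\n"
        )
        with caplog.at_level("WARNING"):
            models = load_gene_models(gff)
        assert not models[0].cds_ok
        assert "divisible by 3" in caplog.text
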