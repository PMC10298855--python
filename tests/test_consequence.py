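"""Codon-level consequence classification against a translation oracle."""
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from cfsomatic.consequence_annotation import (CONSEQUENCE_TYPES, GeneModel,
                                              GeneMutationMatrix,
                                              NotClassifiableError,
                                              build_gene_matrix,
                                              classify_consequence,
                                              consequence_counts,
                                              is_nonsynonymous,
                                              read_gene_models,
                                              top_mutated_genes,
                                              write_gene_models)

from conftest import make_variant


def make_gene(cds_codons, chrom="chr1", start=11, strand="+", symbol="G1"):
    """Single-exon gene whose CDS is the given codon string; the reference
    embeds it (reverse-complemented for minus-strand genes) with padding."""
    cds = "".join(cds_codons)
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    seq = "T" * (start - 1) + genomic + "T" * 50
    model = GeneModel(symbol=symbol, chrom=chrom, strand=strand,
                      exons=[(start, start + len(cds) - 1)])
    return model, {chrom: seq}


class TestClassifySnv:
    def test_synonymous_identity(self):
        model, ref = make_gene(["ATG", "GAA", "TGA"])
        # GAA -> GAG (Glu -> Glu): third base of codon 2 (genomic pos 11+5)
        v = make_variant(pos=16, ref="A", alt="G")
        assert classify_consequence(v, model, ref) == "synonymous"

    def test_stop_gained(self):
        model, ref = make_gene(["ATG", "TAC", "TGA"])
        # TAC -> TAA: Tyr -> stop
        v = make_variant(pos=16, ref="C", alt="A")
        assert classify_consequence(v, model, ref) == "stop_gained"

    def test_missense(self):
        model, ref = make_gene(["ATG", "GAA", "TGA"])
        v = make_variant(pos=14, ref="G", alt="C")  # GAA -> CAA (Glu -> Gln)
        assert classify_consequence(v, model, ref) == "missense"

    def test_start_lost(self):
        model, ref = make_gene(["ATG", "GAA", "TGA"])
        v = make_variant(pos=11, ref="A", alt="G")
        assert classify_consequence(v, model, ref) == "start_lost"

    def test_stop_lost_and_retained(self):
        model, ref = make_gene(["ATG", "GAA", "TGA"])
        assert classify_consequence(make_variant(pos=18, ref="G", alt="A"),
                                    model, ref) == "stop_retained"  # TGA->TAA
        assert classify_consequence(make_variant(pos=18, ref="G", alt="C"),
                                    model, ref) == "stop_lost"      # TGA->TCA

    def test_indels_by_net_length(self):
        model, ref = make_gene(["ATG", "GAA", "AAA", "TGA"])
        assert classify_consequence(make_variant(pos=14, ref="GA", alt="G"),
                                    model, ref) == "frameshift"
        assert classify_consequence(make_variant(pos=14, ref="G", alt="GTTT"),
                                    model, ref) == "in_frame"

    def test_splice_site_margin(self):
        model = GeneModel("G1", "chr1", "+", exons=[(11, 40), (61, 90)])
        seq = {"chr1": "T" * 10 + "A" * 100}
        assert classify_consequence(make_variant(pos=41, ref="A", alt="C"),
                                    model, seq) == "splicing_site"
        assert classify_consequence(make_variant(pos=59, ref="A", alt="C"),
                                    model, seq) == "splicing_site"
        with pytest.raises(NotClassifiableError):
            classify_consequence(make_variant(pos=50, ref="A", alt="C"),
                                 model, seq)


def translation_oracle(v, model, reference):
    """Independent oracle: substitute into the full CDS, translate both
    haplotypes with Biopython, and derive the category from the proteins."""
    if len(v.ref) != len(v.alt):
        return "frameshift" if abs(len(v.ref) - len(v.alt)) % 3 else "in_frame"
    cds_ref = model.cds_sequence(reference)
    i = model.genomic_to_cds(v.pos)
    alt = v.alt if model.strand == "+" else str(Seq(v.alt).complement())
    cds_alt = cds_ref[:i] + alt + cds_ref[i + 1:]
    prot_ref = str(Seq(cds_ref).translate())
    prot_alt = str(Seq(cds_alt).translate())
    ci = i // 3
    if ci == 0 and cds_ref[:3] == "ATG" and cds_alt[:3] != "ATG":
        return "start_lost"
    aa_r, aa_a = prot_ref[ci], prot_alt[ci]
    if aa_r == "*" and aa_a == "*":
        return "stop_retained"
    if aa_r == "*":
        return "stop_lost"
    if aa_a == "*":
        return "stop_gained"
    return "synonymous" if prot_ref == prot_alt else "missense"


class TestAgainstOracle:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_500_random_coding_snvs(self, strand):
        rng = np.random.default_rng(12 if strand == "+" else 13)
        codons = ["ATG"] + ["".join(rng.choice(list("ACGT"), 3))
                            for _ in range(60)] + ["TGA"]
        model, ref = make_gene(codons, strand=strand)
        L = model.cds_length
        start = model.exons[0][0]
        for _ in range(500):
            pos = start + int(rng.integers(0, L))
            base = ref["chr1"][pos - 1]
            alt = "ACGT"[("ACGT".index(base) + int(rng.integers(1, 4))) % 4]
            v = make_variant(pos=pos, ref=base, alt=alt)
            assert classify_consequence(v, model, ref) == \
                translation_oracle(v, model, ref)

    def test_strand_symmetry(self):
        """A minus-strand gene and its plus-strand mirror classify every SNV
        identically."""
        rng = np.random.default_rng(3)
        codons = ["ATG"] + ["".join(rng.choice(list("ACGT"), 3))
                            for _ in range(30)] + ["TGA"]
        plus_model, plus_ref = make_gene(codons, strand="+")
        minus_model, minus_ref = make_gene(codons, strand="-")
        L = plus_model.cds_length
        start = plus_model.exons[0][0]
        for cds_i in rng.integers(0, L, size=100):
            cds_i = int(cds_i)
            # same CDS position on both strands
            p_pos = start + cds_i
            m_pos = start + (L - 1 - cds_i)
            p_base = plus_ref["chr1"][p_pos - 1]
            p_alt = "ACGT"[("ACGT".index(p_base) + 1) % 4]
            m_base = minus_ref["chr1"][m_pos - 1]
            m_alt = str(Seq(p_alt).complement())
            assert str(Seq(p_base).complement()) == m_base
            cp = classify_consequence(make_variant(pos=p_pos, ref=p_base,
                                                   alt=p_alt), plus_model, plus_ref)
            cm = classify_consequence(make_variant(pos=m_pos, ref=m_base,
                                                   alt=m_alt), minus_model, minus_ref)
            assert cp == cm


class TestNonsynonymousAndCounts:
    def test_protein_changing_categories(self):
        assert is_nonsynonymous("missense")
        assert is_nonsynonymous("stop_gained")
        assert not is_nonsynonymous("synonymous")
        assert not is_nonsynonymous("stop_retained")
        with pytest.raises(ValueError):
            is_nonsynonymous("intergenic")

    def test_per_type_counts_sum_to_classified(self, small_cohort, small_pipeline):
        classified = [v for v in small_pipeline.merged if v.consequence]
        counts = consequence_counts(small_pipeline.merged)
        assert counts.sum() == len(classified)
        assert set(counts.index) == set(CONSEQUENCE_TYPES)


class Annotated:
    def __init__(self, sample_id, gene, consequence):
        self.sample_id, self.gene, self.consequence = sample_id, gene, consequence


class TestGeneMatrix:
    def test_presence_not_count(self):
        vs = [Annotated("P1", "G1", "missense")] * 3
        m = build_gene_matrix(vs, ["P1", "P2"])
        assert m.presence.loc["P1", "G1"] and not m.presence.loc["P2", "G1"]
        assert m.counts["G1"] == 1

    def test_synonymous_excluded(self):
        vs = [Annotated("P1", "G1", "synonymous")]
        m = build_gene_matrix(vs, ["P1"])
        assert m.presence.empty or "G1" not in m.presence.columns

    def test_empty_variants_all_false(self):
        m = build_gene_matrix([], ["P1", "P2"])
        assert not m.presence.to_numpy().any()

    def test_top_genes_order_and_tiebreak(self):
        vs = [Annotated("P1", "BBB", "missense"), Annotated("P2", "BBB", "missense"),
              Annotated("P1", "AAA", "missense"), Annotated("P2", "AAA", "missense"),
              Annotated("P1", "CCC", "missense")]
        m = build_gene_matrix(vs, ["P1", "P2", "P3"])
        assert top_mutated_genes(m, 3) == ["AAA", "BBB", "CCC"]
        with pytest.raises(ValueError):
            top_mutated_genes(m, 0)

    def test_top_genes_match_sort_oracle(self, small_cohort, small_pipeline):
        patients = [c.patient_id for c in small_cohort.clinical]
        m = build_gene_matrix(small_pipeline.kept, patients)
        got = top_mutated_genes(m, 20)
        freq = m.frequency
        oracle = sorted(freq.index, key=lambda g: (-freq[g], g))[:20]
        assert got == oracle


def test_gene_model_tsv_roundtrip(tmp_path, small_cohort):
    p = tmp_path / "genes.tsv"
    write_gene_models(small_cohort.gene_models[:20], p)
    back = read_gene_models(p)
    for a, b in zip(small_cohort.gene_models[:20], back):
        assert (a.symbol, a.chrom, a.strand, a.exons) == \
               (b.symbol, b.chrom, b.strand, b.exons)
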