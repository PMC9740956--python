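"""Element classification and consequence annotation, checked against the
mutate-and-retranslate oracle and strand-symmetry."""

import numpy as np
import pytest

from mutcand.effects import (Consequence, DEFAULT_LARGE_EFFECT, Element,
                             ElementIndex, classify_consequence,
                             classify_element, large_effect_genes,
                             shared_gene_venn)
from mutcand.genome import TranscriptModel, revcomp
from mutcand.variants import VariantRecord
from mutcand.synthetic import plant_effect_variant

from _oracles import mirror_scenario, retranslate_category


def _snp_at(pos0, genome, chrom, alt=None):
    ref = genome[chrom][pos0]
    if alt is None:
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    return VariantRecord(chrom, pos0 + 1, ref, alt)


class TestClassifyElement:
    def test_cds_snp_is_exon(self, small_genome):
        genome, models = small_genome
        tx = models[0]
        a, b = tx.cds[0]
        per_gene, summary = classify_element(_snp_at(a, genome, tx.chrom), models)
        assert per_gene[tx.gene_id] is Element.exon
        assert summary is Element.exon

    def test_promoter_500bp_upstream_plus_strand(self, small_genome):
        genome, models = small_genome
        tx = next(t for t in models if t.strand == "+")
        pos = tx.start - 500
        per_gene, summary = classify_element(_snp_at(pos, genome, tx.chrom), models)
        assert per_gene.get(tx.gene_id) is Element.promoter

    def test_far_from_any_gene_is_intergenic(self, small_genome):
        genome, models = small_genome
        spans = [(t.start - 2000, t.end + 2000) for t in models]
        pos = next(p for p in range(0, genome.length("A01"), 137)
                   if not any(a <= p < b for a, b in spans))
        per_gene, summary = classify_element(_snp_at(pos, genome, "A01"), models)
        assert per_gene == {} and summary is Element.intergenic

    def test_beyond_chromosome_end_raises(self, small_genome):
        genome, models = small_genome
        rec = VariantRecord("A01", genome.length("A01") + 10, "A", "T")
        with pytest.raises(ValueError, match="beyond"):
            classify_element(rec, models, chrom_len=genome.length("A01"))

    def test_index_agrees_with_classify_element_everywhere(self, small_genome):
        """The painted per-base label map and the per-variant classifier are
        two routes to the same tiling; they must agree at every position."""
        genome, models = small_genome
        index = ElementIndex(genome, models)
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, genome.length("A01"), size=3000):
            _, summary = classify_element(_snp_at(int(pos), genome, "A01"), models)
            assert index.label("A01", int(pos)) is summary

    def test_element_classes_tile_the_genome(self, small_genome):
        genome, models = small_genome
        index = ElementIndex(genome, models)
        total = sum(len(v) for v in index.labels.values())
        assert total == genome.total_length  # every base has exactly one label


class TestClassifyConsequence:
    def test_cds_one_base_insertion_is_frameshift(self, small_genome):
        genome, models = small_genome
        tx = models[0]
        a, b = max(tx.cds, key=lambda iv: iv[1] - iv[0])
        pos0 = (a + b) // 2
        ref = genome[tx.chrom][pos0]
        rec = VariantRecord(tx.chrom, pos0 + 1, ref, ref + "A")
        assert classify_consequence(rec, tx, genome).consequence \
            is Consequence.frameshift

    def test_three_base_cds_insertion_in_frame(self, small_genome):
        genome, models = small_genome
        tx = models[0]
        a, b = max(tx.cds, key=lambda iv: iv[1] - iv[0])
        pos0 = a + 7
        ref = genome[tx.chrom][pos0]
        rec = VariantRecord(tx.chrom, pos0 + 1, ref, ref + "AAA")
        call = classify_consequence(rec, tx, genome)
        assert call.consequence in (Consequence.none, Consequence.start_lost)

    def test_first_intron_base_is_splice_donor(self, small_genome):
        genome, models = small_genome
        tx = next(t for t in models if t.strand == "+")
        a, b = tx.introns[0]
        rec = _snp_at(a, genome, tx.chrom)  # the G of GT
        assert genome[tx.chrom][a] == "G"
        assert classify_consequence(rec, tx, genome).consequence \
            is Consequence.splice_donor

    def test_last_intron_bases_are_splice_acceptor_minus_strand(self, small_genome):
        genome, models = small_genome
        tx = next(t for t in models if t.strand == "-")
        # transcription-order acceptor on '-' is the genomic start of the gap
        (a, b) = tx.introns[-1]
        rec = _snp_at(a, genome, tx.chrom)
        assert classify_consequence(rec, tx, genome).consequence \
            is Consequence.splice_acceptor

    @pytest.mark.parametrize("category", ["missense", "synonymous", "stop_gained",
                                          "start_lost", "stop_lost"])
    def test_engineered_snps_match_retranslation_oracle(self, small_genome, category):
        genome, models = small_genome
        rng = np.random.default_rng(7)
        for tx in models[:4]:
            chrom, pos, ref, alt = plant_effect_variant(tx, genome, category, rng)
            rec = VariantRecord(chrom, pos, ref, alt)
            got = classify_consequence(rec, tx, genome).consequence.name
            want = retranslate_category(genome, tx, pos - 1, ref, alt)
            assert got == category == want

    def test_random_cds_snps_match_oracle(self, small_genome):
        genome, models = small_genome
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(1000):
            tx = models[int(rng.integers(0, len(models)))]
            a, b = tx.cds[int(rng.integers(0, len(tx.cds)))]
            pos0 = int(rng.integers(a, b))
            ref = genome[tx.chrom][pos0]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            rec = VariantRecord(tx.chrom, pos0 + 1, ref, alt)
            got = classify_consequence(rec, tx, genome).consequence.name
            want = retranslate_category(genome, tx, pos0, ref, alt)
            assert got == want, (rec.key, tx.gene_id, tx.strand)
            checked += 1
        assert checked > 700

    def test_strand_symmetry(self, small_genome):
        """Reverse-complementing the genome and flipping strands leaves every
        SNP consequence call unchanged."""
        genome, models = small_genome
        g2, models2 = mirror_scenario(genome, models)
        rng = np.random.default_rng(13)
        for _ in range(300):
            tx = models[int(rng.integers(0, len(models)))]
            tx2 = next(t for t in models2 if t.tx_id == tx.tx_id)
            pos0 = int(rng.integers(tx.start, tx.end))
            ref = genome[tx.chrom][pos0]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            c1 = classify_consequence(
                VariantRecord(tx.chrom, pos0 + 1, ref, alt), tx, genome)
            L = genome.length(tx.chrom)
            c2 = classify_consequence(
                VariantRecord(tx.chrom, L - pos0, revcomp(ref), revcomp(alt)),
                tx2, g2)
            assert c1.consequence is c2.consequence
            assert c1.element is c2.element


class TestGeneAggregation:
    def test_large_effect_split_by_variant_class(self, trio_private):
        genome, models, priv, truth = trio_private
        from mutcand.effects import annotate_variants
        for m in ("mut1", "mut2"):
            calls = annotate_variants(priv[m], models, genome)
            got = large_effect_genes(calls, DEFAULT_LARGE_EFFECT)
            planted = {g for g, cat in truth.planted_large_effect_genes[m].items()
                       if cat in {c.name for c in DEFAULT_LARGE_EFFECT}}
            assert got["ALL"] == planted
            # the single planted frameshift is the only indel-derived gene
            fs = {g for g, cat in truth.planted_large_effect_genes[m].items()
                  if cat == "frameshift"}
            assert got["INDEL"] == fs

    def test_only_synonymous_yields_empty(self):
        assert large_effect_genes([]) == {"SNP": set(), "INDEL": set(),
                                          "ALL": set()}

    def test_venn_counts(self):
        assert shared_gene_venn({"a", "b", "c"}, {"b", "c", "d"}) == (1, 1, 2)
        assert shared_gene_venn({"x"}, {"x"}) == (0, 0, 1)
        assert shared_gene_venn(set(), {"x"}) == (0, 1, 0)
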