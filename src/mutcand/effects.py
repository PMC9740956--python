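"""Genomic element classification and variant consequence annotation.

Every position falls in exactly one summary element class — coding exon,
5' UTR, 3' UTR, intron, promoter, terminator or intergenic — chosen with the
precedence exon > utr5 > utr3 > intron > promoter > terminator > intergenic
when transcripts or flanks overlap. Consequences (splice-site disruption,
start loss, stop gain/loss, frameshift, missense, synonymous) are called per
transcript, strand-aware, against the annotated reading frame.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .genome import Genome, START_CODON, STOP_CODONS, TranscriptModel, revcomp, translate
from .variants import VariantRecord

DEFAULT_PROMOTER_BP = 2000
DEFAULT_TERMINATOR_BP = 2000


class Element(enum.IntEnum):
    """Summary element classes, ordered by ascending precedence."""

    intergenic = 0
    terminator = 1
    promoter = 2
    intron = 3
    utr3 = 4
    utr5 = 5
    exon = 6  # coding exon (CDS)


class Consequence(enum.IntEnum):
    """Functional consequence categories, ordered by ascending severity."""

    none = 0
    synonymous = 1
    missense = 2
    frameshift = 3
    stop_lost = 4
    stop_gained = 5
    start_lost = 6
    splice_donor = 7
    splice_acceptor = 8


#: categories counted as large-effect by default: splice disruption, start
#: loss, stop gain/loss (the prose definition) plus frameshift.
DEFAULT_LARGE_EFFECT = frozenset({
    Consequence.splice_acceptor,
    Consequence.splice_donor,
    Consequence.start_lost,
    Consequence.stop_gained,
    Consequence.stop_lost,
    Consequence.frameshift,
})

#: the integration stage additionally admits missense so that candidates with
#: an "amino acid change" qualify.
INTEGRATION_LARGE_EFFECT = DEFAULT_LARGE_EFFECT | {Consequence.missense}


@dataclass(frozen=True)
class EffectCall:
    variant_key: tuple[str, int, str, str]
    gene_id: str
    tx_id: str
    element: Element
    consequence: Consequence
    junction_spanning: bool = False

    def is_large_effect(self, categories: frozenset = DEFAULT_LARGE_EFFECT) -> bool:
        return self.consequence in categories


def element_for_transcript(pos: int, tx: TranscriptModel,
                           promoter_bp: int = DEFAULT_PROMOTER_BP,
                           terminator_bp: int = DEFAULT_TERMINATOR_BP) -> Element | None:
    """Element of a 0-based position relative to one transcript, or None when
    the position is outside the transcript and both flanks."""
    if tx.contains(pos):
        for a, b in tx.cds:
            if a <= pos < b:
                return Element.exon
        for a, b in tx.utr5:
            if a <= pos < b:
                return Element.utr5
        for a, b in tx.utr3:
            if a <= pos < b:
                return Element.utr3
        return Element.intron
    a, b = tx.promoter(promoter_bp)
    if a <= pos < b:
        return Element.promoter
    a, b = tx.terminator(terminator_bp)
    if a <= pos < b:
        return Element.terminator
    return None


class ElementIndex:
    """Per-base element labels for fast batch classification.

    The label array is painted in ascending precedence order so that, for any
    position, the single summary label equals the highest-precedence element
    over all overlapping transcripts and flanks. Memory is one byte per base,
    fine for the megabase-scale genomes this pipeline targets.
    """

    def __init__(self, genome: Genome, models: list[TranscriptModel],
                 promoter_bp: int = DEFAULT_PROMOTER_BP,
                 terminator_bp: int = DEFAULT_TERMINATOR_BP):
        self.promoter_bp = promoter_bp
        self.terminator_bp = terminator_bp
        self.labels: dict[str, np.ndarray] = {
            c: np.zeros(genome.length(c), dtype=np.uint8) for c in genome.chroms
        }
        by_chrom: dict[str, list[TranscriptModel]] = {}
        for tx in models:
            by_chrom.setdefault(tx.chrom, []).append(tx)
        for chrom, arr in self.labels.items():
            txs = by_chrom.get(chrom, [])
            n = len(arr)

            def paint(intervals, label):
                for a, b in intervals:
                    arr[max(0, a):min(n, b)] = np.maximum(
                        arr[max(0, a):min(n, b)], np.uint8(label))

            # ascending precedence; np.maximum keeps the stronger label
            paint([tx.terminator(terminator_bp) for tx in txs], Element.terminator)
            paint([tx.promoter(promoter_bp) for tx in txs], Element.promoter)
            for tx in txs:
                paint([(tx.start, tx.end)], Element.intron)
            paint([iv for tx in txs for iv in tx.utr3], Element.utr3)
            paint([iv for tx in txs for iv in tx.utr5], Element.utr5)
            paint([iv for tx in txs for iv in tx.cds], Element.exon)

    def label(self, chrom: str, pos: int) -> Element:
        arr = self.labels[chrom]
        if pos < 0 or pos >= len(arr):
            raise ValueError(f"position {pos} beyond end of {chrom} ({len(arr)} bp)")
        return Element(int(arr[pos]))

    def labels_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.labels[chrom][positions]


def classify_element(variant: VariantRecord, models: list[TranscriptModel],
                     promoter_bp: int = DEFAULT_PROMOTER_BP,
                     terminator_bp: int = DEFAULT_TERMINATOR_BP,
                     chrom_len: int | None = None,
                     ) -> tuple[dict[str, Element], Element]:
    """Per-gene element assignments plus the single summary label.

    Indels are classified by their anchored start position. Returns
    ({gene_id: element}, summary); the summary is the highest-precedence
    element over all overlapping transcripts, or intergenic.
    """
    pos = variant.pos0
    if pos < 0 or (chrom_len is not None and pos >= chrom_len):
        raise ValueError(f"variant at {variant.chrom}:{variant.pos} beyond chromosome end")
    per_gene: dict[str, Element] = {}
    for tx in models:
        if tx.chrom != variant.chrom:
            continue
        el = element_for_transcript(pos, tx, promoter_bp, terminator_bp)
        if el is None:
            continue
        if tx.gene_id not in per_gene or el > per_gene[tx.gene_id]:
            per_gene[tx.gene_id] = el
    summary = max(per_gene.values(), default=Element.intergenic)
    return per_gene, summary


def _splice_hit(pos: int, tx: TranscriptModel) -> Consequence | None:
    for (a, b), kind in tx.splice_sites():
        if a <= pos < b:
            return Consequence[kind]
    return None


def _snp_consequence(variant: VariantRecord, tx: TranscriptModel,
                     genome: Genome) -> Consequence:
    pos = variant.pos0
    hit = _splice_hit(pos, tx)
    if hit is not None:
        return hit
    ci = tx.coding_index(pos)
    if ci is None:
        return Consequence.none
    cds = tx.coding_sequence(genome)
    if len(cds) % 3:
        raise ValueError(f"CDS of {tx.tx_id} not divisible by 3")
    alt_base = variant.alt if tx.strand == "+" else revcomp(variant.alt)
    codon_i, off = divmod(ci, 3)
    codon = cds[codon_i * 3: codon_i * 3 + 3]
    new_codon = codon[:off] + alt_base + codon[off + 1:]
    last = len(cds) // 3 - 1
    if codon_i == 0:
        return Consequence.start_lost if new_codon != START_CODON else Consequence.synonymous
    if codon_i == last and codon in STOP_CODONS:
        # stop retained (e.g. TAA->TAG) counts as synonymous
        return Consequence.synonymous if new_codon in STOP_CODONS else Consequence.stop_lost
    if new_codon in STOP_CODONS:
        return Consequence.stop_gained
    if translate(new_codon) != translate(codon):
        return Consequence.missense
    return Consequence.synonymous


def _indel_consequence(variant: VariantRecord, tx: TranscriptModel) -> tuple[Consequence, bool]:
    """Consequence for a normalized (anchored) indel and a flag marking indels
    whose span crosses an exon boundary (classified by anchored start)."""
    # first changed base: base after the anchor for both insertions and deletions
    eff = variant.pos0 + 1
    span_end = variant.pos0 + max(len(variant.ref), 2)  # at least the base after anchor
    hit = _splice_hit(eff, tx)
    if hit is not None:
        return hit, False
    delta = len(variant.alt) - len(variant.ref)
    in_cds = tx.coding_index(eff) is not None
    if not in_cds:
        return Consequence.none, False
    crosses = tx.coding_index(span_end - 1) is None
    if delta % 3 != 0:
        return Consequence.frameshift, crosses
    # in-frame: flag only start/stop disruption
    cds_len = tx.cds_len
    touched = range(variant.pos0 + 1, variant.pos0 + len(variant.ref))
    indices = [tx.coding_index(p) for p in touched]
    indices = [i for i in indices if i is not None]
    if any(i < 3 for i in indices):
        return Consequence.start_lost, crosses
    if any(i >= cds_len - 3 for i in indices):
        return Consequence.stop_lost, crosses
    if delta > 0:  # pure in-frame insertion inside start/stop codon
        ci = tx.coding_index(eff)
        if ci is not None and 0 < ci < 3:
            return Consequence.start_lost, crosses
        if ci is not None and cds_len - 3 < ci < cds_len:
            return Consequence.stop_lost, crosses
    return Consequence.none, crosses


def classify_consequence(variant: VariantRecord, tx: TranscriptModel,
                         genome: Genome) -> EffectCall:
    """Deterministic consequence call for one normalized variant against one
    transcript; strand-aware (alleles are reverse-complemented on '-')."""
    if variant.is_snp:
        cons = _snp_consequence(variant, tx, genome)
        crosses = False
    else:
        cons, crosses = _indel_consequence(variant, tx)
    el = element_for_transcript(variant.pos0, tx) or Element.intergenic
    return EffectCall(variant.key, tx.gene_id, tx.tx_id, el, cons,
                      junction_spanning=crosses)


def annotate_variants(variants, models: list[TranscriptModel], genome: Genome,
                      ) -> list[EffectCall]:
    """EffectCalls for every variant x overlapping transcript (flanks included
    for element context, but consequences only arise inside the transcript)."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tx in models:
        by_chrom.setdefault(tx.chrom, []).append(tx)
    calls: list[EffectCall] = []
    for rec in variants:
        for tx in by_chrom.get(rec.chrom, []):
            if tx.start - DEFAULT_PROMOTER_BP <= rec.pos0 < tx.end + DEFAULT_TERMINATOR_BP:
                calls.append(classify_consequence(rec, tx, genome))
    return calls


def large_effect_genes(effects: list[EffectCall],
                       categories: frozenset = DEFAULT_LARGE_EFFECT,
                       ) -> dict[str, set[str]]:
    """Gene ids carrying at least one large-effect call, split into SNP-derived
    and indel-derived sets (keys 'SNP', 'INDEL', 'ALL')."""
    snp_genes, indel_genes = set(), set()
    for call in effects:
        if call.consequence not in categories:
            continue
        _, _, ref, alt = call.variant_key
        if len(ref) == 1 and len(alt) == 1:
            snp_genes.add(call.gene_id)
        else:
            indel_genes.add(call.gene_id)
    return {"SNP": snp_genes, "INDEL": indel_genes, "ALL": snp_genes | indel_genes}


def shared_gene_venn(s1: set[str], s2: set[str]) -> tuple[int, int, int]:
    """(only-in-first, only-in-second, shared) counts — the two-set Venn."""
    shared = s1 & s2
    return len(s1 - shared), len(s2 - shared), len(shared)
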