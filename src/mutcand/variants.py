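"""Variant records, GATK-style hard filtering, normalization and set algebra.

The private ("mutagen-induced") variants of a mutant line are those whose
(chrom, pos, ref, alt) key survives hard filtering in the mutant call set but
is absent from the wild-type call set against the same reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .genome import Genome

# Metric -> (violating comparison, bound). A record fails when ANY present
# metric violates its bound; bounds themselves are strict inequalities, so a
# value exactly at the bound passes.
HARD_FILTER_BOUNDS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 200.0),
    "SOR": (">", 10.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}

INFO_KEYS = tuple(HARD_FILTER_BOUNDS)


class VariantClass(enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class FilterStatus(enum.Enum):
    PASS = "PASS"
    FILTERED = "FILTERED"


VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic variant. ``pos`` is 1-based (VCF convention,
    anchored base for indels); ``pos0`` gives the 0-based coordinate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict[str, float] = field(default_factory=dict, compare=False, hash=False)
    filter_status: FilterStatus = field(default=FilterStatus.PASS, compare=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNP
        return VariantClass.INDEL

    @property
    def is_snp(self) -> bool:
        return self.vclass is VariantClass.SNP

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


class VariantSet:
    """An ordered, keyed collection of variants for one sample."""

    def __init__(self, sample: str, records: list[VariantRecord] = (),
                 genome_id: str | None = None):
        self.sample = sample
        self.genome_id = genome_id
        self._records: dict[VariantKey, VariantRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._records

    def __iter__(self):
        return iter(self.records)

    @property
    def records(self) -> list[VariantRecord]:
        return sorted(self._records.values(), key=lambda r: (r.chrom, r.pos, r.ref, r.alt))

    @property
    def keys(self) -> set[VariantKey]:
        return set(self._records)

    def counts(self) -> dict[str, int]:
        n_snp = sum(1 for r in self._records.values() if r.is_snp)
        return {"SNP": n_snp, "INDEL": len(self._records) - n_snp}

    def _like(self, sample: str, records: list[VariantRecord]) -> "VariantSet":
        return VariantSet(sample, records, genome_id=self.genome_id)


def split_multiallelic(chrom: str, pos: int, ref: str, alts: list[str],
                       info: dict[str, float]) -> list[VariantRecord]:
    """Split a (possibly multi-allelic) VCF row into biallelic records and
    decompose MNPs into SNPs; the SNP/indel dichotomy needs atomic keys."""
    out: list[VariantRecord] = []
    for alt in alts:
        if alt in (".", "*", ref):
            continue
        if len(ref) == len(alt) and len(ref) > 1:  # MNP -> component SNPs
            for i, (rb, ab) in enumerate(zip(ref, alt)):
                if rb != ab:
                    out.append(VariantRecord(chrom, pos + i, rb, ab, dict(info)))
        else:
            out.append(VariantRecord(chrom, pos, ref, alt, dict(info)))
    return out


def apply_hard_filter(vs: VariantSet) -> VariantSet:
    """Keep records passing the GATK-style hard filter.

    A record is FILTERED iff any *present* metric violates its strict bound
    (QD < 2.0, FS > 200.0, SOR > 10.0, MQRankSum < -12.5,
    ReadPosRankSum < -8.0); absent metrics are simply not evaluated.
    """
    passed = []
    for rec in vs.records:
        if record_passes_filter(rec):
            passed.append(rec)
    return vs._like(vs.sample, passed)


def record_passes_filter(rec: VariantRecord) -> bool:
    for key, (op, bound) in HARD_FILTER_BOUNDS.items():
        if key not in rec.info:
            continue
        val = rec.info[key]
        try:
            val = float(val)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric INFO {key}={val!r} at {rec.chrom}:{rec.pos}"
            ) from exc
        if (op == "<" and val < bound) or (op == ">" and val > bound):
            return False
    return True


def normalize(rec: VariantRecord, genome: Genome) -> VariantRecord:
    """Normalize a variant: trim shared suffix/prefix to a single anchor base
    and left-align indels against the reference until no further shift is
    possible (vt-style algorithm)."""
    chrom, pos0 = rec.chrom, rec.pos0
    ref, alt = rec.ref.upper(), rec.alt.upper()
    seq = genome[chrom]
    if seq[pos0:pos0 + len(ref)] != ref:
        raise ValueError(
            f"REF mismatch at {chrom}:{rec.pos}: VCF says {ref!r}, "
            f"genome has {seq[pos0:pos0 + len(ref)]!r}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
        elif not ref or not alt:
            if pos0 == 0:
                raise ValueError(f"cannot left-extend variant at {chrom}:1")
            pos0 -= 1
            base = seq[pos0]
            ref, alt = base + ref, base + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    if ref == alt:
        raise ValueError(f"ref == alt after trimming at {chrom}:{rec.pos}")
    return replace(rec, pos=pos0 + 1, ref=ref, alt=alt)


def normalize_set(vs: VariantSet, genome: Genome) -> VariantSet:
    return vs._like(vs.sample, [normalize(r, genome) for r in vs.records])


def _check_same_genome(a: VariantSet, b: VariantSet) -> None:
    if a.genome_id is not None and b.genome_id is not None and a.genome_id != b.genome_id:
        raise ValueError(
            f"variant sets called against different genomes: "
            f"{a.genome_id!r} vs {b.genome_id!r}"
        )


def private_variants(mutant: VariantSet, wt: VariantSet) -> VariantSet:
    """Variants of ``mutant`` whose key is absent from ``wt`` — the
    mutagen-induced set when both inputs are filtered and normalized."""
    _check_same_genome(mutant, wt)
    wt_keys = wt.keys
    return mutant._like(mutant.sample,
                        [r for r in mutant.records if r.key not in wt_keys])


def shared_variants(p1: VariantSet, p2: VariantSet) -> VariantSet:
    """Key intersection of two (private) variant sets."""
    _check_same_genome(p1, p2)
    keys2 = p2.keys
    return p1._like(f"{p1.sample}&{p2.sample}",
                    [r for r in p1.records if r.key in keys2])
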