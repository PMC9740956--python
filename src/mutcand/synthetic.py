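"""Synthetic genomes, variant trios, coverage tracks and count matrices with
planted ground truth.

The generator emulates the study design the pipeline targets: one wild-type
and two irradiation-derived mutant lines sharing background variants against
the reference, each mutant carrying additional private variants, some of them
engineered to guarantee a chosen functional consequence inside a gene;
coverage tracks with optional planted deletions; and negative-binomial read
counts (three replicates per line) with planted fold changes.

Defaults follow the emulated study: ~8x sequencing depth, three biological
replicates, planted |log2FC| = 2 on well-expressed genes, NB dispersion 0.05.
Background variants avoid CDS and splice dinucleotides by default so that the
planted large-effect gene sets are exactly the recoverable truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dge import CountMatrix
from .genome import (Genome, START_CODON, STOP_CODONS, TranscriptModel,
                     revcomp, translate)
from .variants import VariantRecord, VariantSet, normalize, record_passes_filter
from .windows import CoverageTrack

SAMPLES = ("WT", "mut1", "mut2")
MUTANTS = ("mut1", "mut2")

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

EFFECT_CATEGORIES = frozenset({
    "splice_acceptor", "splice_donor", "start_lost", "stop_gained",
    "stop_lost", "frameshift", "missense", "synonymous",
})

# INFO metric ranges guaranteed to pass / fail the hard filter
_PASSING_INFO = {
    "QD": (5.0, 30.0), "FS": (0.0, 50.0), "SOR": (0.3, 3.0),
    "MQRankSum": (-3.0, 3.0), "ReadPosRankSum": (-3.0, 3.0),
}
_FAILING_INFO = {
    "QD": (0.0, 1.99), "FS": (200.01, 300.0), "SOR": (10.01, 15.0),
    "MQRankSum": (-20.0, -12.51), "ReadPosRankSum": (-12.0, -8.01),
}


@dataclass
class SyntheticTruth:
    """Exactly the planted deviations of one synthetic scenario."""

    # sample -> {(chrom, pos, ref, alt): {"pass": bool, "class": "SNP"|"INDEL"}}
    planted_private_variants: dict[str, dict[tuple, dict]] = field(default_factory=dict)
    # sample -> {gene_id: category name}
    planted_large_effect_genes: dict[str, dict[str, str]] = field(default_factory=dict)
    # sample -> [(chrom, start, end, copy_ratio)]
    planted_deletions: dict[str, list[tuple]] = field(default_factory=dict)
    # gene -> {condition: log2FC}
    planted_de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    shared_variant_keys: dict[tuple, bool] = field(default_factory=dict)  # key -> passes
    seed: int = 0

    def private_pass(self, sample: str) -> set[tuple]:
        return {k for k, v in self.planted_private_variants.get(sample, {}).items()
                if v["pass"]}

    def private_pass_counts(self, sample: str) -> dict[str, int]:
        recs = [v for k, v in self.planted_private_variants.get(sample, {}).items()
                if v["pass"]]
        n_snp = sum(1 for v in recs if v["class"] == "SNP")
        return {"SNP": n_snp, "INDEL": len(recs) - n_snp}

    def to_json(self) -> str:
        def enc_keys(d):
            return {"|".join(map(str, k)): v for k, v in d.items()}
        payload = {
            "planted_private_variants": {
                s: enc_keys(d) for s, d in self.planted_private_variants.items()},
            "planted_large_effect_genes": self.planted_large_effect_genes,
            "planted_deletions": self.planted_deletions,
            "planted_de_genes": self.planted_de_genes,
            "shared_variant_keys": enc_keys(self.shared_variant_keys),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)

        def dec_key(s):
            chrom, pos, ref, alt = s.split("|")
            return (chrom, int(pos), ref, alt)

        return cls(
            planted_private_variants={
                s: {dec_key(k): v for k, v in d.items()}
                for s, d in raw["planted_private_variants"].items()},
            planted_large_effect_genes=raw["planted_large_effect_genes"],
            planted_deletions={s: [tuple(d) for d in ds]
                               for s, ds in raw["planted_deletions"].items()},
            planted_de_genes=raw["planted_de_genes"],
            shared_variant_keys={dec_key(k): v
                                 for k, v in raw["shared_variant_keys"].items()},
            seed=raw["seed"],
        )


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASE_BYTES[rng.integers(0, 4, size=n)]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n codons, none of them stops."""
    out = []
    while len(out) < n:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _build_gene(rng: np.random.Generator) -> dict:
    """One gene in transcription-order ("spliced-plus-introns") coordinates."""
    utr5_len = int(rng.integers(60, 200))
    utr3_len = int(rng.integers(80, 250))
    n_codons = int(rng.integers(60, 300))  # including start and stop
    cds = (START_CODON + _random_codons(rng, n_codons - 2)
           + sorted(STOP_CODONS)[int(rng.integers(0, 3))])
    spliced = ("".join(_BASES[i] for i in rng.integers(0, 4, size=utr5_len))
               + cds
               + "".join(_BASES[i] for i in rng.integers(0, 4, size=utr3_len)))
    spliced_len = len(spliced)

    n_introns = int(rng.integers(1, 4))
    min_edge, min_sep = 20, 25
    for _ in range(50):
        cuts = np.sort(rng.integers(min_edge, spliced_len - min_edge,
                                    size=n_introns))
        if n_introns == 1 or np.all(np.diff(cuts) >= min_sep):
            break
    else:
        cuts = np.array([spliced_len // 2])
    intron_seqs = []
    for _ in cuts:
        ilen = int(rng.integers(80, 300))
        intron_seqs.append("GT"
                           + "".join(_BASES[i] for i in rng.integers(0, 4, size=ilen - 4))
                           + "AG")

    # assemble region sequence and exon intervals in region coordinates
    region_parts, exon_ivs = [], []
    prev, offset = 0, 0
    for cut, iseq in zip(cuts, intron_seqs):
        region_parts.append(spliced[prev:cut])
        exon_ivs.append((prev + offset, cut + offset))
        region_parts.append(iseq)
        offset += len(iseq)
        prev = cut
    region_parts.append(spliced[prev:])
    exon_ivs.append((prev + offset, spliced_len + offset))
    region_seq = "".join(region_parts)

    def spliced_to_region_ivs(a: int, b: int) -> list[tuple[int, int]]:
        """Map the spliced interval [a, b) onto region-coordinate exon pieces."""
        out, prev_s, offset_i = [], 0, 0
        for (ra, rb), cut in zip(exon_ivs, list(cuts) + [spliced_len]):
            lo, hi = max(a, prev_s), min(b, cut)
            if hi > lo:
                out.append((lo + (ra - prev_s), hi + (ra - prev_s)))
            prev_s = cut
        return out

    return {
        "seq": region_seq,
        "exons": exon_ivs,
        "cds": spliced_to_region_ivs(utr5_len, utr5_len + len(cds)),
        "utr5": spliced_to_region_ivs(0, utr5_len),
        "utr3": spliced_to_region_ivs(utr5_len + len(cds), spliced_len),
    }


def _flip(ivs: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    return sorted((length - b, length - a) for a, b in ivs)


def simulate_genome(n_chrom: int, chrom_len: int, n_genes: int, seed: int,
                    min_gap: int = 500,
                    ) -> tuple[Genome, list[TranscriptModel]]:
    """Random genome with non-overlapping multi-exon gene models.

    Chromosomes are named A01, B01, A02, ... (the allotetraploid A/B
    subgenome naming convention; nothing downstream depends on it). Every
    gene gets >= 2 exons, a CDS opening with ATG and closing with a stop
    codon, 5'/3' UTRs, and GT..AG introns; both strands are used.
    """
    if chrom_len < 50_000:
        raise ValueError("chrom_len must be at least 50 kb")
    rng = np.random.default_rng(seed)
    chrom_names = [f"{'AB'[i % 2]}{i // 2 + 1:02d}" for i in range(n_chrom)]
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]

    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    gene_no = 0
    for chrom, k in zip(chrom_names, per_chrom):
        genes = [_build_gene(rng) for _ in range(k)]
        total = sum(len(g["seq"]) for g in genes)
        slack = chrom_len - total - min_gap * (k + 1)
        if slack < 0:
            raise ValueError(
                f"cannot pack {k} genes ({total} bp + gaps) into {chrom_len} bp "
                f"chromosome {chrom}"
            )
        weights = rng.random(k + 1)
        gaps = min_gap + np.floor(weights / weights.sum() * slack).astype(int)

        arr = _random_dna(rng, chrom_len)
        cursor = 0
        for i, g in enumerate(genes):
            cursor += int(gaps[i])
            start = cursor
            seq = g["seq"]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                placed = revcomp(seq)
                L = len(seq)
                exons = [(start + a, start + b) for a, b in _flip(g["exons"], L)]
                cds = [(start + a, start + b) for a, b in _flip(g["cds"], L)]
                utr5 = [(start + a, start + b) for a, b in _flip(g["utr5"], L)]
                utr3 = [(start + a, start + b) for a, b in _flip(g["utr3"], L)]
            else:
                placed = seq
                exons = [(start + a, start + b) for a, b in g["exons"]]
                cds = [(start + a, start + b) for a, b in g["cds"]]
                utr5 = [(start + a, start + b) for a, b in g["utr5"]]
                utr3 = [(start + a, start + b) for a, b in g["utr3"]]
            arr[start:start + len(placed)] = np.frombuffer(
                placed.encode(), dtype=np.uint8)
            gene_no += 1
            gid = f"g{gene_no:04d}"
            models.append(TranscriptModel(gid, gid + ".1", chrom, strand,
                                          exons, cds, utr5, utr3))
            cursor = start + len(placed)
        sequences[chrom] = arr.tobytes().decode()
    return Genome(sequences), models


# --------------------------------------------------------------------------
# variant planting


def _engineer_snp(tx: TranscriptModel, genome: Genome, category: str,
                  rng: np.random.Generator) -> tuple[str, int, str, str]:
    """A (chrom, pos1, ref, alt) SNP guaranteed to produce ``category``."""
    if category in ("splice_donor", "splice_acceptor"):
        sites = [iv for iv, kind in tx.splice_sites() if kind == category]
        if not sites:
            raise ValueError(f"{tx.gene_id} has no {category} site")
        a, b = sites[int(rng.integers(0, len(sites)))]
        pos = int(rng.integers(a, b))
        ref = genome[tx.chrom][pos]
        alt = _BASES[int(rng.integers(0, 4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(0, 4))]
        return tx.chrom, pos + 1, ref, alt

    cds = tx.coding_sequence(genome)
    positions = tx.coding_positions()
    n_codons = len(cds) // 3
    candidates: list[tuple[int, str]] = []  # (coding index, new transcript base)

    def codon(i: int) -> str:
        return cds[3 * i: 3 * i + 3]

    if category == "start_lost":
        rng_codons = [0]
    elif category == "stop_lost":
        rng_codons = [n_codons - 1]
    else:
        rng_codons = list(rng.permutation(np.arange(1, n_codons - 1)))
    for ci in rng_codons:
        cd = codon(int(ci))
        for off in range(3):
            for b in _BASES:
                if b == cd[off]:
                    continue
                new = cd[:off] + b + cd[off + 1:]
                ok = False
                if category == "start_lost":
                    ok = new != START_CODON
                elif category == "stop_lost":
                    ok = new not in STOP_CODONS
                elif category == "stop_gained":
                    ok = new in STOP_CODONS
                elif category == "missense":
                    ok = (new not in STOP_CODONS
                          and translate(new) != translate(cd))
                elif category == "synonymous":
                    ok = (new not in STOP_CODONS
                          and translate(new) == translate(cd))
                if ok:
                    candidates.append((3 * int(ci) + off, b))
        if candidates:
            break
    if not candidates:
        raise ValueError(f"cannot engineer {category} in {tx.gene_id}")
    ci, new_base = candidates[int(rng.integers(0, len(candidates)))]
    pos = positions[ci]
    ref = genome[tx.chrom][pos]
    alt = new_base if tx.strand == "+" else revcomp(new_base)
    assert alt != ref
    return tx.chrom, pos + 1, ref, alt


def _engineer_frameshift(tx: TranscriptModel, genome: Genome,
                         rng: np.random.Generator) -> tuple[str, int, str, str]:
    """1-bp CDS insertion: REF length 1, ALT length 2 -> frameshift."""
    wide = [iv for iv in tx.cds if iv[1] - iv[0] >= 6]
    if not wide:
        raise ValueError(f"{tx.gene_id} has no CDS interval wide enough")
    a, b = wide[int(rng.integers(0, len(wide)))]
    pos = int(rng.integers(a + 1, b - 2))  # anchor and next base inside CDS
    ref = genome[tx.chrom][pos]
    # avoid duplicating the anchor or the following base: keeps the record
    # already left-aligned so the planted key survives normalization unchanged
    nxt = genome[tx.chrom][pos + 1]
    choices = [c for c in _BASES if c != nxt and c != ref]
    ins = choices[int(rng.integers(0, len(choices)))]
    return tx.chrom, pos + 1, ref, ref + ins


def plant_effect_variant(tx: TranscriptModel, genome: Genome, category: str,
                         rng: np.random.Generator) -> tuple[str, int, str, str]:
    if category not in EFFECT_CATEGORIES:
        raise ValueError(f"unknown effect category {category!r}")
    if category == "frameshift":
        return _engineer_frameshift(tx, genome, rng)
    return _engineer_snp(tx, genome, category, rng)


def _forbidden_mask(genome: Genome, models: list[TranscriptModel],
                    ) -> dict[str, np.ndarray]:
    """Positions background variants must avoid: CDS and splice dinucleotides
    (with a 3-bp buffer so short indels cannot reach into them)."""
    masks = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.chroms}
    for tx in models:
        m = masks[tx.chrom]
        for a, b in tx.cds:
            m[max(0, a - 4):b + 4] = True
        for (a, b), _ in tx.splice_sites():
            m[max(0, a - 4):b + 4] = True
    return masks


def _draw_info(rng: np.random.Generator, fail: bool) -> dict[str, float]:
    info = {k: float(rng.uniform(*v)) for k, v in _PASSING_INFO.items()}
    if fail:
        key = list(_FAILING_INFO)[int(rng.integers(0, len(_FAILING_INFO)))]
        info[key] = float(rng.uniform(*_FAILING_INFO[key]))
    return {k: round(v, 3) for k, v in info.items()}


def _random_variant(genome: Genome, chrom: str, pos: int,
                    rng: np.random.Generator, indel_fraction: float,
                    ) -> tuple[int, str, str] | None:
    seq = genome[chrom]
    if pos < 1 or pos >= len(seq) - 5:
        return None
    if rng.random() >= indel_fraction:  # SNP
        ref = seq[pos]
        alt = _BASES[int(rng.integers(0, 4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(0, 4))]
        return pos + 1, ref, alt
    length = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # insertion after anchor
        ref = seq[pos]
        ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if ins[0] == seq[pos + 1]:  # keep left-aligned as emitted
            return None
        return pos + 1, ref, ref + ins
    ref = seq[pos:pos + 1 + length]
    if ref[1] == seq[pos + 1 + length]:  # would left-shift under normalization
        return None
    return pos + 1, ref, ref[0]


def plant_variants(genome: Genome, models: list[TranscriptModel],
                   n_shared: int, n_private: dict[str, int],
                   planted_effects: list[tuple] = (),
                   seed: int = 0, fail_fraction: float = 0.1,
                   indel_fraction: float = 0.2, avoid_coding: bool = True,
                   ) -> tuple[dict[str, VariantSet], SyntheticTruth]:
    """Build the WT/mut1/mut2 trio of call sets.

    Shared background variants (vs the reference) appear in all three sets
    with identical INFO fields; each sample additionally gets its private
    background variants; ``planted_effects`` entries
    (gene_id, category[, samples]) engineer a variant guaranteeing the
    requested consequence (default: planted in both mutants). A
    ``fail_fraction`` of background records carries an INFO value violating
    the hard filter.
    """
    rng = np.random.default_rng(seed)
    models_by_gene = {tx.gene_id: tx for tx in models}
    truth = SyntheticTruth(seed=seed)
    truth.planted_private_variants = {s: {} for s in SAMPLES}
    truth.planted_large_effect_genes = {s: {} for s in SAMPLES}
    sets = {s: VariantSet(s, genome_id="synthetic") for s in SAMPLES}
    used: set[tuple[str, int]] = set()

    # planted effect variants first: their coordinates are constrained
    for entry in planted_effects:
        gene_id, category = entry[0], entry[1]
        target_samples = tuple(entry[2]) if len(entry) > 2 else MUTANTS
        tx = models_by_gene.get(gene_id)
        if tx is None:
            raise ValueError(f"unknown gene {gene_id!r} in planted_effects")
        chrom, pos, ref, alt = plant_effect_variant(tx, genome, category, rng)
        if (chrom, pos) in used:
            raise ValueError(f"planted-effect collision at {chrom}:{pos}")
        used.add((chrom, pos))
        rec = normalize(VariantRecord(chrom, pos, ref, alt,
                                      _draw_info(rng, fail=False)), genome)
        used.add((chrom, rec.pos0))
        vclass = "SNP" if rec.is_snp else "INDEL"
        for s in target_samples:
            sets[s].add(rec)
            truth.planted_private_variants[s][rec.key] = {
                "pass": True, "class": vclass}
            truth.planted_large_effect_genes[s][gene_id] = category

    # background variants avoid coding-critical sites so planted truth stays
    # exactly the recoverable truth
    masks = _forbidden_mask(genome, models) if avoid_coding else {
        c: np.zeros(genome.length(c), dtype=bool) for c in genome.chroms}
    chroms = genome.chroms
    lengths = np.array([genome.length(c) for c in chroms])
    bounds = np.cumsum(lengths)

    def draw_records(n: int) -> list[VariantRecord]:
        out = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 50 * n + 1000:
                raise ValueError("cannot place background variants "
                                 "(genome too small or too constrained)")
            flat = int(rng.integers(0, bounds[-1]))
            ci = int(np.searchsorted(bounds, flat, side="right"))
            chrom = chroms[ci]
            pos = flat - (int(bounds[ci]) - int(lengths[ci]))
            if (chrom, pos) in used:
                continue
            made = _random_variant(genome, chrom, pos, rng, indel_fraction)
            if made is None:
                continue
            pos1, ref, alt = made
            # canonicalize so planted keys survive pipeline normalization
            canon = normalize(VariantRecord(chrom, pos1, ref, alt), genome)
            pos1, ref, alt = canon.pos, canon.ref, canon.alt
            if (chrom, pos1 - 1) in used:
                continue
            if masks[chrom][max(0, pos1 - 2): pos1 - 1 + len(ref) + 1].any():
                continue
            used.add((chrom, pos1 - 1))
            if pos1 - 1 != pos:
                used.add((chrom, pos))
            fail = bool(rng.random() < fail_fraction)
            out.append(VariantRecord(chrom, pos1, ref, alt,
                                     _draw_info(rng, fail=fail)))
        return out

    for rec in draw_records(n_shared):
        passes = record_passes_filter(rec)
        truth.shared_variant_keys[rec.key] = passes
        for s in SAMPLES:
            sets[s].add(rec)

    for sample in SAMPLES:
        for rec in draw_records(int(n_private.get(sample, 0))):
            sets[sample].add(rec)
            truth.planted_private_variants[sample][rec.key] = {
                "pass": record_passes_filter(rec),
                "class": "SNP" if rec.is_snp else "INDEL",
            }
    return sets, truth


# --------------------------------------------------------------------------
# coverage


def simulate_depth(genome: Genome, mean_depth: float = 8.0,
                   window: int = 100_000,
                   deletions: dict[str, list[tuple]] | None = None,
                   noise_cv: float = 0.1, seed: int = 0,
                   samples: tuple[str, ...] = SAMPLES,
                   ) -> tuple[dict[str, CoverageTrack], dict[str, list[tuple]]]:
    """Per-sample window depth tracks with optional planted deletions.

    ``deletions`` maps sample -> [(chrom, start, end, copy_ratio)] with
    copy_ratio in {0, 0.5}; windows overlapping a deletion are scaled by the
    overlap-weighted copy ratio. Depth noise is gamma-distributed with CV
    ``noise_cv`` (0 gives exact means).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    deletions = deletions or {}
    for sample, dels in deletions.items():
        seen: dict[str, list[tuple]] = {}
        for chrom, start, end, ratio in dels:
            if chrom not in genome or not (0 <= start < end <= genome.length(chrom)):
                raise ValueError(f"deletion {chrom}:{start}-{end} out of bounds")
            for s0, e0 in seen.get(chrom, []):
                if start < e0 and s0 < end:
                    raise ValueError("planted deletion intervals overlap")
            seen.setdefault(chrom, []).append((start, end))
    for chrom in genome.chroms:
        if window > genome.length(chrom):
            raise ValueError(
                f"window {window} larger than chromosome {chrom} "
                f"({genome.length(chrom)} bp)")

    rng = np.random.default_rng(seed)
    tracks: dict[str, CoverageTrack] = {}
    for sample in samples:
        depths: dict[str, np.ndarray] = {}
        for chrom in genome.chroms:
            n_win = -(-genome.length(chrom) // window)
            if noise_cv > 0:
                shape = 1.0 / noise_cv ** 2
                vals = rng.gamma(shape, mean_depth / shape, size=n_win)
            else:
                vals = np.full(n_win, float(mean_depth))
            for dchrom, start, end, ratio in deletions.get(sample, []):
                if dchrom != chrom:
                    continue
                w_starts = np.arange(n_win) * window
                w_ends = np.minimum(w_starts + window, genome.length(chrom))
                overlap = (np.minimum(w_ends, end) - np.maximum(w_starts, start)).clip(0)
                frac = overlap / (w_ends - w_starts)
                vals = vals * (1.0 - frac * (1.0 - ratio))
            depths[chrom] = vals
        tracks[sample] = CoverageTrack(sample, window, depths)
    return tracks, deletions


# --------------------------------------------------------------------------
# counts


def simulate_counts(models: list[TranscriptModel],
                    de_spec: dict[str, dict[str, float]] | None = None,
                    dispersion: float = 0.05,
                    lib_sizes: dict[str, float] | None = None,
                    n_reps: int = 3, seed: int = 0,
                    baseline_log_mean: float = 5.0,
                    baseline_log_sd: float = 1.0,
                    de_baseline: tuple[float, float] = (500.0, 1500.0),
                    ) -> CountMatrix:
    """NB read counts for WT/mut1/mut2 with ``n_reps`` replicates each.

    counts ~ NB(mean = baseline * lib_size * 2^log2FC(gene, condition),
    dispersion); dispersion 0 reduces to Poisson. Genes named in ``de_spec``
    get a well-expressed baseline so planted fold changes are a detectable
    signal, not a coin flip.
    """
    import pandas as pd

    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    de_spec = de_spec or {}
    rng = np.random.default_rng(seed)
    genes = [tx.gene_id for tx in models]
    sample_names = [f"{cond}_{r + 1}" for cond in SAMPLES for r in range(n_reps)]
    conditions = {s: s.rsplit("_", 1)[0] for s in sample_names}
    if lib_sizes is None:
        lib_sizes = {s: float(rng.uniform(0.8, 1.2)) for s in sample_names}
    if any(v <= 0 for v in lib_sizes.values()):
        raise ValueError("lib_sizes must be positive")

    baselines = np.exp(rng.normal(baseline_log_mean, baseline_log_sd,
                                  size=len(genes)))
    for i, g in enumerate(genes):
        if g in de_spec:
            baselines[i] = rng.uniform(*de_baseline)

    mat = np.zeros((len(genes), len(sample_names)), dtype=int)
    for j, s in enumerate(sample_names):
        cond = conditions[s]
        lfc = np.array([de_spec.get(g, {}).get(cond, 0.0) for g in genes])
        mu = baselines * lib_sizes[s] * np.power(2.0, lfc)
        if dispersion == 0:
            mat[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            mat[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(mat, index=genes, columns=sample_names)
    lengths = pd.Series({tx.gene_id: tx.exonic_length() for tx in models})
    return CountMatrix(counts, conditions, lengths)
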