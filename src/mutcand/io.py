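"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Biopython, VCF parsing through pysam, GFF3 parsing through
gffutils; GFF3/VCF/BedGraph emission writes the plain-text records directly
(coordinates convert between the internal 0-based half-open convention and
the 1-based file conventions here, and only here).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Genome, TranscriptModel
from .variants import INFO_KEYS, VariantSet, split_multiallelic
from .windows import CoverageTrack


# -- FASTA ------------------------------------------------------------------

def write_fasta(genome: Genome, path: str) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Genome:
    return Genome({rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(path, "fasta")})


# -- GFF3 -------------------------------------------------------------------

def write_gff3(models: list[TranscriptModel], path: str) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, 1-based closed coordinates."""
    def line(chrom, ftype, a, b, strand, attrs, phase="."):
        return "\t".join([chrom, "mutcand", ftype, str(a + 1), str(b),
                          ".", strand, phase, attrs])

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(models, key=lambda t: (t.chrom, t.start)):
            g, t = tx.gene_id, tx.tx_id
            fh.write(line(tx.chrom, "gene", tx.start, tx.end, tx.strand,
                          f"ID={g}") + "\n")
            fh.write(line(tx.chrom, "mRNA", tx.start, tx.end, tx.strand,
                          f"ID={t};Parent={g}") + "\n")
            for a, b in tx.exons:
                fh.write(line(tx.chrom, "exon", a, b, tx.strand,
                              f"Parent={t}") + "\n")
            # CDS phase in transcription order
            cds = tx.cds if tx.strand == "+" else list(reversed(tx.cds))
            done = 0
            for a, b in cds:
                phase = str((3 - done % 3) % 3)
                fh.write(line(tx.chrom, "CDS", a, b, tx.strand,
                              f"Parent={t}", phase) + "\n")
                done += b - a
            for a, b in tx.utr5:
                fh.write(line(tx.chrom, "five_prime_UTR", a, b, tx.strand,
                              f"Parent={t}") + "\n")
            for a, b in tx.utr3:
                fh.write(line(tx.chrom, "three_prime_UTR", a, b, tx.strand,
                              f"Parent={t}") + "\n")


def read_gff3(path: str) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for mrna in db.features_of_type("mRNA"):
        def ivs(ftype):
            return sorted((f.start - 1, f.end)
                          for f in db.children(mrna, featuretype=ftype))
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        models.append(TranscriptModel(
            gene_id=gene_id, tx_id=mrna.id, chrom=mrna.seqid,
            strand=mrna.strand, exons=ivs("exon"), cds=ivs("CDS"),
            utr5=ivs("five_prime_UTR"), utr3=ivs("three_prime_UTR")))
    return models


# -- VCF --------------------------------------------------------------------

def write_vcf(vs: VariantSet, genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutcand\n")
        for chrom in genome.chroms:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        for key in INFO_KEYS:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,'
                     f'Description="{key} metric">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + vs.sample + "\n")
        for rec in vs.records:
            info = ";".join(f"{k}={rec.info[k]:g}" for k in INFO_KEYS
                            if k in rec.info) or "."
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                     f"{info}\tGT\t1/1\n")


def read_vcf(path: str, sample: str | None = None,
             genome_id: str | None = None) -> VariantSet:
    """Parse a (plain or bgzipped) VCF into a VariantSet, splitting
    multi-allelic rows and decomposing MNPs."""
    import pysam

    with pysam.VariantFile(path) as vf:
        if sample is None:
            sample = list(vf.header.samples)[0] if vf.header.samples \
                else os.path.basename(path).split(".")[0]
        vs = VariantSet(sample, genome_id=genome_id)
        for row in vf:
            info = {}
            for key in INFO_KEYS:
                if key in row.info:
                    val = row.info[key]
                    info[key] = float(val[0] if isinstance(val, tuple) else val)
            for rec in split_multiallelic(row.chrom, row.pos, row.ref,
                                          list(row.alts or ()), info):
                vs.add(rec)
    return vs


# -- BedGraph ---------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str,
                   chrom_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample}"\n')
        for chrom, vals in track.depths.items():
            for i, v in enumerate(vals):
                start = i * track.window
                end = start + track.window
                if chrom_lengths and chrom in chrom_lengths:
                    end = min(end, chrom_lengths[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.4f}\n")


def read_bedgraph(path: str, sample: str | None = None) -> CoverageTrack:
    """Read a BedGraph of fixed-width windows back into a CoverageTrack."""
    if sample is None:
        sample = os.path.basename(path).split(".")[0]
    rows: dict[str, list[tuple[int, float]]] = {}
    window = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, val = line.split()[:4]
            start, end = int(start), int(end)
            if window is None:
                window = end - start
            rows.setdefault(chrom, []).append((start, float(val)))
    if window is None:
        raise ValueError(f"no data lines in {path}")
    depths = {}
    for chrom, pairs in rows.items():
        pairs.sort()
        depths[chrom] = np.array([v for _, v in pairs])
    return CoverageTrack(sample, window, depths)


# -- tables -----------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def private_summary_table(raw: dict[str, dict[str, int]],
                          private: dict[str, dict[str, int]],
                          shared: dict[str, int]) -> pd.DataFrame:
    """Summary mirroring the per-line variant-count table: calls vs reference
    per sample, private calls per mutant, and the mutant-shared counts."""
    rows = []
    for sample, counts in raw.items():
        rows.append({"set": f"{sample} vs Ref", **counts})
    for sample, counts in private.items():
        rows.append({"set": f"{sample} private", **counts})
    rows.append({"set": "shared by mutants", **shared})
    return pd.DataFrame(rows).set_index("set")
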