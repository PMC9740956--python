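"""Independent oracles used by the test suite.

These deliberately take a different computational path from the package:
consequence categories come from mutating the chromosome string and
re-translating the rebuilt CDS; normalization comes from a global
prefix/suffix comparison of the reference and edited haplotype; Mann-Whitney
p-values come from brute-force enumeration written separately from the
implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

from mutcand.genome import Genome, TranscriptModel


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _translate(s: str) -> str:
    return str(Seq(s).translate())


def rebuild_mutant_cds(genome: Genome, tx: TranscriptModel,
                       pos0: int, ref: str, alt: str) -> str:
    """Apply the edit to the chromosome string and re-extract the CDS, shifting
    downstream CDS bounds by the length change. Only valid when the edited
    bases lie wholly inside one CDS interval."""
    seq = genome[tx.chrom]
    assert seq[pos0:pos0 + len(ref)] == ref
    mutant = seq[:pos0] + alt + seq[pos0 + len(ref):]
    delta = len(alt) - len(ref)
    new_cds = []
    for a, b in tx.cds:
        if pos0 >= b:
            new_cds.append((a, b))
        elif a <= pos0 and pos0 + len(ref) <= b:
            new_cds.append((a, b + delta))
        elif pos0 + len(ref) <= a:
            new_cds.append((a + delta, b + delta))
        else:
            raise ValueError("edit crosses a CDS boundary")
    parts = "".join(mutant[a:b] for a, b in sorted(new_cds))
    return _revcomp(parts) if tx.strand == "-" else parts


def retranslate_category(genome: Genome, tx: TranscriptModel,
                         pos0: int, ref: str, alt: str) -> str:
    """Expected consequence of a CDS variant by full re-translation.

    For indels the in-frame subcategories reduce to length arithmetic plus
    start/stop integrity (matching the annotation contract that internal
    in-frame indels are 'none')."""
    new_cds = rebuild_mutant_cds(genome, tx, pos0, ref, alt)
    old_cds = tx.coding_sequence(genome)
    if len(new_cds) % 3 != 0:
        return "frameshift"
    if new_cds[:3] != "ATG":
        return "start_lost"
    old_prot = _translate(old_cds)
    new_prot = _translate(new_cds)
    if len(ref) == len(alt) == 1:
        if "*" in new_prot[:-1]:
            return "stop_gained"
        if old_prot.endswith("*") and not new_prot.endswith("*"):
            return "stop_lost"
        return "missense" if new_prot != old_prot else "synonymous"
    # in-frame indel: only start/stop disruption is called
    if old_prot.endswith("*") and not new_prot.endswith("*"):
        return "stop_lost"
    return "none"


def leftmost_minimal(seq: str, pos0: int, ref: str, alt: str,
                     window: int = 60) -> tuple[int, str, str]:
    """Leftmost minimal (pos0, ref, alt) representation of the edit, derived by
    comparing the reference and edited haplotype strings directly: maximal
    common suffix first (pushing the representation left), then the common
    prefix down to a single anchor base."""
    lo = max(0, pos0 - window)
    hi = min(len(seq), pos0 + len(ref) + window)
    ref_w = seq[lo:hi]
    hap_w = seq[lo:pos0] + alt + seq[pos0 + len(ref):hi]
    ls, lh = len(ref_w), len(hap_w)
    s = 0
    while s < min(ls, lh) and ref_w[ls - 1 - s] == hap_w[lh - 1 - s]:
        s += 1
    p = 0
    while p < min(ls, lh) - s and ref_w[p] == hap_w[p]:
        p += 1
    new_ref, new_alt = ref_w[p:ls - s], hap_w[p:lh - s]
    if not new_ref or not new_alt:
        p -= 1
        new_ref, new_alt = ref_w[p] + new_ref, ref_w[p] + new_alt
    return lo + p, new_ref, new_alt


def mwu_exact_p(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumeration over midranked pooled
    values; returns (U of x, p)."""
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    svals = [pooled[k] for k in order]
    while i < len(svals):
        j = i
        while j < len(svals) and svals[j] == svals[i]:
            j += 1
        for k in range(i, j):
            ranks[order[k]] = (i + j + 1) / 2
        i = j
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    dist = abs(u_obs - center)
    hits = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= dist - 1e-9:
            hits += 1
    return u_obs, min(1.0, hits / total)


def hypergeom_enum_p(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for the hypergeometric by exhaustive subset enumeration
    (feasible for N <= 20)."""
    items = [1] * K + [0] * (N - K)
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        if sum(items[i] for i in combo) >= k:
            hits += 1
    return hits / total


def mirror_scenario(genome: Genome, models: list[TranscriptModel],
                    ) -> tuple[Genome, list[TranscriptModel]]:
    """Reverse-complement every chromosome and flip all strands/intervals."""
    g2 = Genome({c: _revcomp(s) for c, s in genome.sequences.items()})

    def flip(ivs, L):
        return sorted((L - b, L - a) for a, b in ivs)

    models2 = []
    for tx in models:
        L = genome.length(tx.chrom)
        models2.append(TranscriptModel(
            tx.gene_id, tx.tx_id, tx.chrom,
            "-" if tx.strand == "+" else "+",
            flip(tx.exons, L), flip(tx.cds, L),
            flip(tx.utr5, L), flip(tx.utr3, L)))
    return g2, models2
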