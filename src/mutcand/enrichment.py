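"""Observed/expected element enrichment via random control sites, and a
hypergeometric term over-representation test.

The O/E design: draw the same number of control positions uniformly over the
assembled genome, classify them into element classes, and report the ratio of
observed class counts to the mean control count over resamples. A flat
gene -> terms map drives the over-representation test (no DAG propagation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .dge import bh_adjust
from .effects import Element, ElementIndex
from .genome import Genome


@dataclass
class EnrichmentResult:
    element: Element
    observed: int
    expected: float  # mean over resamples
    ratio: float | None  # None when expected == 0 (undefined, not infinity)
    resample_sd: float
    n_resamples: int
    seed: int


@dataclass
class TermEnrichment:
    term: str
    k: int  # set genes carrying the term
    n: int  # set size
    K: int  # universe genes carrying the term
    N: int  # universe size
    p: float
    q: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def sample_control_sites(genome: Genome, n: int, seed: int,
                         ) -> list[tuple[str, int]]:
    """n positions (chrom, 0-based pos) uniform over total assembled length."""
    if n < 1:
        raise ValueError("need at least one control site")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms
    lengths = np.array([genome.length(c) for c in chroms])
    flat = rng.integers(0, lengths.sum(), size=n)
    bounds = np.cumsum(lengths)
    idx = np.searchsorted(bounds, flat, side="right")
    return [(chroms[i], int(p - (bounds[i] - lengths[i]))) for i, p in zip(idx, flat)]


def _classify_positions(index: ElementIndex, sites: list[tuple[str, int]],
                        ) -> np.ndarray:
    counts = np.zeros(len(Element), dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in sites:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        labels = index.labels_at(chrom, np.asarray(positions))
        counts += np.bincount(labels, minlength=len(Element))
    return counts


def observed_expected(observed_sites: list[tuple[str, int]], genome: Genome,
                      index: ElementIndex, n_resamples: int = 100,
                      seed: int = 0) -> list[EnrichmentResult]:
    """O/E ratio per element class for one set of observed positions.

    ``expected`` is the mean class count over ``n_resamples`` uniform control
    draws of equal size; classes with expected 0 get ratio None.
    """
    if n_resamples < 1:
        raise ValueError("need at least one resample")
    obs_counts = _classify_positions(index, observed_sites)
    n = len(observed_sites)
    resampled = np.zeros((n_resamples, len(Element)), dtype=int)
    for r in range(n_resamples):
        control = sample_control_sites(genome, n, seed=seed + r)
        resampled[r] = _classify_positions(index, control)
    expected = resampled.mean(axis=0)
    sds = resampled.std(axis=0, ddof=1) if n_resamples > 1 else np.zeros(len(Element))
    out = []
    for el in Element:
        exp = float(expected[el])
        ratio = float(obs_counts[el]) / exp if exp > 0 else None
        out.append(EnrichmentResult(el, int(obs_counts[el]), exp, ratio,
                                    float(sds[el]), n_resamples, seed))
    return out


def observed_expected_by_class(variants, genome: Genome, index: ElementIndex,
                               n_resamples: int = 100, seed: int = 0,
                               ) -> dict[str, list[EnrichmentResult]]:
    """Run the O/E analysis separately for SNPs and indels of a VariantSet."""
    snp_sites = [(r.chrom, r.pos0) for r in variants if r.is_snp]
    indel_sites = [(r.chrom, r.pos0) for r in variants if not r.is_snp]
    out = {}
    if snp_sites:
        out["SNP"] = observed_expected(snp_sites, genome, index, n_resamples, seed)
    if indel_sites:
        out["INDEL"] = observed_expected(indel_sites, genome, index,
                                         n_resamples, seed + n_resamples)
    return out


def term_overrepresentation(gene_set: set[str], universe: set[str],
                            term_map: dict[str, set[str]],
                            ) -> list[TermEnrichment]:
    """Hypergeometric upper-tail over-representation of each term in
    ``gene_set`` against ``universe``, BH-adjusted; q < 0.05 is significant."""
    if not universe:
        raise ValueError("empty gene universe")
    extra = gene_set - universe
    if extra:
        raise ValueError(f"gene set not contained in universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(gene_set)
    term_universe: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for gene in universe:
        for term in term_map.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in gene_set:
                term_set[term] = term_set.get(term, 0) + 1
    results = []
    for term, K in sorted(term_universe.items()):
        k = term_set.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        results.append(TermEnrichment(term, k, n, K, N, min(p, 1.0)))
    qs = bh_adjust(np.array([t.p for t in results])) if results else []
    for t, q in zip(results, qs):
        t.q = float(q)
    return results
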