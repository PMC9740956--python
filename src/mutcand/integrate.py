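"""Candidate-gene integration and small companion statistics.

A candidate gene must be differentially expressed in BOTH mutants with the
SAME direction and carry a large-effect variant in BOTH mutants' private
sets. The module also provides the 2^-ddCt relative-expression transform and
a Mann-Whitney U test with exact enumeration for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as normal_dist

from .dge import DEResult
from .effects import Consequence, EffectCall, INTEGRATION_LARGE_EFFECT, large_effect_genes


def shared_degs(de1: tuple[set[str], set[str]], de2: tuple[set[str], set[str]],
                ) -> tuple[set[str], set[str], set[str]]:
    """(shared_up, shared_down, discordant): concordant intersections of the
    two mutants' (up, down) DEG sets; genes up in one and down in the other
    are reported separately and never shared."""
    up1, down1 = de1
    up2, down2 = de2
    discordant = (up1 & down2) | (down1 & up2)
    return (up1 & up2) - discordant, (down1 & down2) - discordant, discordant


def candidate_genes(shared_up: set[str], shared_down: set[str],
                    effects_by_sample: dict[str, list[EffectCall]],
                    de_by_sample: dict[str, list[DEResult]],
                    categories: frozenset = INTEGRATION_LARGE_EFFECT,
                    known_genes: set[str] | None = None,
                    require_union: bool = False,
                    ) -> pd.DataFrame:
    """The candidate report: shared DEGs that carry large-effect variants in
    every mutant (or any, with ``require_union``).

    Columns mirror the summary-table layout — gene, chromosome, 1-based
    position, reference and variant alleles, effect — plus per-mutant log2FC
    and direction. Rows are ordered by (chrom, position). DEGs absent from the
    annotation (``known_genes``) are dropped with a warning column upstream.
    """
    samples = sorted(effects_by_sample)
    le_sets = [large_effect_genes(effects_by_sample[s], categories)["ALL"]
               for s in samples]
    if require_union:
        le_shared = set().union(*le_sets) if le_sets else set()
    else:
        le_shared = set.intersection(*le_sets) if le_sets else set()
    degs = shared_up | shared_down
    dropped = degs - known_genes if known_genes is not None else set()
    if dropped:
        import warnings
        warnings.warn(f"{len(dropped)} shared DEGs absent from annotation; dropped")
        degs -= dropped
    candidates = degs & le_shared

    de_lookup = {s: {r.gene: r for r in de_by_sample[s]} for s in de_by_sample}
    rows = []
    for gene in candidates:
        evidence: dict[tuple, EffectCall] = {}
        for s in samples:
            for call in effects_by_sample[s]:
                if call.gene_id == gene and call.consequence in categories:
                    prev = evidence.get(call.variant_key)
                    if prev is None or call.consequence > prev.consequence:
                        evidence[call.variant_key] = call
        for key, call in sorted(evidence.items()):
            chrom, pos, ref, alt = key
            row = {
                "Gene_ID": gene,
                "Chromosome": chrom,
                "Physical_Position": pos,
                "Reference": ref,
                "Variation": alt,
                "Effect": call.consequence.name,
            }
            for s in de_by_sample:
                r = de_lookup[s].get(gene)
                row[f"log2FC_{s}"] = r.log2fc if r else float("nan")
                row[f"Direction_{s}"] = r.direction.value if r else "na"
            rows.append(row)
    cols = (["Gene_ID", "Chromosome", "Physical_Position", "Reference",
             "Variation", "Effect"]
            + [f"log2FC_{s}" for s in de_by_sample]
            + [f"Direction_{s}" for s in de_by_sample])
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["Chromosome", "Physical_Position",
                           "Gene_ID"]).reset_index(drop=True)


@dataclass
class RelativeExpression:
    sample: str
    delta_delta_ct: float
    fold: float


def delta_delta_ct(ct_target: dict[str, float], ct_reference: dict[str, float],
                   calibrator: str) -> list[RelativeExpression]:
    """Relative expression by the 2^-ddCt method.

    dCt_s = Ct_target,s - Ct_ref,s; ddCt_s = dCt_s - dCt_calibrator;
    fold = 2^-ddCt (fold 1 at the calibrator by construction).
    """
    for name, table in (("target", ct_target), ("reference", ct_reference)):
        if calibrator not in table:
            raise ValueError(f"calibrator {calibrator!r} missing from {name} Ct values")
    missing = set(ct_target) ^ set(ct_reference)
    if missing:
        raise ValueError(f"Ct values missing for samples: {sorted(missing)}")
    d_cal = ct_target[calibrator] - ct_reference[calibrator]
    out = []
    for sample in ct_target:
        ddct = (ct_target[sample] - ct_reference[sample]) - d_cal
        out.append(RelativeExpression(sample, ddct, 2.0 ** (-ddct)))
    return out


EXACT_MWU_MAX_N = 12


def _u_statistic(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2)


def mann_whitney_u(x, y, exact_max_n: int = EXACT_MWU_MAX_N) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Returns (U of the first sample, two-sided p). p is exact by enumeration of
    all C(n1+n2, n1) rank assignments when n1+n2 <= ``exact_max_n``, else a
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(n1 + n2)
    # midranks
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    u1 = _u_statistic(ranks[:n1], n1)
    u2 = n1 * n2 - u1
    u_small = min(u1, u2)

    if n1 + n2 <= exact_max_n:
        all_u = []
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            r = ranks[list(combo)]
            all_u.append(_u_statistic(r, n1))
        all_u = np.asarray(all_u)
        total = len(all_u)
        # two-sided: both tails at distance >= |U - n1 n2 / 2| from the center
        hits = int(((all_u <= u_small + 1e-9)
                    | (all_u >= n1 * n2 - u_small - 1e-9)).sum())
        p = min(1.0, hits / total)
    else:
        t_counts = np.unique(pooled, return_counts=True)[1]
        n = n1 + n2
        mean = n1 * n2 / 2
        tie_term = ((t_counts ** 3 - t_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12 * (n + 1 - tie_term)
        if var <= 0:
            return u1, 1.0
        z = (abs(u1 - mean) - 0.5) / math.sqrt(var)
        p = min(1.0, 2 * float(normal_dist.sf(max(z, 0.0))))
    return u1, p
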