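"""Expression filtering, FPKM categories, and negative-binomial differential
expression with Benjamini-Hochberg FDR control.

The DE test follows the standard NB workflow: median-of-ratios size factors,
gene-wise method-of-moments dispersion pooled within conditions, and a
likelihood-ratio test of separate vs common group means (chi-square, 1 df).
Dispersion shrinkage, outlier filtering and independent filtering are
deliberately not reproduced; differential genes are called at FDR < 0.05 and
linear fold change >= 2 (or <= 0.5).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

MIN_DISPERSION = 1e-8
DEFAULT_ALPHA = 0.05
DEFAULT_FC_MIN = 2.0
FPKM_REMOVE_BELOW = 0.1


class Direction(enum.Enum):
    up = "up"
    down = "down"
    ns = "ns"


class ExpressionCategory(enum.Enum):
    very_high = "very_high"  # FPKM >= 50
    high = "high"            # 10 <= FPKM < 50
    moderate = "moderate"    # 2 <= FPKM < 10
    low = "low"              # 0.1 <= FPKM < 2
    removed = "removed"      # FPKM < 0.1 in all samples


@dataclass
class CountMatrix:
    """Gene x sample integer counts with condition labels and gene lengths."""

    counts: pd.DataFrame                  # genes x samples
    conditions: dict[str, str]            # sample -> condition label
    lengths: pd.Series                    # gene -> union-of-exons bp

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("gene lengths missing for some genes")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass
class DEResult:
    gene: str
    base_mean: float
    log2fc: float
    p: float           # NaN for untested (all-zero) genes
    fdr: float
    direction: Direction


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    factor_j = median over genes (positive in every sample) of
    count_gj / geometric-mean_g. Raises if no gene is positive everywhere.
    """
    mat = counts.values.astype(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with nonzero counts in all samples; "
                         "cannot compute size factors")
    log_mat = np.log(mat[all_pos])
    log_geo = log_mat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_mat - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM_gj = count_gj * 1e9 / (length_g * library-size_j)."""
    lengths = lengths.reindex(counts.index)
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts * 1e9 / np.outer(lengths.values, totals.values)


def _categorize(value: float) -> ExpressionCategory:
    if value >= 50:
        return ExpressionCategory.very_high
    if value >= 10:
        return ExpressionCategory.high
    if value >= 2:
        return ExpressionCategory.moderate
    if value >= FPKM_REMOVE_BELOW:
        return ExpressionCategory.low
    return ExpressionCategory.removed


def expression_summary(counts: pd.DataFrame, lengths: pd.Series,
                       per_sample: bool = True,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """FPKM table, per-sample (or mean-based) category labels, and the index of
    genes removed for having FPKM < 0.1 in every sample."""
    table = fpkm(counts, lengths)
    removed = table.index[(table < FPKM_REMOVE_BELOW).all(axis=1)]
    if per_sample:
        cats = table.map(lambda v: _categorize(v).value)
    else:
        mean = table.mean(axis=1)
        col = mean.map(lambda v: _categorize(v).value)
        cats = pd.DataFrame({s: col for s in table.columns})
    cats.loc[removed, :] = ExpressionCategory.removed.value
    return table, cats, removed


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted
    p-values; NaNs pass through untouched and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        res = np.empty(m)
        res[order] = adj
        out[mask] = res
    return out


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood, Poisson limit for tiny dispersion.

    k, mu: genes x samples; alpha: per-gene dispersion (var = mu + alpha mu^2).
    """
    mu = np.maximum(mu, 1e-300)
    alpha = alpha[:, None]
    pois = k * np.log(mu) - mu - gammaln(k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 / np.maximum(alpha, MIN_DISPERSION)
        nb = (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
              + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu)))
    ll = np.where(alpha < 1e-6, pois, nb)
    return ll.sum(axis=1)


def nb_test(cm: CountMatrix, mutant: str, wt: str = "WT",
            factors: pd.Series | None = None,
            genes: pd.Index | None = None) -> list[DEResult]:
    """Per-gene NB likelihood-ratio test of ``mutant`` vs ``wt``.

    Full model: separate group means; reduced: common mean; shared gene-wise
    MoM dispersion floored at 1e-8. log2FC uses a pseudo-mean
    c = 0.5 / median size factor. Genes with all-zero counts in both groups
    are reported ns with p = NaN and excluded from BH.
    """
    cols = cm.samples_for(mutant) + cm.samples_for(wt)
    if len(cm.samples_for(mutant)) < 2 or len(cm.samples_for(wt)) < 2:
        raise ValueError("need at least two replicates per condition")
    sub = cm.counts[cols] if genes is None else cm.counts.loc[genes, cols]
    if factors is None:
        factors = size_factors(cm.counts)
    sf = factors[cols].values
    raw = sub.values.astype(float)
    norm = raw / sf
    is_mut = np.array([cm.conditions[s] == mutant for s in cols])

    m_mut = norm[:, is_mut].mean(axis=1)
    m_wt = norm[:, ~is_mut].mean(axis=1)
    base_mean = norm.mean(axis=1)
    c = 0.5 / float(np.median(sf))
    log2fc = np.log2((m_mut + c) / (m_wt + c))

    # gene-wise MoM dispersion from within-condition residuals (df = n - 2)
    n = norm.shape[1]
    group_means = np.where(is_mut, m_mut[:, None], m_wt[:, None])
    ss_within = ((norm - group_means) ** 2).sum(axis=1)
    s2 = ss_within / max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - base_mean) / np.maximum(base_mean, 1e-300) ** 2
    alpha = np.clip(np.nan_to_num(alpha), MIN_DISPERSION, None)

    mu_full = group_means * sf
    mu_red = base_mean[:, None] * sf
    stat = 2.0 * (_nb_loglik(raw, mu_full, alpha) - _nb_loglik(raw, mu_red, alpha))
    stat = np.maximum(stat, 0.0)
    p = chi2.sf(stat, df=1)

    testable = raw.sum(axis=1) > 0
    p = np.where(testable, p, np.nan)
    fdr = bh_adjust(p)

    results = []
    for i, gene in enumerate(sub.index):
        if not testable[i]:
            direction = Direction.ns
        elif fdr[i] < DEFAULT_ALPHA and log2fc[i] >= 1:
            direction = Direction.up
        elif fdr[i] < DEFAULT_ALPHA and log2fc[i] <= -1:
            direction = Direction.down
        else:
            direction = Direction.ns
        results.append(DEResult(gene, float(base_mean[i]), float(log2fc[i]),
                                float(p[i]), float(fdr[i]), direction))
    return results


def call_degs(results: list[DEResult], alpha: float = DEFAULT_ALPHA,
              fc_min: float = DEFAULT_FC_MIN) -> tuple[set[str], set[str]]:
    """(up, down) gene sets at FDR < alpha and fold change >= fc_min (up) or
    <= 1/fc_min (down); both thresholds strict on FDR."""
    lfc_min = np.log2(fc_min)
    up = {r.gene for r in results
          if not np.isnan(r.fdr) and r.fdr < alpha and r.log2fc >= lfc_min}
    down = {r.gene for r in results
            if not np.isnan(r.fdr) and r.fdr < alpha and r.log2fc <= -lfc_min}
    return up, down


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.base_mean, r.log2fc, r.p, r.fdr, r.direction.value)
         for r in results],
        columns=["gene", "baseMean", "log2FC", "p", "fdr", "direction"],
    ).set_index("gene")
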