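"""Windowed genome statistics: variant-density tracks and the depth-of-coverage
ratio screen for large structural variants.

The screen takes non-overlapping 100-kb windows, computes
log10((mutant depth + eps) / (WT depth + eps)) per window, optionally smooths
with a k-window moving average, and flags sustained runs beyond a threshold —
a run of strongly negative windows marks a candidate large deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import VariantSet

DEFAULT_WINDOW_BP = 100_000
DEFAULT_DENSITY_WINDOW_BP = 5_000_000
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_DEL_THRESHOLD = -0.8
DEFAULT_MIN_RUN = 5
DEFAULT_SMOOTH_K = 5


@dataclass
class CoverageTrack:
    """Per-window mean depth for one sample; windows tile each chromosome left
    to right (the last window may be short)."""

    sample: str
    window: int
    depths: dict[str, np.ndarray]  # chrom -> per-window mean depth

    def grid_signature(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.depths.items()}


@dataclass
class WindowRatio:
    chrom: str
    index: int
    log10_ratio: float
    smoothed: float


@dataclass
class SVInterval:
    chrom: str
    start: int  # 0-based, bp
    end: int
    mean_ratio: float
    n_windows: int = field(default=0)


def variant_density(variants: VariantSet, chrom_lengths: dict[str, int],
                    window: int = DEFAULT_DENSITY_WINDOW_BP,
                    ) -> dict[str, dict[str, np.ndarray]]:
    """Per-window variant counts, SNPs and indels tallied separately.

    Returns {chrom: {'SNP': counts, 'INDEL': counts, 'ALL': counts}} with one
    entry per tiling window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // window))
        out[chrom] = {k: np.zeros(n_win, dtype=int) for k in ("SNP", "INDEL", "ALL")}
    for rec in variants:
        tracks = out.get(rec.chrom)
        if tracks is None:
            continue
        w = min(rec.pos0 // window, len(tracks["ALL"]) - 1)
        tracks["SNP" if rec.is_snp else "INDEL"][w] += 1
        tracks["ALL"][w] += 1
    return out


def moving_average(values: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average with edge windows shrunk to the available span."""
    if k <= 1:
        return values.astype(float)
    kernel = np.ones(k)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return sums / counts


def depth_ratio(mut: CoverageTrack, wt: CoverageTrack,
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                smooth_k: int = DEFAULT_SMOOTH_K) -> list[WindowRatio]:
    """log10((mut + eps) / (wt + eps)) per window, with moving-average
    smoothing over ``smooth_k`` windows (1 disables smoothing)."""
    if mut.window != wt.window or mut.grid_signature() != wt.grid_signature():
        raise ValueError(
            f"mismatched window grids: {mut.sample} {mut.grid_signature()} vs "
            f"{wt.sample} {wt.grid_signature()}"
        )
    out: list[WindowRatio] = []
    for chrom in wt.depths:
        ratios = np.log10((mut.depths[chrom] + pseudocount)
                          / (wt.depths[chrom] + pseudocount))
        smoothed = moving_average(ratios, smooth_k)
        out.extend(WindowRatio(chrom, i, float(r), float(s))
                   for i, (r, s) in enumerate(zip(ratios, smoothed)))
    return out


def flag_sv_windows(ratios: list[WindowRatio], window: int = DEFAULT_WINDOW_BP,
                    threshold: float = DEFAULT_DEL_THRESHOLD,
                    min_run: int = DEFAULT_MIN_RUN,
                    use_smoothed: bool = True) -> list[SVInterval]:
    """Maximal runs of >= min_run consecutive windows with (smoothed) ratio
    beyond ``threshold``, merged into intervals.

    A negative threshold flags windows with ratio <= threshold (deletions); a
    positive one flags ratio >= threshold (duplications).
    """
    by_chrom: dict[str, list[WindowRatio]] = {}
    for wr in ratios:
        by_chrom.setdefault(wr.chrom, []).append(wr)
    flagged: list[SVInterval] = []
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda r: r.index)
        vals = np.array([r.smoothed if use_smoothed else r.log10_ratio for r in rows])
        hit = vals <= threshold if threshold < 0 else vals >= threshold
        i = 0
        while i < len(hit):
            if not hit[i]:
                i += 1
                continue
            j = i
            while j < len(hit) and hit[j]:
                j += 1
            if j - i >= min_run:
                flagged.append(SVInterval(
                    chrom=chrom,
                    start=rows[i].index * window,
                    end=rows[j - 1].index * window + window,
                    mean_ratio=float(vals[i:j].mean()),
                    n_windows=j - i,
                ))
            i = j
    return flagged


def plot_depth_ratio(ratios_by_sample: dict[str, list[WindowRatio]],
                     window: int, path: str) -> None:
    """One panel per sample: per-window log10 depth ratio along the genome,
    A-subgenome chromosomes in red, B-subgenome in skyblue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(ratios_by_sample)
    fig, axes = plt.subplots(n, 1, figsize=(10, 2.2 * n), squeeze=False)
    for ax, (sample, ratios) in zip(axes.ravel(), ratios_by_sample.items()):
        offset = 0
        for chrom in sorted({r.chrom for r in ratios}):
            rows = sorted((r for r in ratios if r.chrom == chrom), key=lambda r: r.index)
            x = offset + np.arange(len(rows)) * window / 1e6
            color = "red" if chrom.startswith("A") else "skyblue"
            ax.plot(x, [r.smoothed for r in rows], color=color, lw=0.8, label=chrom)
            offset = x[-1] + window / 1e6 if len(rows) else offset
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_ylabel("log10 ratio")
        ax.set_title(sample, fontsize=9)
    axes.ravel()[-1].set_xlabel("position (Mb, concatenated)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
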