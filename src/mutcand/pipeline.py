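"""End-to-end orchestration: synthetic scenario construction and the full
candidate-gene discovery run.

A scenario plants three kinds of genes: true candidates (a large-effect
variant shared by both mutants AND a concordant expression change), decoys
carrying only the variant, and decoys carrying only the expression change.
The pipeline must return exactly the true candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from . import __version__
from .dge import CountMatrix, call_degs, expression_summary, nb_test, size_factors
from .effects import (DEFAULT_LARGE_EFFECT, ElementIndex, INTEGRATION_LARGE_EFFECT,
                      annotate_variants, large_effect_genes, shared_gene_venn)
from .enrichment import observed_expected_by_class
from .genome import Genome, TranscriptModel
from .integrate import candidate_genes, shared_degs
from .synthetic import (MUTANTS, SyntheticTruth, plant_variants, simulate_counts,
                        simulate_depth, simulate_genome)
from .variants import (VariantSet, apply_hard_filter, normalize_set,
                       private_variants, shared_variants)
from .windows import (CoverageTrack, DEFAULT_DEL_THRESHOLD, DEFAULT_MIN_RUN,
                      depth_ratio, flag_sv_windows, variant_density)

DEFAULT_EFFECT_CYCLE = ("frameshift", "missense", "stop_gained",
                        "splice_donor", "start_lost")


@dataclass
class ScenarioConfig:
    """Stated world of one synthetic run (defaults mirror the emulated study:
    a WT + two-mutant trio, 3 replicates, ~8x depth, planted |log2FC| = 2)."""

    n_chrom: int = 2
    chrom_len: int = 2_500_000
    n_genes: int = 80
    n_shared: int = 300
    n_private: dict[str, int] = field(default_factory=lambda: {"mut1": 150, "mut2": 150})
    fail_fraction: float = 0.1
    n_candidates: int = 5
    n_effect_only: int = 5
    n_de_only: int = 5
    effect_cycle: tuple[str, ...] = DEFAULT_EFFECT_CYCLE
    # the end-to-end scenario is a wiring test: planted expression changes are
    # strong positive controls (8-fold) so that a recovery failure indicates a
    # pipeline defect, not an unlucky NB draw; marginal-power behaviour is
    # measured separately at |log2FC| = 2
    planted_lfc: float = 3.0
    dispersion: float = 0.05
    mean_depth: float = 8.0
    depth_window: int = 100_000
    noise_cv: float = 0.1
    deletions: dict[str, list[tuple]] = field(default_factory=dict)


@dataclass
class Scenario:
    config: ScenarioConfig
    seed: int
    genome: Genome
    models: list[TranscriptModel]
    variant_sets: dict[str, VariantSet]
    tracks: dict[str, CoverageTrack]
    counts: CountMatrix
    truth: SyntheticTruth


def build_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    cfg = config or ScenarioConfig()
    genome, models = simulate_genome(cfg.n_chrom, cfg.chrom_len, cfg.n_genes,
                                     seed=seed)
    rng = np.random.default_rng(seed + 1)
    gene_ids = [tx.gene_id for tx in models]
    n_planted = cfg.n_candidates + cfg.n_effect_only + cfg.n_de_only
    if n_planted > len(gene_ids):
        raise ValueError("more planted genes requested than genes simulated")
    chosen = list(rng.choice(gene_ids, size=n_planted, replace=False))
    cand = chosen[:cfg.n_candidates]
    effect_only = chosen[cfg.n_candidates:cfg.n_candidates + cfg.n_effect_only]
    de_only = chosen[cfg.n_candidates + cfg.n_effect_only:]

    planted_effects = [(g, cfg.effect_cycle[i % len(cfg.effect_cycle)])
                       for i, g in enumerate(cand + effect_only)]
    de_spec = {}
    for i, g in enumerate(cand + de_only):
        lfc = cfg.planted_lfc if i % 2 == 0 else -cfg.planted_lfc
        de_spec[g] = {m: lfc for m in MUTANTS}

    sets, truth = plant_variants(genome, models, cfg.n_shared, cfg.n_private,
                                 planted_effects, seed=seed + 2,
                                 fail_fraction=cfg.fail_fraction)
    truth.planted_de_genes = de_spec
    tracks, deletions = simulate_depth(genome, cfg.mean_depth, cfg.depth_window,
                                       cfg.deletions, cfg.noise_cv, seed=seed + 3)
    truth.planted_deletions = {s: list(d) for s, d in deletions.items()}
    counts = simulate_counts(models, de_spec, cfg.dispersion, seed=seed + 4)
    return Scenario(cfg, seed, genome, models, sets, tracks, counts, truth)


def run_pipeline(scn: Scenario, n_resamples: int = 20,
                 enrichment_seed: int | None = None,
                 run_enrichment: bool = True) -> dict[str, Any]:
    """Execute every stage on a scenario and return all intermediate and final
    results, keyed by stage."""
    genome, models = scn.genome, scn.models

    # variant sets: hard-filter, normalize, subtract
    filtered = {s: normalize_set(apply_hard_filter(vs), genome)
                for s, vs in scn.variant_sets.items()}
    private = {m: private_variants(filtered[m], filtered["WT"]) for m in MUTANTS}
    shared_priv = shared_variants(private["mut1"], private["mut2"])

    # consequence annotation on the private sets
    effects = {m: annotate_variants(private[m], models, genome) for m in MUTANTS}
    le = {m: large_effect_genes(effects[m], INTEGRATION_LARGE_EFFECT)
          for m in MUTANTS}
    le_strict = {m: large_effect_genes(effects[m], DEFAULT_LARGE_EFFECT)
                 for m in MUTANTS}
    venn = shared_gene_venn(le["mut1"]["ALL"], le["mut2"]["ALL"])

    # windowed statistics
    chrom_lengths = {c: genome.length(c) for c in genome.chroms}
    density = {m: variant_density(private[m], chrom_lengths) for m in MUTANTS}
    ratios = {m: depth_ratio(scn.tracks[m], scn.tracks["WT"]) for m in MUTANTS}
    sv_flags = {m: flag_sv_windows(ratios[m], scn.tracks[m].window,
                                   DEFAULT_DEL_THRESHOLD, DEFAULT_MIN_RUN)
                for m in MUTANTS}

    # observed/expected element enrichment
    enrich = {}
    if run_enrichment:
        index = ElementIndex(genome, models)
        eseed = scn.seed + 10 if enrichment_seed is None else enrichment_seed
        enrich = {m: observed_expected_by_class(private[m], genome, index,
                                                n_resamples=n_resamples,
                                                seed=eseed)
                  for m in MUTANTS}

    # differential expression on the FPKM-filtered universe
    _, categories, removed = expression_summary(scn.counts.counts,
                                                scn.counts.lengths)
    universe = scn.counts.counts.index.difference(removed)
    factors = size_factors(scn.counts.counts)
    de = {m: nb_test(scn.counts, m, "WT", factors=factors, genes=universe)
          for m in MUTANTS}
    degs = {m: call_degs(de[m]) for m in MUTANTS}
    sh_up, sh_down, discordant = shared_degs(degs["mut1"], degs["mut2"])

    candidates = candidate_genes(sh_up, sh_down, effects, de,
                                 categories=INTEGRATION_LARGE_EFFECT,
                                 known_genes=set(tx.gene_id for tx in models))
    manifest = {
        "tool": "mutcand",
        "version": __version__,
        "seed": scn.seed,
        "config": asdict(scn.config),
        "counts": {
            "variants_raw": {s: vs.counts() for s, vs in scn.variant_sets.items()},
            "variants_filtered": {s: vs.counts() for s, vs in filtered.items()},
            "private": {m: private[m].counts() for m in MUTANTS},
            "shared_private": shared_priv.counts(),
            "large_effect_genes": {m: {k: len(v) for k, v in le[m].items()}
                                   for m in MUTANTS},
            "degs": {m: {"up": len(degs[m][0]), "down": len(degs[m][1])}
                     for m in MUTANTS},
            "shared_degs": {"up": len(sh_up), "down": len(sh_down),
                            "discordant": len(discordant)},
            "sv_flags": {m: len(sv_flags[m]) for m in MUTANTS},
            "genes_removed_fpkm": int(len(removed)),
            "candidates": int(candidates["Gene_ID"].nunique()),
        },
    }
    return {
        "filtered": filtered,
        "private": private,
        "shared_private": shared_priv,
        "effects": effects,
        "large_effect": le,
        "large_effect_strict": le_strict,
        "venn": venn,
        "density": density,
        "depth_ratios": ratios,
        "sv_flags": sv_flags,
        "enrichment": enrich,
        "expression_categories": categories,
        "removed_genes": removed,
        "de": de,
        "degs": degs,
        "shared_up": sh_up,
        "shared_down": sh_down,
        "discordant": discordant,
        "candidates": candidates,
        "manifest": manifest,
    }


def manifest_json(results: dict[str, Any]) -> str:
    return json.dumps(results["manifest"], indent=1, default=str)
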