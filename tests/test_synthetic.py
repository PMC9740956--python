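"""Generator invariants: gene-model validity, determinism, planted-truth
consistency, depth and count construction."""

import numpy as np
import pytest

from mutcand import plant_variants, simulate_counts, simulate_depth, simulate_genome
from mutcand.genome import translate
from mutcand.io import write_fasta, write_gff3

from _oracles import rebuild_mutant_cds


class TestSimulateGenome:
    def test_gene_models_valid(self, small_genome):
        genome, models = small_genome
        assert len(models) == 8
        spans = sorted((tx.chrom, tx.start, tx.end) for tx in models)
        for (c1, a1, b1), (c2, a2, b2) in zip(spans, spans[1:]):
            assert c1 != c2 or b1 <= a2, "gene spans overlap"
        for tx in models:
            assert len(tx.exons) >= 2
            assert tx.cds_len % 3 == 0
            cds = tx.coding_sequence(genome)
            assert cds.startswith("ATG")
            prot = translate(cds)
            assert prot.endswith("*") and "*" not in prot[:-1]
            # exon/CDS/UTR consistency: CDS+UTRs tile the exons
            exonic = {p for a, b in tx.exons for p in range(a, b)}
            pieces = {p for ivs in (tx.cds, tx.utr5, tx.utr3)
                      for a, b in ivs for p in range(a, b)}
            assert exonic == pieces
            # canonical splice dinucleotides
            for (a, b), kind in tx.splice_sites():
                dinuc = genome.fetch(tx.chrom, a, b)
                if tx.strand == "-":
                    from mutcand.genome import revcomp
                    dinuc = revcomp(dinuc)
                assert dinuc == ("GT" if kind == "splice_donor" else "AG")

    def test_deterministic_output_files(self, tmp_path):
        files = []
        for rep in range(2):
            genome, models = simulate_genome(1, 100_000, 10, seed=1)
            fa, gff = tmp_path / f"g{rep}.fa", tmp_path / f"g{rep}.gff3"
            write_fasta(genome, str(fa))
            write_gff3(models, str(gff))
            files.append((fa.read_bytes(), gff.read_bytes()))
        assert files[0] == files[1]

    def test_both_strands_represented(self):
        _, models = simulate_genome(2, 200_000, 40, seed=7)
        strands = {tx.strand for tx in models}
        assert strands == {"+", "-"}

    def test_impossible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_genome(1, 50_000, 100, seed=0)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="50 kb"):
            simulate_genome(1, 10_000, 1, seed=0)


class TestPlantVariants:
    def test_vcf_ref_matches_genome(self, trio):
        genome, _, sets, _ = trio
        for vs in sets.values():
            for rec in vs:
                assert genome.fetch(rec.chrom, rec.pos0,
                                    rec.pos0 + len(rec.ref)) == rec.ref

    def test_shared_variants_in_all_three(self, trio):
        _, _, sets, truth = trio
        for key in truth.shared_variant_keys:
            assert all(key in sets[s] for s in ("WT", "mut1", "mut2"))

    def test_truth_enumerates_exactly_the_planted_deviations(self, trio):
        _, _, sets, truth = trio
        for m in ("mut1", "mut2"):
            extra = sets[m].keys - sets["WT"].keys
            assert extra == set(truth.planted_private_variants[m])

    def test_degenerate_no_private_no_effects(self, small_genome):
        genome, models = small_genome
        sets, _ = plant_variants(genome, models, n_shared=20,
                                 n_private={}, seed=9)
        assert sets["WT"].keys == sets["mut1"].keys == sets["mut2"].keys

    def test_planted_frameshift_is_one_base_insertion_in_cds(self, trio):
        genome, models, sets, truth = trio
        fs_genes = [g for g, cat in truth.planted_large_effect_genes["mut1"].items()
                    if cat == "frameshift"]
        assert fs_genes
        tx = next(t for t in models if t.gene_id == fs_genes[0])
        recs = [r for r in sets["mut1"]
                if r.key in truth.planted_private_variants["mut1"]
                and any(a <= r.pos0 < b for a, b in tx.cds)]
        assert len(recs) == 1
        rec = recs[0]
        assert len(rec.ref) == 1 and len(rec.alt) == 2

    def test_planted_stop_gained_retranslates_to_premature_stop(self):
        genome, models = simulate_genome(1, 100_000, 6, seed=5)
        sets, truth = plant_variants(
            genome, models, 0, {}, [(models[2].gene_id, "stop_gained")], seed=5)
        (key,) = truth.planted_private_variants["mut1"]
        tx = models[2]
        chrom, pos, ref, alt = key
        mutant_cds = rebuild_mutant_cds(genome, tx, pos - 1, ref, alt)
        prot = translate(mutant_cds)
        assert "*" in prot[:-1], "no premature stop after re-translation"

    def test_unknown_gene_or_category_rejected(self, small_genome):
        genome, models = small_genome
        with pytest.raises(ValueError, match="unknown gene"):
            plant_variants(genome, models, 0, {}, [("nope", "frameshift")], seed=0)
        with pytest.raises(ValueError, match="category"):
            plant_variants(genome, models, 0, {},
                           [(models[0].gene_id, "upstream")], seed=0)


class TestSimulateDepth:
    def test_zero_noise_exact_mean(self, small_genome):
        genome, _ = small_genome
        tracks, _ = simulate_depth(genome, mean_depth=30, window=10_000,
                                   noise_cv=0.0, seed=0)
        for track in tracks.values():
            for vals in track.depths.values():
                assert np.all(vals == 30.0)

    def test_deletion_halves_depth_exactly(self, small_genome):
        genome, _ = small_genome
        dels = {"mut1": [("A01", 20_000, 60_000, 0.5)]}
        tracks, _ = simulate_depth(genome, 30, 10_000, dels, noise_cv=0.0, seed=0)
        vals = tracks["mut1"].depths["A01"]
        assert np.all(vals[2:6] == 15.0)
        assert np.all(vals[:2] == 30.0) and np.all(vals[6:] == 30.0)

    def test_deterministic(self, small_genome):
        genome, _ = small_genome
        t1, _ = simulate_depth(genome, 30, 10_000, noise_cv=0.1, seed=4)
        t2, _ = simulate_depth(genome, 30, 10_000, noise_cv=0.1, seed=4)
        for s in t1:
            for c in t1[s].depths:
                assert np.array_equal(t1[s].depths[c], t2[s].depths[c])

    def test_window_larger_than_chromosome_raises(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError, match="larger than chromosome"):
            simulate_depth(genome, 30, 10_000_000)

    def test_overlapping_deletions_rejected(self, small_genome):
        genome, _ = small_genome
        dels = {"mut1": [("A01", 0, 50_000, 0.0), ("A01", 40_000, 90_000, 0.5)]}
        with pytest.raises(ValueError, match="overlap"):
            simulate_depth(genome, 30, 10_000, dels)


class TestSimulateCounts:
    def test_zero_dispersion_is_poisson(self, small_genome):
        _, models = small_genome
        lib = {f"{c}_{r}": 1.0 for c in ("WT", "mut1", "mut2")
               for r in range(1, 201)}
        cm = simulate_counts(models, dispersion=0.0, n_reps=200,
                             lib_sizes=lib, seed=2)
        # Poisson limit: per-gene variance/mean ~ 1 across 200 replicates
        wt = cm.counts[[c for c in cm.counts.columns if c.startswith("WT")]]
        ratios = wt.var(axis=1) / wt.mean(axis=1)
        assert np.all((ratios > 0.75) & (ratios < 1.3))

    def test_null_fold_changes_track_library_sizes(self, small_genome):
        _, models = small_genome
        lib = {f"{c}_{r}": (1.0 if c == "WT" else 1.5)
               for c in ("WT", "mut1", "mut2") for r in (1, 2, 3)}
        cm = simulate_counts(models * 150, de_spec={}, dispersion=0.05,
                             lib_sizes=lib, seed=3)
        wt_cols = [c for c in cm.counts.columns if c.startswith("WT")]
        m1_cols = [c for c in cm.counts.columns if c.startswith("mut1")]
        ratio = (cm.counts[m1_cols].values.mean()
                 / cm.counts[wt_cols].values.mean())
        assert abs(ratio - 1.5) < 0.1

    def test_planted_fold_change_recovered(self, small_genome):
        _, models = small_genome
        gene = models[0].gene_id
        folds = []
        for seed in range(200):
            cm = simulate_counts(models, {gene: {"mut1": 2.0, "mut2": 2.0}},
                                 dispersion=0.05, seed=seed,
                                 lib_sizes={f"{c}_{r}": 1.0 for c in
                                            ("WT", "mut1", "mut2")
                                            for r in (1, 2, 3)})
            row = cm.counts.loc[gene]
            wt = row[[c for c in row.index if c.startswith("WT")]].mean()
            m1 = row[[c for c in row.index if c.startswith("mut1")]].mean()
            folds.append(m1 / wt)
        assert abs(np.mean(folds) - 4.0) < 0.25

    def test_negative_dispersion_rejected(self, small_genome):
        _, models = small_genome
        with pytest.raises(ValueError, match="dispersion"):
            simulate_counts(models, dispersion=-1)
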