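import pytest

from mutcand import plant_variants, simulate_genome
from mutcand.variants import apply_hard_filter, normalize_set, private_variants

ALL_CATEGORIES = ("frameshift", "missense", "stop_gained", "splice_donor",
                  "splice_acceptor", "start_lost", "stop_lost", "synonymous")


@pytest.fixture(scope="session")
def small_genome():
    """One 120-kb chromosome with 8 genes."""
    return simulate_genome(1, 120_000, 8, seed=1)


@pytest.fixture(scope="session")
def trio():
    """A WT + two-mutant trio with one planted variant per effect category
    (in both mutants) plus background/private variants."""
    genome, models = simulate_genome(1, 300_000, 12, seed=3)
    effects = [(models[i].gene_id, cat) for i, cat in enumerate(ALL_CATEGORIES)]
    sets, truth = plant_variants(genome, models, n_shared=60,
                                 n_private={"mut1": 40, "mut2": 50},
                                 planted_effects=effects, seed=5)
    return genome, models, sets, truth


@pytest.fixture(scope="session")
def trio_private(trio):
    genome, models, sets, truth = trio
    filt = {s: normalize_set(apply_hard_filter(v), genome)
            for s, v in sets.items()}
    priv = {m: private_variants(filt[m], filt["WT"]) for m in ("mut1", "mut2")}
    return genome, models, priv, truth
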