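import numpy as np
import pytest

import gsascore as gs


@pytest.fixture(scope="session")
def small_data():
    """120 samples, 4 disjoint sets of 10 genes + 10 background genes, SNR 5."""
    cfg = gs.GeneratorConfig(
        n_samples=120, n_sets=4, genes_per_set=10, n_background_genes=10, snr=5.0, seed=42
    )
    return gs.generate(cfg)


@pytest.fixture(scope="session")
def quick_cfg():
    return gs.TrainingConfig(
        step1_epochs=60, step2_epochs=40, step3_epochs=60, batch_size=32, seed=7
    )


@pytest.fixture(scope="session")
def small_model(small_data, quick_cfg):
    x, col, _ = small_data
    model, trace = gs.train_full(col, x, None, quick_cfg)
    return model, trace


@pytest.fixture(scope="session")
def small_scores(small_data, small_model):
    x, _, _ = small_data
    model, _ = small_model
    return gs.compute_gsas(model, x)


@pytest.fixture
def toy_collection():
    sets = (
        gs.GeneSet("S1", "first", ("g1", "g2", "g3")),
        gs.GeneSet("S2", "second", ("g3", "g4")),
    )
    return gs.GeneSetCollection(sets)


def random_expression(n_samples, gene_ids, seed=0, standardized=False):
    rng = np.random.default_rng(seed)
    x = gs.ExpressionMatrix(
        rng.normal(size=(n_samples, len(gene_ids))),
        tuple(f"s{i}" for i in range(n_samples)),
        tuple(gene_ids),
    )
    return gs.standardize(x) if standardized else x
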