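import pytest

import pdacpheno as pp


@pytest.fixture(scope="session")
def cfg():
    return pp.AnalysisConfig()


@pytest.fixture(scope="session")
def small_table():
    """2,000 tiles from the default 4-profile catalog, default noise."""
    table, gt = pp.generate_tile_table(n_per_phenotype=500, seed=7)
    return table, gt


@pytest.fixture(scope="session")
def recovery_fit():
    """The 5,000-tile recovery experiment: log2 → PCA → silhouette-selected
    k-means on the default catalog at default noise, shared across tests."""
    table, gt = pp.generate_tile_table(n_per_phenotype=1250, seed=42)
    model = pp.TilePhenotypeModel(table)
    res = model.fit()
    return table, gt, res


@pytest.fixture()
def square_stack():
    """Noise-free slide stack: four 200×200-px regions (one per phenotype)
    aligned to the 100-px tile grid, identity transforms."""
    layout = {
        f"region_{p.name}": (
            (100 + (i % 2) * 300, 100 + (i // 2) * 300,
             300 + (i % 2) * 300, 300 + (i // 2) * 300),
            p.name,
        )
        for i, p in enumerate(pp.DEFAULT_PROFILES)
    }
    stack, gt = pp.generate_slide_stack(pp.DEFAULT_PROFILES, layout,
                                        mpp=2.0, seed=3, margin=80)
    return stack, gt, layout
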