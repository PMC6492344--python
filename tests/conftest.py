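import numpy as np
import pandas as pd
import pytest

import lymphomap as lm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale synthetic cohort: 800 genes, 4 modules, 4 classes."""
    cfg = lm.default_config(
        seed=5,
        n_genes=800,
        n_modules=4,
        genes_per_module=40,
        class_definitions=[
            ("c1", frozenset("AB"), 20),
            ("c2", frozenset("CD"), 20),
            ("c3", frozenset("AC"), 20),
            ("c4", frozenset("BD"), 20),
        ],
        module_betas={"D": 0.7},
        censor_rate=0.2,
    )
    matrix, truth = lm.simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """Trained 10x10 SOM with portraits and group means for the cohort."""
    cfg, matrix, truth = small_cohort
    pre = lm.preprocess(matrix)
    model = lm.train_som(pre, rows=10, cols=10, seed=5, epochs=15)
    portraits = lm.sample_portraits(model, pre)
    classes = pd.Series(truth.sample_class)
    groups = {
        c: lm.mean_portrait(
            [portraits[s] for s in classes.index[classes == c]], c
        )
        for c in sorted(classes.unique())
    }
    return pre, model, portraits, groups


def random_portrait(rng, rows=6, cols=6, pid="p"):
    return lm.Portrait(
        sample_or_group_id=pid,
        values=rng.normal(size=rows * cols),
        grid_rows=rows,
        grid_cols=cols,
    )
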