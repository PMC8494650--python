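import numpy as np
import pandas as pd
import pytest

import isoshift as iso


def make_matrix(values, cell_ids=None, feature_ids=None, **kwargs):
    values = np.asarray(values, dtype=float)
    cells = cell_ids or [f"c{i}" for i in range(values.shape[0])]
    feats = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    return iso.ExpressionMatrix(values, pd.Index(cells), pd.Index(feats), **kwargs)


@pytest.fixture
def two_class_config():
    """Two classes x one cluster each, enough cells for stable tests."""
    def _make(seed=0, n_cells=250, n_genes=60, effects=()):
        return iso.SimulationConfig(
            seed=seed,
            ontology={
                "glut": {"Lg": {"c_glut": n_cells}},
                "gaba": {"Lb": {"c_gaba": n_cells}},
            },
            n_genes=n_genes,
            planted_effects=list(effects),
        )
    return _make


@pytest.fixture
def simulated(two_class_config):
    cfg = two_class_config(seed=42)
    ann = iso.simulate_annotation(cfg)
    m, cells, truth = iso.simulate_counts(cfg, ann)
    return cfg, ann, m, cells, truth
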