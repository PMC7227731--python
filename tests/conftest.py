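import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sfnull as sf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(coords, tissues=None, networks=None, prefix="s"):
    """Small hand-built sample table for toy fixtures."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != 3:
        coords = np.column_stack([coords, np.zeros((len(coords), 3 - coords.shape[1]))])
    n = len(coords)
    ids = np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    if tissues is None:
        tissues = [f"t{i}" for i in range(n)]
    if networks is None:
        networks = np.zeros(n, dtype=int)
    return sf.SampleTable(ids, coords, np.asarray(tissues, dtype=object), networks)


@pytest.fixture(scope="session")
def toy_factory():
    return make_table


@pytest.fixture(scope="session")
def cortex_structured():
    """Small cortex with strong 20 mm spatial autocorrelation (shared)."""
    cfg = sf.SyntheticConfig(
        n_samples=300, n_genes=500, gene_blocks=((500, 20.0),), seed=11
    )
    table = sf.generate_cortex_geometry(cfg)
    expr = sf.generate_expression(table, cfg)
    return cfg, table, expr


@pytest.fixture(scope="session")
def cortex_unstructured():
    """Small cortex whose expression is pure i.i.d. noise (shared)."""
    cfg = sf.SyntheticConfig(
        n_samples=300, n_genes=500, gene_blocks=((500, 0.0),), seed=11
    )
    table = sf.generate_cortex_geometry(cfg)
    expr = sf.generate_expression(table, cfg)
    return cfg, table, expr
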