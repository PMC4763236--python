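import dataclasses

import numpy as np
import pandas as pd
import pytest

from richdet import synthetic as syn
from richdet.weights import build_distance_band_weights


@pytest.fixture(scope="session")
def small_landscape():
    """400-unit three-region landscape with weights, env and richness."""
    cfg = dataclasses.replace(syn.GeneratorConfig(), n_units=400, seed=11)
    counties = syn.generate_counties(cfg)
    w = build_distance_band_weights(
        counties[["x_km", "y_km"]].to_numpy(),
        cfg.spatial_range_km,
        ids=counties["id"].to_numpy(),
    )
    env = syn.generate_env_fields(counties, cfg, w)
    richness = syn.generate_richness(counties, env, w, cfg)
    return cfg, counties, w, env, richness


@pytest.fixture
def grid_weights():
    """5x5 lattice, 60 km spacing, 100 km band (rook+diagonal at 84.85)."""
    xs, ys = np.meshgrid(np.arange(5) * 60.0, np.arange(5) * 60.0)
    cents = np.column_stack([xs.ravel(), ys.ravel()])
    return cents, build_distance_band_weights(cents, 100.0)


def dense_morans_i(values: np.ndarray, w_dense: np.ndarray) -> float:
    """Naive O(n^2) double-sum Moran's I oracle."""
    z = values - values.mean()
    n = len(z)
    s0 = w_dense.sum()
    num = sum(
        w_dense[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return float(n / s0 * num / (z @ z))
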