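"""Shared fixtures: one small synthetic world reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from walkability import (build_index_table, compute_components,
                         generate_landscape, generate_survey)
from walkability.grids import GridLayer
from walkability.synthetic import SyntheticScenario


@pytest.fixture(scope="session")
def scenario():
    """Moderate default world: 5 km x 5 km at 25 m cells, 400 units."""
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def landscape(scenario):
    return generate_landscape(scenario)


@pytest.fixture(scope="session")
def components_150(landscape):
    return compute_components(landscape, 150.0)


@pytest.fixture(scope="session")
def index_150(components_150):
    return build_index_table(components_150)


@pytest.fixture(scope="session")
def survey_tables(scenario, index_150):
    return generate_survey(scenario, index_150)


@pytest.fixture()
def small_grid():
    """10x10 grid of 25 m cells with a reproducible random surface."""
    rng = np.random.default_rng(42)
    return GridLayer((0.0, 0.0), 25.0, rng.uniform(0, 5, size=(10, 10)),
                     "value")


def focal_mean_loop_oracle(layer: GridLayer, radius_m: float) -> np.ndarray:
    """Brute-force per-cell focal mean with centre-in-circle membership.

    Iterates kernel offsets in the same lexicographic (dy, dx) order as a
    sequential left-fold, making float sums comparable bit-for-bit.
    """
    vals = np.asarray(layer.values, dtype=float)
    nr, nc = vals.shape
    r_cells = int(np.floor(radius_m / layer.cell_m))
    offsets = [(dy, dx)
               for dy in range(-r_cells, r_cells + 1)
               for dx in range(-r_cells, r_cells + 1)
               if (dx * dx + dy * dy) * layer.cell_m ** 2 <= radius_m ** 2]
    out = np.empty_like(vals)
    for i in range(nr):
        for j in range(nc):
            acc, cnt = 0.0, 0
            for dy, dx in offsets:
                ii, jj = i + dy, j + dx
                if 0 <= ii < nr and 0 <= jj < nc:
                    acc += vals[ii, jj]
                    cnt += 1
            out[i, j] = acc / cnt
    return out


def pearson_r_direct(x, y) -> float:
    """Textbook Pearson correlation, independent of numpy.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm * xm).sum() * (ym * ym).sum()))
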