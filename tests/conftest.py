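"""Shared fixtures: small synthetic landscapes and extracted samples.

Everything is generated programmatically and seeded; the heavier fixtures
are module/session-scoped so the fit runs are shared across tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from maxsdm import (
    SyntheticConfig,
    background_samples,
    extract_samples,
    gen_climate_stack,
    sample_occurrences,
    true_suitability,
)
from maxsdm.raster import RasterGrid, RasterStack
from maxsdm.samples import SampleMatrix


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A 6-variable, 40x40 landscape with two drivers; fast to fit."""
    defaults = dict(
        nrows=40,
        ncols=40,
        n_variables=6,
        n_occurrences=60,
        seed=seed,
        correlation_plan=[("bio1", "bio6", 0.9)],
        responses={"bio1": (22.0, 28.0, 1.5), "bio4": (70.0, 160.0, 12.0)},
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_stack(small_cfg):
    return gen_climate_stack(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_stack):
    return true_suitability(small_stack, small_cfg)


@pytest.fixture(scope="session")
def small_presence(small_cfg, small_stack, small_truth) -> SampleMatrix:
    occ = sample_occurrences(small_truth, small_cfg.n_occurrences, small_cfg.seed)
    return extract_samples(small_stack, occ)


@pytest.fixture(scope="session")
def small_background(small_stack) -> SampleMatrix:
    return background_samples(small_stack, n_background=600, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_stack) -> SampleMatrix:
    matrix, idx = small_stack.to_matrix()
    return SampleMatrix(
        pd.DataFrame(matrix, columns=small_stack.names), "background", cell_indices=idx
    )


def make_grid(values, xll=0.0, yll=0.0, cellsize=1.0, nodata=-9999.0) -> RasterGrid:
    values = np.asarray(values, dtype=float)
    return RasterGrid(
        nrows=values.shape[0],
        ncols=values.shape[1],
        xll=xll,
        yll=yll,
        cellsize=cellsize,
        nodata=nodata,
        values=values,
    )


def make_stack(named_values, **kw) -> RasterStack:
    return RasterStack({n: make_grid(v, **kw) for n, v in named_values.items()})
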