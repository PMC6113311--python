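"""Shared fixtures.

The Monte Carlo calibration artifacts are expensive, so one response matrix
and one depth-response table are computed once per session at fixed seeds
and shared by the calibration, reconstruction and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from subslice.calibration import (
    DepthResponseTable,
    ResponseMatrix,
    build_response_matrix,
    compute_depth_response,
    invert_response,
    PUBLISHED_RESPONSE_MATRIX,
)
from subslice.phantom import three_cuboid_model


@pytest.fixture(scope="session")
def published_matrix() -> ResponseMatrix:
    """The published (1.0, 1.4) keV / 12.5 nm response matrix."""
    A = ResponseMatrix(energies=(1.0, 1.4), dz=12.5, A=PUBLISHED_RESPONSE_MATRIX.copy())
    return invert_response(A)


@pytest.fixture(scope="session")
def mc_matrix() -> ResponseMatrix:
    """Response matrix calibrated with this package's Monte Carlo."""
    rng = np.random.default_rng(20180828)
    A = build_response_matrix(1.0, 1.4, n_electrons=60_000, rng=rng)
    return invert_response(A)


@pytest.fixture(scope="session")
def depth_table() -> DepthResponseTable:
    """Depth response over 0.8-1.6 keV for four 12.5-nm layers."""
    rng = np.random.default_rng(314159)
    return compute_depth_response(
        np.round(np.arange(0.8, 1.65, 0.1), 1),
        n_layers=4,
        n_electrons=25_000,
        rng=rng,
    )


@pytest.fixture()
def compact_three_cuboid():
    """Three-cuboid sensitivity phantom at reduced lateral scale."""
    return three_cuboid_model(
        cuboid_xy=250.0, x_gap=125.0, block_extent=(1500.0, 750.0, 200.0)
    )
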