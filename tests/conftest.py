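"""Shared fixtures: synthetic stacks and lineage records built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import lineagefish as lf


def make_calibration_stack(
    n_spots: int = 50,
    intensity_cv: float = 0.2,
    noise: lf.NoiseModel | None = None,
    seed: int = 100,
    channel: str = "egl-1",
):
    """A sparse lattice of singleton-mRNA cells: ideal SI_Spot material."""
    grid = lf.VoxelGrid(shape=(24, 220, 220))
    ex, ey, ez = grid.extent
    cells = []
    k = 0
    for z in (0.35 * ez, 0.65 * ez):
        for y in np.arange(2.0, ey - 2.0, 3.2):
            for x in np.arange(2.0, ex - 2.0, 3.2):
                if k >= n_spots:
                    break
                k += 1
                cells.append(
                    lf.SyntheticCell(f"cal{k:02d}", (x, y, z), 1.2, {channel: 1})
                )
    stack, truth = lf.simulate_embryo_image(
        cells,
        lf.SpotModel(intensity_cv=intensity_cv),
        noise if noise is not None else lf.NoiseModel(),
        nuclei_count=0,
        voxel_grid=grid,
        seed=seed,
    )
    return stack, truth


def make_single_cell_stack(
    true_count: int,
    diameter: float = 3.5,
    noise: lf.NoiseModel | None = None,
    seed: int = 0,
    intensity_cv: float = 0.2,
    channel: str = "egl-1",
):
    """One spherical cell centred in a small stack, plus its ROI."""
    grid = lf.VoxelGrid(shape=(16, 120, 120))
    center = (7.2, 7.2, 4.0)
    cell = lf.SyntheticCell("cell", center, diameter, {channel: true_count})
    stack, truth = lf.simulate_embryo_image(
        [cell],
        lf.SpotModel(intensity_cv=intensity_cv),
        noise if noise is not None else lf.NoiseModel(),
        nuclei_count=0,
        voxel_grid=grid,
        seed=seed,
    )
    roi = lf.SphericalROI(center, diameter)
    return stack, truth, roi


@pytest.fixture(scope="session")
def calibrated_si_spot() -> float:
    """SI_Spot from a default-noise calibration field (shared across tests)."""
    stack, _ = make_calibration_stack(seed=100)
    return lf.calibrate_spot_intensity(stack, channel="egl-1")


@pytest.fixture(scope="session")
def wildtype_records():
    return lf.simulate_lineage("wild_type", n_embryos=4, seed=1)


@pytest.fixture(scope="session")
def psf2_records_large():
    """Enough candidates for binomial checks on the block probability."""
    return lf.simulate_lineage("psf2_like", n_embryos=200, seed=3)
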