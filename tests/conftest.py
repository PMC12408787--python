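"""Shared fixtures: small noiseless frames and standard ROIs.

Everything is generated at test time from explicit seeds; no image
fixtures are stored on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from hcbfquant.frames import Channel
from hcbfquant.plate import AnalyticalRegion
from hcbfquant.quant import AnalysisParams
from hcbfquant.simulate import (
    AcquisitionModel,
    CellSpot,
    SceneTruth,
    render_frame,
)


@pytest.fixture()
def roi384() -> AnalyticalRegion:
    """Analytical ROI that fits the default 384-well frame."""
    return AnalyticalRegion(diameter_um=2500.0)


@pytest.fixture()
def clean_acq() -> AcquisitionModel:
    """Noise-free, vignette-free, ring-free acquisition at 1 µm/px."""
    return AcquisitionModel(
        um_per_px=1.0,
        shot_noise=False,
        read_noise_sd=0.0,
        vignette_strength=0.0,
        meniscus_ring=(0.9, 0.0),
    )


@pytest.fixture()
def default_acq() -> AcquisitionModel:
    return AcquisitionModel()


@pytest.fixture()
def wide_open_params() -> AnalysisParams:
    """Recipe with an effectively disabled size filter, no ROI, no smoothing."""
    return AnalysisParams(
        signal_threshold=3000.0,
        size_min_um=1.0,
        size_max_um=1000.0,
        split_touching=False,
        rolling_ball_um=20.0,
        smoothing=0,
        roi=None,
    )


def small_frame(cells, image_px=64, acq=None, channel=Channel.CELL_DEFOCUS):
    """Render a tiny noiseless frame from (x, y, diameter) cell tuples."""
    acq = acq or AcquisitionModel(
        um_per_px=1.0,
        shot_noise=False,
        read_noise_sd=0.0,
        vignette_strength=0.0,
        meniscus_ring=(0.9, 0.0),
        channel=channel,
    )
    truth = SceneTruth(
        cells=[CellSpot(x, y, d) for x, y, d in cells],
        well_diameter_um=image_px * acq.um_per_px,
    )
    return truth, render_frame(truth, acq, image_px=image_px)


def flood_fill_count(mask: np.ndarray) -> int:
    """Independent 8-connected component count by iterative flood fill."""
    mask = mask.copy()
    ny, nx = mask.shape
    count = 0
    for sy in range(ny):
        for sx in range(nx):
            if not mask[sy, sx]:
                continue
            count += 1
            stack = [(sy, sx)]
            mask[sy, sx] = False
            while stack:
                y, x = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx]:
                            mask[yy, xx] = False
                            stack.append((yy, xx))
    return count
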