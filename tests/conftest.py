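import numpy as np
import pytest

from phenoplate import GridSpec, PlateImage, make_layout
from phenoplate.imaging import TRANSMISSION_GREY
from phenoplate.synthetic import SimulationConfig, simulate_fitness_plate, simulate_plate_image


@pytest.fixture
def grid96() -> GridSpec:
    return GridSpec(8, 12)


@pytest.fixture
def layout96_nogrid():
    return make_layout(96, grid_scheme="none")


@pytest.fixture
def full_plate_image_96(layout96_nogrid):
    """Synthetic 96-format greyscale plate, one radius-8 disk per position."""
    cfg = SimulationConfig(format=96, noise_cv=0.0, gradient_amplitude=0.0, seed=0)
    sizes = np.full((8, 12), 100.0)
    return simulate_plate_image(cfg, layout96_nogrid, sizes, mode="grey")


def make_disk_image(positions, radius=8.0, n_rows=8, n_cols=12, pitch=24, margin=24):
    """Greyscale plate image with disks only at the given (row, col) positions."""
    layout = make_layout(96, grid_scheme="none") if (n_rows, n_cols) == (8, 12) else None
    height = max(64, 2 * margin + pitch * (n_rows - 1) + 1)
    width = max(64, 2 * margin + pitch * (n_cols - 1) + 1)
    canvas = np.full((height, width), 0.85)
    for r, c in positions:
        cy, cx = margin + r * pitch, margin + c * pitch
        half = int(np.ceil(radius)) + 2
        yy, xx = np.mgrid[cy - half : cy + half + 1, cx - half : cx + half + 1]
        alpha = np.clip(radius + 0.5 - np.hypot(yy - cy, xx - cx), 0, 1)
        canvas[cy - half : cy + half + 1, cx - half : cx + half + 1] -= alpha * 0.6
    return PlateImage(np.clip(canvas, 0, 1), TRANSMISSION_GREY)
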