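import numpy as np
import pytest

from titinafm import Blob, Filament, HeightMap, MoleculeLayout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_blob_layout():
    """One M-complex cap (R=20 nm, peak 16.6 nm) centred in a 200 nm field."""
    return MoleculeLayout(
        field_size=(200.0, 200.0),
        blobs=[Blob(center=(100.0, 100.0), radius=20.0, peak_height=16.6)],
    )


@pytest.fixture
def straight_filament_layout():
    """One horizontal titin filament through a 400 nm field."""
    return MoleculeLayout(
        field_size=(400.0, 400.0),
        filaments=[
            Filament(
                points=np.array([[50.0, 200.0], [350.0, 200.0]]),
                tube_radius=3.0,
                peak_height=0.3,
            )
        ],
    )


@pytest.fixture
def flat_map():
    return HeightMap(np.zeros((32, 32)), pixel_size=2.0)


def brute_force_dilation(heights: np.ndarray, tip_radius: float,
                         pixel_size: float) -> np.ndarray:
    """O(N^2 K^2) max-plus dilation oracle with edge padding.

    Independent of the production path: explicit loops over every pixel
    and every probe offset inside the spherical footprint.
    """
    kr = int(np.floor(tip_radius / pixel_size))
    rows, cols = heights.shape
    padded = np.pad(heights, kr, mode="edge")
    out = np.empty_like(heights)
    offsets = []
    for di in range(-kr, kr + 1):
        for dj in range(-kr, kr + 1):
            rho2 = (di * pixel_size) ** 2 + (dj * pixel_size) ** 2
            if rho2 <= tip_radius**2:
                offsets.append((di, dj, np.sqrt(tip_radius**2 - rho2)
                                - tip_radius))
    for i in range(rows):
        for j in range(cols):
            best = -np.inf
            for di, dj, tip_h in offsets:
                val = padded[i + kr + di, j + kr + dj] + tip_h
                if val > best:
                    best = val
            out[i, j] = best
    return out
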