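import numpy as np
import pytest

from alffkit.io_core import BrainMask, TimeSeriesVolume
from alffkit.synthetic_data import SimulationConfig, default_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid_config():
    """Tiny, fast simulation geometry (still TR 2 s so band bins are valid)."""
    return SimulationConfig(
        grid_shape=(12, 12, 6), n_timepoints=60, voxel_size_mm=(6.0, 6.0, 10.0)
    )


@pytest.fixture
def atlas_and_mask():
    return default_atlas((24, 24, 12))


@pytest.fixture
def tiny_volume(rng):
    data = rng.normal(100.0, 1.0, size=(4, 5, 3, 40))
    return TimeSeriesVolume(data=data, tr_seconds=2.0, affine=np.diag((6.0, 6.0, 10.0, 1.0)))


@pytest.fixture
def full_mask():
    return BrainMask(data=np.ones((4, 5, 3), dtype=bool), affine=np.diag((6.0, 6.0, 10.0, 1.0)))


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """Independent brute-force connected components by breadth-first search.

    Used as the oracle against the labelling-based cluster decomposition.
    """
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    remaining = {tuple(v) for v in np.argwhere(binary)}
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(comp)
    return components
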