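import numpy as np
import pytest

from mprad.core import (
    MultiparametricVolume,
    QuantizationSpec,
    ROIMask,
    SignatureField,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_field(level_maps: np.ndarray, G: int, mask: np.ndarray | None = None
               ) -> SignatureField:
    """Build a SignatureField directly from (N, *grid) integer level maps."""
    level_maps = np.asarray(level_maps, dtype=np.int64)
    grid = level_maps.shape[1:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    positions = np.argwhere(mask)
    idx = tuple(positions.T)
    levels = np.stack([lm[idx] for lm in level_maps], axis=1)
    return SignatureField(levels=levels, positions=positions,
                          level_maps=level_maps, mask=mask, G=G)


def field_from_rows(rows: np.ndarray, G: int) -> SignatureField:
    """SignatureField with no meaningful geometry: one voxel per row."""
    rows = np.asarray(rows, dtype=np.int64)
    return make_field(rows.T[:, :, None], G)


def random_volume(rng, shape=(16, 16), n_channels=3) -> MultiparametricVolume:
    return MultiparametricVolume(
        [rng.random(shape) for _ in range(n_channels)]
    )


@pytest.fixture
def full_mask():
    def _mk(shape):
        return ROIMask(np.ones(shape, dtype=bool))

    return _mk


@pytest.fixture
def qspec():
    return QuantizationSpec(G=4, B=16)
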