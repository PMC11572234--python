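"""Shared fixtures and independent oracles for the test suite."""

from collections import deque

import numpy as np
import pytest

from wmhshape.mask_model import BinaryMask, VolumeGeometry


def make_mask(data, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    data = np.asarray(data, dtype=bool)
    return BinaryMask(VolumeGeometry.from_spacing(data.shape, spacing), data)


def digitized_ball(radius_vox: int, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Voxels whose center lies within ``radius_vox`` voxel units of the center."""
    n = 2 * radius_vox + 3
    c = n // 2
    idx = np.indices((n, n, n)).astype(float)
    return sum((idx[k] - c) ** 2 for k in range(3)) <= radius_vox**2


def flood_fill_components(data: np.ndarray, connectivity: int = 26):
    """Brute-force BFS labelling; independent of scipy.ndimage."""
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
        and (connectivity == 26 or abs(di) + abs(dj) + abs(dk) == 1)
    ]
    labels = np.zeros(data.shape, dtype=int)
    n = 0
    for start in zip(*np.nonzero(data)):
        if labels[start]:
            continue
        n += 1
        labels[start] = n
        queue = deque([start])
        while queue:
            i, j, k = queue.popleft()
            for di, dj, dk in offsets:
                p = (i + di, j + dj, k + dk)
                if (
                    all(0 <= p[a] < data.shape[a] for a in range(3))
                    and data[p]
                    and not labels[p]
                ):
                    labels[p] = n
                    queue.append(p)
    return labels, n


def brute_force_distance(reference: np.ndarray, spacing) -> np.ndarray:
    """O(N^2) all-pairs minimum physical distance to the reference set."""
    sp = np.asarray(spacing, dtype=float)
    ref_pts = np.argwhere(reference).astype(float) * sp
    out = np.empty(reference.shape)
    for idx in np.ndindex(reference.shape):
        p = np.array(idx, dtype=float) * sp
        out[idx] = np.sqrt(((ref_pts - p) ** 2).sum(axis=1)).min()
    return out


@pytest.fixture(scope="session")
def ball_r10():
    return digitized_ball(10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240807)
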