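import numpy as np
import pytest

import contourctl as cc


@pytest.fixture(scope="session")
def phantom():
    """Default two-ellipse phantom with its left-ellipse reference."""
    return cc.make_phantom()


@pytest.fixture(scope="session")
def gradient_phantom():
    return cc.make_gradient_phantom()


@pytest.fixture
def grid64():
    return cc.Grid((64, 64))


@pytest.fixture
def circle_sdf(grid64):
    """Signed distance of a radius-20 circle, interior positive."""
    return cc.circle_seed(grid64, (32, 32), 20.0)


def brute_force_interface_distance(phi):
    """Independent oracle: distance to axis-edge zero crossings of phi.

    Linear interpolation along every grid line, then a direct O(N*M) minimum
    over the crossing points — no tree, no contour extraction.
    """
    values = phi.values
    spacing = np.asarray(phi.grid.spacing)
    pts = []
    for axis in range(values.ndim):
        lo = [slice(None)] * values.ndim
        hi = [slice(None)] * values.ndim
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        a, b = values[tuple(lo)], values[tuple(hi)]
        cross = a * b < 0
        idx = np.argwhere(cross).astype(float)
        theta = a[cross] / (a[cross] - b[cross])
        coords = idx * spacing
        coords[:, axis] += theta * spacing[axis]
        pts.append(coords)
    zero = values == 0.0
    if zero.any():
        pts.append(np.argwhere(zero).astype(float) * spacing)
    pts = np.vstack([p for p in pts if len(p)])
    cells = np.stack([c.ravel() for c in phi.grid.coordinate_arrays()], axis=1)
    d = np.empty(len(cells))
    for i, c in enumerate(cells):
        d[i] = np.sqrt(((pts - c) ** 2).sum(axis=1)).min()
    return d.reshape(phi.grid.shape)
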