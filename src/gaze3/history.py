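"""Spatial encoding of recent fixation history.

Each of the k most recent fixations is rendered as three feature maps on
the readout grid: Euclidean distance to the fixation, and the signed x and
y coordinate differences (grid point minus fixation, so dx is positive to
the right of the fixation).  Values are scaled by the inverse grid diagonal
so inputs stay O(1) across image sizes.  Slots for fixations that do not
exist yet are masked out and contribute exactly zero downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import Scanpath


@dataclass
class HistoryStack:
    """k slots x 3 channels of (H', W') maps plus a presence mask.

    Slot j (0-based) encodes fixation f_{i-1-j}; channel order is
    (distance, dx, dy).
    """

    maps: np.ndarray  # (k, 3, H', W')
    mask: np.ndarray  # (k,) bool

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def diagonal_scale(grid_shape) -> float:
    h, w = grid_shape
    return 1.0 / math.hypot(h, w)


def encode_fixation_maps(fx: float, fy: float, grid_shape, scale: float) -> np.ndarray:
    """Three (H', W') maps: distance, dx, dy to a fixation in grid coords."""
    h, w = grid_shape
    if h <= 0 or w <= 0:
        raise ValueError("zero-size grid")
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    dx = (xs - fx) * scale
    dy = (ys - fy) * scale
    dist = np.sqrt(dx**2 + dy**2)
    return np.stack([dist, dx, dy])


def image_to_grid(x: float, y: float, downsample: float) -> tuple:
    """Map continuous image coords to readout-grid coords (cell centers)."""
    return (x + 0.5) / downsample - 0.5, (y + 0.5) / downsample - 0.5


def build_history_stack(sp: Scanpath, i: int, k: int, grid_shape,
                        downsample: float = 1.0, scale=None) -> HistoryStack:
    """Encode the up-to-k fixations preceding target index i.

    Slot 0 holds f_{i-1} (the current fixation the subject saccades away
    from), slot j holds f_{i-1-j}.  Slots beyond the start of the scanpath
    are masked with all-zero maps; k=0 yields an empty stack.
    """
    if i < 1:
        raise ValueError("no fixation to predict before index 1")
    if i > len(sp.fixations):
        raise IndexError("target index beyond scanpath end")
    h, w = grid_shape
    if scale is None:
        scale = diagonal_scale(grid_shape)
    maps = np.zeros((k, 3, h, w))
    mask = np.zeros(k, dtype=bool)
    for j in range(k):
        src = i - 1 - j
        if src < 0:
            break
        f = sp.fixations[src]
        gx, gy = image_to_grid(f.x, f.y, downsample)
        maps[j] = encode_fixation_maps(gx, gy, grid_shape, scale)
        mask[j] = True
    return HistoryStack(maps=maps, mask=mask)
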