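"""Probability grids over image pixels: normalization, likelihood, sampling.

Densities are represented as natural-log probability *masses* per pixel
cell (H x W grids whose logsumexp is 0).  Log-likelihoods are reported in
bits relative to the uniform grid, the standard exchange rate for comparing
fixation models across image sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_io import Fixation

_NORM_TOL = 1e-6


@dataclass
class LogDensityGrid:
    """Normalized per-pixel log probability masses."""

    values: np.ndarray  # (H, W) natural log masses

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("density grid must be 2-D")
        total = logsumexp(self.values)
        if not np.isfinite(total) or abs(total) > _NORM_TOL:
            raise ValueError(f"grid not normalized: logsumexp = {total}")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def probabilities(self) -> np.ndarray:
        return np.exp(self.values)

    def cell_of(self, f: Fixation) -> tuple:
        """Containing pixel cell (row, col) of a continuous fixation."""
        r, c = int(math.floor(f.y)), int(math.floor(f.x))
        if not (0 <= r < self.height and 0 <= c < self.width):
            raise ValueError(f"fixation ({f.x}, {f.y}) outside {self.shape} grid")
        return r, c


def uniform_log_density(shape) -> LogDensityGrid:
    h, w = shape
    return LogDensityGrid(np.full((h, w), -math.log(h * w)))


def normalize_log_density(raw: np.ndarray) -> LogDensityGrid:
    """Softmax in log space: subtract the logsumexp of the raw grid."""
    raw = np.asarray(raw, dtype=np.float64)
    total = logsumexp(raw)
    if not np.isfinite(total):
        raise ValueError("cannot normalize: logsumexp is not finite")
    return LogDensityGrid(raw - total)


def loglik_bits(d: LogDensityGrid, f: Fixation) -> float:
    """Log-likelihood of a fixation in bits relative to the uniform grid."""
    r, c = d.cell_of(f)
    return (d.values[r, c] + math.log(d.height * d.width)) / math.log(2.0)


def sample_fixation(d: LogDensityGrid, rng: np.random.Generator) -> Fixation:
    """Draw one fixation (integer cell coordinates) from the grid.

    Inverse-CDF sampling on the flattened cell masses; deterministic given
    the generator state.
    """
    cum = np.cumsum(d.probabilities().ravel())
    idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    idx = min(idx, cum.size - 1)
    r, c = divmod(idx, d.width)
    return Fixation(float(c), float(r))


# --------------------------------------------------------------------------
IDENTITY_SIGMA = 0.3  # below this blur width the kernel is a delta


def _gaussian_kernel(sigma: float):
    """Truncated (4 sigma), unit-sum 1-D Gaussian kernel and its d/dsigma."""
    radius = int(math.ceil(4.0 * sigma))
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(t**2) / (2.0 * sigma**2))
    s = g.sum()
    k = g / s
    # derivative of the normalized taps with respect to sigma
    dg = g * t**2 / sigma**3
    dk = (dg - k * dg.sum()) / s
    return k, dk


def blur_operator(n: int, sigma: float, with_grad: bool = False):
    """Dense n x n matrix of 1-D Gaussian blur with replicate padding.

    Row i holds the kernel centered at i; taps beyond the border accumulate
    onto the edge sample (the matrix form of replicate padding).  When
    ``with_grad`` is true also returns the elementwise d/dsigma matrix.
    """
    if n <= 0:
        raise ValueError("grid dimension must be positive")
    if sigma < IDENTITY_SIGMA:
        B = np.eye(n)
        return (B, np.zeros((n, n))) if with_grad else B
    k, dk = _gaussian_kernel(sigma)
    radius = (len(k) - 1) // 2
    B = np.zeros((n, n))
    dB = np.zeros((n, n))
    for i in range(n):
        for off in range(-radius, radius + 1):
            j = min(max(i + off, 0), n - 1)  # replicate padding
            B[i, j] += k[off + radius]
            dB[i, j] += dk[off + radius]
    return (B, dB) if with_grad else B


def gaussian_blur(m: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur, 4-sigma truncation, replicate padding.

    Acts on raw (unbounded) grids, not on probabilities; sigma below
    ``IDENTITY_SIGMA`` pixels returns the input unchanged.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("expected a non-empty 2-D grid")
    if sigma < IDENTITY_SIGMA:
        return m.copy()
    Bh = blur_operator(m.shape[0], sigma)
    Bw = blur_operator(m.shape[1], sigma)
    return Bh @ m @ Bw.T


def bilinear_upsample_operator(n_out: int, n_in: int) -> np.ndarray:
    """1-D cell-center-aligned linear interpolation matrix (n_out x n_in)."""
    factor = n_out / n_in
    U = np.zeros((n_out, n_in))
    for i in range(n_out):
        u = (i + 0.5) / factor - 0.5
        lo = int(math.floor(u))
        frac = u - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        U[i, lo_c] += 1.0 - frac
        U[i, hi_c] += frac
    return U


def finalize(readout: np.ndarray, log_cb: np.ndarray, w: float,
             sigma: float) -> LogDensityGrid:
    """Blur the readout, add the weighted log center bias, softmax.

    The softmax comes last so the output is guaranteed to be a
    distribution; the center bias enters in log space with weight ``w``.
    """
    readout = np.asarray(readout, dtype=np.float64)
    log_cb = np.asarray(log_cb, dtype=np.float64)
    if readout.shape != log_cb.shape:
        raise ValueError(
            f"shape mismatch: readout {readout.shape} vs center bias {log_cb.shape}"
        )
    return normalize_log_density(gaussian_blur(readout, sigma) + w * log_cb)
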