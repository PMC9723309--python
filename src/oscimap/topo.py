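"""Spectral topographic volumes.

Each kept 1-second trial becomes a 20 x 20 x 50 tensor: a stack of scalp
power maps, one per frequency bin from 1 to 99 Hz in 2 Hz steps. The scalp
maps use nearest-electrode assignment on an azimuthal-equidistant grid
(row 0 = anterior), and the per-trial power values are quantile-mapped onto
a Gamma(shape 1, scale 0.5) distribution so that absolute scales are
comparable across trials while the spectral pattern (the ranks) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .montage import ElectrodeLayout, grid_cell_centers

GRID_SIZE = 20
N_BINS = 50


def bin_centers(start: float = 1.0, step: float = 2.0, n: int = N_BINS) -> np.ndarray:
    """Frequency bin centres: 1, 3, ..., 99 Hz by default."""
    return start + step * np.arange(n)


@dataclass
class SpectralMatrix:
    """Per-trial channel x frequency power (64 x 50)."""

    power: np.ndarray
    bin_centers: np.ndarray

    def __post_init__(self):
        if self.power.ndim != 2 or self.power.shape[1] != len(self.bin_centers):
            raise ValueError("power must be channels x bins")


@dataclass
class SpectralVolume:
    """20 x 20 x 50 spectral topographic volume (z axis = frequency)."""

    volume: np.ndarray
    grid_assignment: np.ndarray
    bin_centers: np.ndarray


def _periodogram_at_centers(x: np.ndarray, rate: float, centers: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(x)):
        raise ValueError("trial contains non-finite samples")
    freqs, pxx = sps.periodogram(x, fs=rate, window="hann", detrend="linear",
                                 axis=-1, scaling="density")
    idx = np.abs(freqs[None, :] - centers[:, None]).argmin(axis=1)
    return pxx[..., idx]


def compute_spectrum(trial: np.ndarray, rate: float,
                     centers: np.ndarray | None = None) -> SpectralMatrix:
    """Single-taper (Hanning) periodogram sampled at the 50 bin centres.

    The trial is linearly detrended, multiplied by a single Hann window and
    its periodogram power is read out at the discrete frequency nearest each
    bin centre.
    """
    if centers is None:
        centers = bin_centers()
    centers = np.asarray(centers, float)
    return SpectralMatrix(power=_periodogram_at_centers(trial, rate, centers),
                          bin_centers=centers)


def compute_spectra(trials: np.ndarray, rate: float,
                    centers: np.ndarray | None = None) -> np.ndarray:
    """Vectorized spectra for a (n_trials, n_channels, n_samples) stack."""
    if centers is None:
        centers = bin_centers()
    return _periodogram_at_centers(trials, rate, np.asarray(centers, float))


def gamma_resample(matrix: SpectralMatrix, shape: float = 1.0,
                   scale: float = 0.5) -> SpectralMatrix:
    """Rank-based quantile mapping of the trial's pooled values onto
    Gamma(shape, scale) quantiles at plotting positions (rank - 0.5)/n.

    Order-preserving; tied inputs share an output value. With the default
    shape of 1 this is the exponential distribution with mean ``scale``.
    """
    values = matrix.power.ravel()
    if np.unique(values).size < 2:
        raise ValueError("gamma resampling needs at least two distinct values")
    ranks = stats.rankdata(values, method="average")
    q = stats.gamma.ppf((ranks - 0.5) / values.size, a=shape, scale=scale)
    return SpectralMatrix(power=q.reshape(matrix.power.shape),
                          bin_centers=matrix.bin_centers)


def build_grid_assignment(layout: ElectrodeLayout, grid_size: int = GRID_SIZE) -> np.ndarray:
    """Nearest-electrode index for each of the grid cells.

    Cell centres live on the same planar disc as the projected electrodes;
    ties break deterministically toward the lower channel index. Cells
    outside the head circle still take their nearest electrode (dense maps,
    no masking).
    """
    gx, gy = grid_cell_centers(grid_size)
    cells = np.stack([gx.ravel(), gy.ravel()], axis=1)
    d = np.linalg.norm(cells[:, None, :] - layout.positions2d[None, :, :], axis=2)
    return d.argmin(axis=1).reshape(grid_size, grid_size)


def build_volume(matrix: SpectralMatrix, grid_assignment: np.ndarray) -> SpectralVolume:
    """volume[i, j, f] = power[assignment[i, j], f]."""
    if matrix.power.shape[1] != len(matrix.bin_centers):
        raise ValueError("matrix shape inconsistent with bin centres")
    if grid_assignment.max() >= matrix.power.shape[0]:
        raise ValueError("grid assignment refers to channels beyond the matrix")
    vol = matrix.power[grid_assignment]  # (g, g, n_bins)
    return SpectralVolume(volume=vol, grid_assignment=grid_assignment,
                          bin_centers=matrix.bin_centers)


def trials_to_volumes(trials: np.ndarray, rate: float, grid_assignment: np.ndarray,
                      centers: np.ndarray | None = None,
                      gamma_shape: float = 1.0, gamma_scale: float = 0.5) -> np.ndarray:
    """Full trial -> volume map for a stack of kept trials.

    Returns an (n_trials, 20, 20, 50) array: periodogram at the bin centres,
    per-trial gamma resampling (pooled over channels x bins), then
    nearest-electrode gridding. Deterministic.
    """
    if centers is None:
        centers = bin_centers()
    power = compute_spectra(trials, rate, centers)  # (n, ch, bins)
    out = np.empty((power.shape[0],) + grid_assignment.shape + (len(centers),))
    for i in range(power.shape[0]):
        m = gamma_resample(SpectralMatrix(power[i], np.asarray(centers, float)),
                           gamma_shape, gamma_scale)
        out[i] = m.power[grid_assignment]
    return out


def band_bins(centers: np.ndarray, band: tuple) -> np.ndarray:
    """Indices of bins whose centre falls in [low, high) Hz (left-closed)."""
    lo, hi = band
    return np.flatnonzero((centers >= lo) & (centers < hi))
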