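"""Grad-CAM saliency volumes, across-trial t-volumes, supra-threshold
spatio-oscillatory clusters, band maps and frequency profiles.

For a trained classifier and a test volume, Grad-CAM weights each filter of
a convolutional layer by the spatial/frequency average of the gradient of a
target scalar (the class's pre-softmax score by default, optionally the
loss), sums the weighted feature maps, and upsamples the result trilinearly
to the 20 x 20 x 50 input geometry. No rectification is applied before
z-scoring: signed maps are kept, because the sign carries the one-versus-
rest direction (negative values mark features favouring the *other*
classes).

Across the test trials of one class, each z-scored map is reduced to a
per-voxel one-sample t statistic against zero ("t-volume"); voxels above a
conservative threshold are mapped back to electrodes through the grid
assignment and reported per canonical frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .net import Model3DCNN

#: Canonical frequency bands (Hz), left-closed intervals.
BANDS = {
    "delta_theta": (1.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}


@dataclass
class GradCAMVolume:
    volume: np.ndarray        # (20, 20, 50) saliency, signed
    target_class: int
    layer_index: int
    zscored: bool = False


@dataclass
class TVolume:
    t: np.ndarray             # (20, 20, 50), NaN where across-trial variance is 0
    n_trials: int
    target_class: int


@dataclass
class ClusterResult:
    target_class: int
    band: str
    electrodes: tuple
    peak_t: float
    peak_freq: float
    sign: int = +1            # +1: favours the class; -1: reverse direction


def _upsample_trilinear(vol: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Trilinear interpolation to the input geometry (half-pixel convention).

    Each native cell of the feature map covers a block of input cells (the
    cumulative pooling factor), so output coordinate g maps to source
    coordinate (g + 0.5) / r - 0.5 with r the size ratio; this registers
    native cell centres onto the centres of the blocks they summarize,
    unlike the align-corners convention, which stretches the map by up to
    half a block at the edges.
    """
    axes = []
    for s_in, s_out in zip(vol.shape, out_shape):
        r = s_out / s_in
        axes.append((np.arange(s_out) + 0.5) / r - 0.5)
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(vol, np.array(coords), order=1, mode="nearest")


def gradcam_volume(model: Model3DCNN, volume: np.ndarray, target_class: int,
                   layer_index: int = 3, scalar: str = "class_score") -> GradCAMVolume:
    """Grad-CAM map of one volume for one target class.

    Per-filter weight = mean over the layer's spatial and frequency axes of
    d(scalar)/d(activation); the map is the weight-summed activation,
    upsampled to the input dimensions.
    """
    maps = gradcam_volumes(model, np.asarray(volume)[None], target_class,
                           layer_index, scalar)
    return GradCAMVolume(volume=maps[0], target_class=target_class,
                         layer_index=layer_index)


def gradcam_volumes(model: Model3DCNN, volumes: np.ndarray, target_class: int,
                    layer_index: int = 3, scalar: str = "class_score") -> np.ndarray:
    """Batched Grad-CAM maps, shape (n, 20, 20, 50)."""
    act, grad = model.activation_gradient(volumes, target_class, layer_index, scalar)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite Grad-CAM gradients (untrained model?)")
    weights = grad.mean(axis=(1, 2, 3))                  # (n, filters)
    maps = np.einsum("nxyzf,nf->nxyz", act, weights)
    out_shape = tuple(model.spec.input_shape)
    return np.stack([_upsample_trilinear(m, out_shape) for m in maps])


def gradcam_filter_weights(model: Model3DCNN, volume: np.ndarray, target_class: int,
                           layer_index: int = 3, scalar: str = "class_score") -> np.ndarray:
    """The per-filter Grad-CAM weights of one volume (for verification)."""
    act, grad = model.activation_gradient(np.asarray(volume)[None], target_class,
                                          layer_index, scalar)
    return grad.mean(axis=(1, 2, 3))[0]


def zscore_volume(volume: np.ndarray) -> np.ndarray:
    """Z-score a saliency volume over its voxels (mean 0, SD 1)."""
    v = np.asarray(volume, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant volume")
    return (v - v.mean()) / sd


def t_volume(zvolumes: np.ndarray, target_class: int = -1) -> TVolume:
    """Per-voxel one-sample t statistic across trials.

    t = mean / (SD / sqrt(n)) with the across-trial sample SD (ddof 1);
    voxels with zero across-trial variance are flagged NaN.
    """
    z = np.asarray(zvolumes, dtype=float)
    n = z.shape[0]
    if n < 2:
        raise ValueError("t-volume needs at least 2 trials")
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return TVolume(t=t, n_trials=n, target_class=target_class)


def t_volume_pvalues(tv: TVolume) -> np.ndarray:
    """Two-tailed p-values from the Student t(n-1) reference."""
    return 2.0 * stats.t.sf(np.abs(tv.t), df=tv.n_trials - 1)


def contrast_t_volume(z_target: np.ndarray, z_rest: np.ndarray,
                      target_class: int = -1) -> TVolume:
    """One-versus-all contrast: per-voxel pooled two-sample t.

    Compares the z-scored Grad-CAM maps of the cohort in question against
    the superposed maps of the other cohorts, so network structure that is
    common to all cohorts cancels; negative t marks the reverse direction
    (features favouring the other cohorts).
    """
    a = np.asarray(z_target, dtype=float)
    b = np.asarray(z_rest, dtype=float)
    n1, n0 = a.shape[0], b.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValueError("contrast t-volume needs >= 2 maps per group")
    m1, m0 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v0 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sp2 > 0, (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0)), np.nan)
    return TVolume(t=t, n_trials=n1 + n0, target_class=target_class)


def zscored_maps(model: Model3DCNN, volumes: np.ndarray, target_class: int,
                 layer_index: int = 3, scalar: str = "class_score",
                 batch_size: int = 100) -> np.ndarray:
    """Per-volume z-scored Grad-CAM maps for a stack of volumes.

    A constant saliency map (e.g. a trial whose gradient path is fully
    rectified away) carries no localization information; it is kept as an
    all-zero map rather than failing the whole ensemble.
    """
    maps = []
    for i in range(0, len(volumes), batch_size):
        maps.append(gradcam_volumes(model, volumes[i : i + batch_size],
                                    target_class, layer_index, scalar))
    maps = np.concatenate(maps, axis=0)
    out = np.empty_like(maps)
    for i, m in enumerate(maps):
        out[i] = zscore_volume(m) if m.std() > 0 else 0.0
    return out


def class_t_volume(model: Model3DCNN, volumes: np.ndarray, target_class: int,
                   layer_index: int = 3, scalar: str = "class_score",
                   batch_size: int = 100,
                   rest_volumes: np.ndarray | None = None) -> TVolume:
    """Grad-CAM -> per-volume z-scoring -> across-trial t, in one call.

    Without ``rest_volumes`` this is the one-sample t against zero over the
    given trials. With ``rest_volumes`` (the other cohorts' test trials) it
    is the one-versus-all two-sample contrast, which localizes
    class-discriminative rather than merely stable saliency.
    """
    z = zscored_maps(model, volumes, target_class, layer_index, scalar, batch_size)
    if rest_volumes is None:
        return t_volume(z, target_class)
    z_rest = zscored_maps(model, rest_volumes, target_class, layer_index, scalar,
                          batch_size)
    return contrast_t_volume(z, z_rest, target_class)


def extract_clusters(tv: TVolume, grid_assignment: np.ndarray,
                     bin_centers: np.ndarray, layout_names,
                     threshold: float = 20.0, bands: dict = BANDS,
                     include_negative: bool = True) -> list:
    """Supra-threshold electrodes per canonical band.

    Voxels with t above the (conservative) threshold are mapped back to
    their assigned electrodes; per band, the member electrode set and the
    extremal t (with its frequency) are reported. The reverse direction
    (t below -threshold) is reported separately with sign -1.
    """
    results = []
    t = tv.t
    for sign in (+1, -1) if include_negative else (+1,):
        st = sign * t
        for band_name, (lo, hi) in bands.items():
            bins = np.flatnonzero((bin_centers >= lo) & (bin_centers < hi))
            if bins.size == 0:
                continue
            sub = st[:, :, bins]
            mask = np.nan_to_num(sub, nan=-np.inf) > threshold
            if not mask.any():
                continue
            cells = np.any(mask, axis=2)
            electrodes = tuple(
                sorted({layout_names[grid_assignment[i, j]]
                        for i, j in zip(*np.nonzero(cells))})
            )
            flat = np.nan_to_num(sub, nan=-np.inf)
            i, j, b = np.unravel_index(np.argmax(flat), flat.shape)
            results.append(
                ClusterResult(
                    target_class=tv.target_class, band=band_name,
                    electrodes=electrodes, peak_t=float(sign * sub[i, j, b]),
                    peak_freq=float(bin_centers[bins[b]]), sign=sign,
                )
            )
    return results


def frequency_profile(tv: TVolume, electrodes, grid_assignment: np.ndarray,
                      layout_names, bin_centers: np.ndarray,
                      prominence: float | None = None) -> dict:
    """Mean t over an electrode set's assigned cells, per frequency bin.

    Returns the profile and its local maxima (prominence-based detection;
    ties are reported in ascending frequency order).
    """
    electrodes = tuple(electrodes)
    if not electrodes:
        raise ValueError("electrode set must be non-empty")
    names = list(layout_names)
    idx = {names.index(e) for e in electrodes}
    cells = np.isin(grid_assignment, list(idx))
    if not cells.any():
        raise ValueError("no grid cells are assigned to the given electrodes")
    profile = np.nanmean(tv.t[cells], axis=0)
    if prominence is None:
        span = np.nanmax(profile) - np.nanmin(profile)
        prominence = 0.05 * span if span > 0 else None
    peaks, props = signal.find_peaks(np.nan_to_num(profile, nan=-np.inf),
                                     prominence=prominence)
    return {
        "freqs": np.asarray(bin_centers, float),
        "profile": profile,
        "peak_freqs": np.asarray(bin_centers, float)[peaks],
        "peak_t": profile[peaks],
    }


def localization_specificity(tv: TVolume, grid_assignment: np.ndarray,
                             layout_names, electrodes, bands_hz,
                             bin_centers: np.ndarray,
                             threshold: float = 20.0) -> float:
    """Fraction of supra-threshold voxels inside a target electrode set and
    band list (the synthetic-recovery specificity measure). Returns NaN if
    nothing is supra-threshold."""
    names = list(layout_names)
    idx = {names.index(e) for e in electrodes}
    cells = np.isin(grid_assignment, list(idx))
    bins = np.zeros(len(bin_centers), dtype=bool)
    for lo, hi in bands_hz:
        bins |= (bin_centers >= lo) & (bin_centers < hi)
    mask = np.nan_to_num(tv.t, nan=-np.inf) > threshold
    total = mask.sum()
    if total == 0:
        return float("nan")
    inside = mask & cells[:, :, None] & bins[None, None, :]
    return float(inside.sum() / total)


def argmax_voxel(tv: TVolume) -> tuple:
    """(i, j, bin) of the largest finite t value."""
    flat = np.nan_to_num(tv.t, nan=-np.inf)
    return np.unravel_index(np.argmax(flat), flat.shape)


def band_map(tv: TVolume, band: tuple, bin_centers: np.ndarray) -> np.ndarray:
    """Mean t over a band's bins: a 20 x 20 topographic map."""
    bins = np.flatnonzero((bin_centers >= band[0]) & (bin_centers < band[1]))
    return np.nanmean(tv.t[:, :, bins], axis=2)


def save_band_maps(tv: TVolume, bin_centers: np.ndarray, path,
                   bands: dict = BANDS, title: str = ""):
    """Export the four canonical band maps as one figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(bands), figsize=(3 * len(bands), 3))
    for ax, (name, band) in zip(np.atleast_1d(axes), bands.items()):
        m = band_map(tv, band, bin_centers)
        lim = np.nanmax(np.abs(m)) or 1.0
        im = ax.imshow(m, cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.set_title(f"{name} ({band[0]:g}-{band[1]:g} Hz)", fontsize=8)
        ax.set_xticks([]), ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
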