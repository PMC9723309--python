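"""Electrode layout: 64-channel extended 10-20 montage and its planar projection.

The scalp positions come from MNE's standard 10-05 template. Planar
coordinates use an azimuthal-equidistant projection about the vertex, the
standard convention for EEG topographic maps: the angular distance from Cz
becomes the planar radius, so anterior electrodes sit at the top ("north")
of the map and occipital electrodes at the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default 64-channel montage. Extended 10-20 labels covering the frontal,
#: central, temporal, parietal, parieto-occipital and occipital rows,
#: including the inferior parietal ring (P9/P10, PO9).
CHANNELS_64 = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO9", "PO7", "PO5", "PO3", "PO1", "POz", "PO2", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

#: Channels that carry the stereotyped blink transient in the simulator.
FRONTAL_BLINK_CHANNELS = ("Fp1", "Fp2", "AF7", "AF8")


def _fit_sphere(points: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre of a point cloud (linearized fit)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


@dataclass(frozen=True)
class ElectrodeLayout:
    """64-channel montage with 3D unit-sphere and projected 2D coordinates.

    Attributes
    ----------
    names : tuple of str
        Unique channel labels.
    positions3d : (n, 3) array
        Unit vectors from the fitted head-sphere centre (+x right,
        +y anterior, +z superior).
    positions2d : (n, 2) array
        Azimuthal-equidistant projection scaled so every electrode lies
        strictly inside the unit disc; +y is anterior.
    """

    names: tuple
    positions3d: np.ndarray = field(repr=False)
    positions2d: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel labels must be unique")
        if not np.all(np.linalg.norm(self.positions2d, axis=1) < 1.0):
            raise ValueError("projected positions must lie inside the unit disc")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name) if isinstance(self.names, list) else tuple(self.names).index(name)
        except ValueError:
            raise KeyError(f"unknown electrode label: {name!r}") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def __len__(self) -> int:
        return len(self.names)


def project_to_disc(positions3d: np.ndarray, names) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere electrode positions.

    The polar angle from the vertex direction (Cz) maps to the planar
    radius; the azimuth (0 = anterior) is preserved. Radii are scaled by
    the largest electrode angle so all electrodes fall inside the unit
    disc. Deterministic given the 3D positions.
    """
    names = list(names)
    v = positions3d / np.linalg.norm(positions3d, axis=1, keepdims=True)
    pole = v[names.index("Cz")]
    pole = pole / np.linalg.norm(pole)
    anterior_raw = 0.5 * (v[names.index("Fp1")] + v[names.index("Fp2")])
    anterior = anterior_raw - pole * (anterior_raw @ pole)
    anterior /= np.linalg.norm(anterior)
    right = np.cross(anterior, pole)
    right /= np.linalg.norm(right)

    a = v @ right          # rightward component
    b = v @ anterior       # anterior component
    c = np.clip(v @ pole, -1.0, 1.0)
    theta = np.arccos(c)
    scale = theta.max() * (1.0 + 1e-9)
    planar = np.hypot(a, b)
    planar[planar == 0] = 1.0
    r = theta / scale
    return np.column_stack([r * a / planar, r * b / planar])


def standard_layout(names=CHANNELS_64) -> ElectrodeLayout:
    """Build the default layout from MNE's standard 10-05 template positions."""
    import mne

    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    missing = [n for n in names if n not in pos]
    if missing:
        raise KeyError(f"labels absent from the standard montage: {missing}")
    pts = np.array([pos[n] for n in names], dtype=float)
    centre = _fit_sphere(pts)
    v = pts - centre
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos2d = project_to_disc(v, names)
    return ElectrodeLayout(names=tuple(names), positions3d=v, positions2d=pos2d)


def grid_cell_centers(grid_size: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Planar coordinates of grid cell centres.

    Returns ``(gx, gy)`` arrays of shape (grid_size, grid_size) where row 0
    is the anterior ("north") edge of the map, matching the orientation of
    the electrode projection.
    """
    step = 2.0 / grid_size
    coords = -1.0 + step * (np.arange(grid_size) + 0.5)
    gx = np.tile(coords, (grid_size, 1))           # left -> right
    gy = np.tile(coords[::-1, None], (1, grid_size))  # row 0 = anterior
    return gx, gy
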