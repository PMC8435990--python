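"""Image-stack input/output and grayscale preprocessing.

A specimen scan arrives as a series of cross-section images, one per axial
layer (a directory of PNG/TIFF files or a single multipage TIFF). Stacks whose
value set has at most two distinct values are treated as already binarized,
with the maximal value as metal (foreground); anything else loads as a
grayscale volume to be smoothed and thresholded with :func:`binarize`.

Conventions (fixed for reproducibility):

* slice ordering = ascending natural sort of filenames; layer 0 is the first
  image, and the slice axis is the specimen's longitudinal axis;
* in-plane points are (x, y) = (column, row);
* heatmap grids are written row = layer (ascending), column = 2° angular bin
  starting at the +x axis and increasing toward +y.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .errors import FormatError, InputError

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp"}


@dataclass
class GrayVolume:
    """Axial stack of intensity cross-sections.

    Parameters
    ----------
    data : ndarray, shape (n_slices, height, width)
        Intensity values, slice axis first.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (15 for the reference scans).
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError("volume data must be a (n_slices, h, w) array")
        if self.voxel_size_um <= 0:
            raise InputError("voxel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class BinaryVolume:
    """Axial stack of boolean cross-sections; True marks the metal core."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise FormatError("volume data must be a (n_slices, h, w) array")
        if self.data.shape[0] < 2:
            raise InputError("a volume needs at least 2 slices")
        if self.voxel_size_um <= 0:
            raise InputError("voxel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def core_volume_um3(self) -> float:
        """Voxel-counted metal volume in µm³."""
        return float(self.data.sum()) * self.voxel_size_um**3


def _natural_key(path: Path):
    return [int(t) if t.isdigit() else t.lower()
            for t in re.split(r"(\d+)", path.name)]


def _to_2d(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        return img[..., :3].mean(axis=-1)
    raise FormatError(f"unsupported image shape {img.shape}")


def read_stack(path, voxel_size_um: float = 15.0):
    """Load a slice stack from a directory or multipage TIFF.

    Returns a :class:`BinaryVolume` when the stack holds at most two distinct
    values (foreground = maximal value), otherwise a :class:`GrayVolume`.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted((p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
                       key=_natural_key)
        if len(files) < 2:
            raise InputError(f"need at least 2 slice images in {path}")
        slices = [_to_2d(np.asarray(iio.imread(f))) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise FormatError(f"slices have mixed dimensions: {sorted(shapes)}")
        data = np.stack(slices)
    else:
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2 or (data.ndim == 3 and data.shape[0] < 2):
            raise InputError("multipage stack needs at least 2 slices")
        if data.ndim != 3:
            raise FormatError(f"unsupported stack shape {data.shape}")

    vals = np.unique(data)
    if len(vals) <= 2:
        if len(vals) == 1:
            binary = data > 0
        else:
            binary = data == vals.max()
        return BinaryVolume(binary, voxel_size_um)
    return GrayVolume(data, voxel_size_um)


def write_stack(volume, path, prefix: str = "slice") -> list[Path]:
    """Write a volume as a PNG slice series (or one multipage TIFF).

    ``path`` ending in ``.tif``/``.tiff`` selects a multipage TIFF; otherwise
    it is treated as a directory and zero-padded PNGs are written into it.
    Binary volumes are stored as 0/255 uint8 so they round-trip through
    :func:`read_stack` bit-identically.
    """
    path = Path(path)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(volume.n_slices - 1)))
    out = []
    for i, sl in enumerate(data):
        f = path / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(f, np.ascontiguousarray(sl))
        out.append(f)
    return out


def binarize(volume: GrayVolume, threshold: float,
             gaussian_sigma_px: float = 2.0) -> BinaryVolume:
    """Per-slice Gaussian smoothing followed by global thresholding.

    A voxel becomes metal when its smoothed intensity is >= ``threshold``.
    Smoothing is 2D within each cross-section (sigma in pixels); the threshold
    is a required, scan-specific choice — the core/degradation-layer contrast
    varies between scans and no automatic rule is assumed. A threshold outside
    the intensity range is allowed and yields an all-true or all-false volume.
    """
    out = np.empty(volume.data.shape, dtype=bool)
    for i, sl in enumerate(volume.data):
        if gaussian_sigma_px > 0:
            sm = ndimage.gaussian_filter(sl.astype(float), gaussian_sigma_px)
        else:
            sm = sl.astype(float)
        out[i] = sm >= threshold
    return BinaryVolume(out, volume.voxel_size_um)


def export_heatmap(depths, csv_path, png_path=None, voxel_size_um: float | None = None):
    """Write the unrolled-surface penetration grid (layers × angle bins).

    ``depths`` holds the radial distance (µm) from the initial radius r0 to
    the metal surface. The CSV is a plain comma-delimited numeric grid; the
    optional PNG renders the unrolled cylinder surface with a colorbar.
    """
    try:
        grid = np.asarray(depths, dtype=float)
    except ValueError as e:
        raise InputError("depth grid must be rectangular") from e
    if grid.ndim != 2 or grid.dtype == object:
        raise InputError("depth grid must be a 2D rectangular array")
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(csv_path, grid, delimiter=",", fmt="%.3f")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(grid.T, aspect="auto", origin="lower", cmap="inferno",
                       extent=(0, grid.shape[0], 0, 360))
        ax.set_xlabel("layer")
        ax.set_ylabel("angle (deg)")
        fig.colorbar(im, ax=ax, label="penetration from r0 (µm)")
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return csv_path
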