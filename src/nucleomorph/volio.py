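"""Calibrated 3D image-stack I/O and preprocessing.

The measurement pipeline treats a z-stack of a single fluorescence channel as a
:class:`VoxelGrid` — a ``(z, y, x)`` array of non-negative intensities plus its
spatial calibration (x/y pixel size and z-step, in micrometres).  Preprocessing
follows the standard route for nuclear-envelope stain segmentation:

1. pick the most in-focus z-plane (:func:`select_focus_plane`),
2. compute one global "optimal" auto-threshold on that plane and apply it to
   every plane of the stack (:func:`auto_threshold`),
3. clean the binary volume with a 3D median filter over a ball neighbourhood
   (:func:`median_filter_3d`),
4. label disconnected foreground objects (:func:`label_objects`).

Conventions (fixed so masks are bit-reproducible): axis order is ``z, y, x``
with 0-based voxel indices; a voxel is foreground iff its intensity is
*strictly greater* than the threshold; the default connectivity for labeling
is 26 (full 3D neighbourhood).
"""

from __future__ import annotations


from dataclasses import dataclass, replace

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import filters as _skfilters
from skimage.measure import label as _sklabel
from skimage.morphology import ball as _ball


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested on a constant (single-valued) plane."""


@dataclass(frozen=True)
class SpatialCalibration:
    """Physical voxel spacing: ``pixel_size_xy`` (µm/px) and ``z_step`` (µm/plane)."""

    pixel_size_xy: float
    z_step: float

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0 and self.z_step > 0):
            raise ValueError(
                "calibration must be strictly positive "
                f"(got pixel_size_xy={self.pixel_size_xy}, z_step={self.z_step})"
            )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.pixel_size_xy * self.pixel_size_xy * self.z_step

    @property
    def spacings_zyx(self) -> tuple[float, float, float]:
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)


@dataclass
class VoxelGrid:
    """A calibrated single-channel intensity stack in ``(z, y, x)`` order."""

    values: np.ndarray
    calibration: SpatialCalibration
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.values.ndim}")
        if self.values.shape[0] < 1:
            raise ValueError("stack must contain at least one plane")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stack intensities must be finite")
        if np.min(self.values) < 0:
            raise ValueError("stack intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_planes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryVolume:
    """A thresholded stack: boolean mask plus the global threshold that produced it."""

    mask: np.ndarray
    calibration: SpatialCalibration
    threshold_used: float = float("nan")
    name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) mask, got ndim={self.mask.ndim}")


@dataclass
class LabeledVolume:
    """Connected components of a binary volume: 0 = background, 1..n = objects."""

    labels: np.ndarray
    n_objects: int
    connectivity: int
    calibration: SpatialCalibration
    name: str = ""

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")


# ---------------------------------------------------------------------------
# I/O


def read_stack(path, calibration: SpatialCalibration, name: str | None = None) -> VoxelGrid:
    """Read a single-channel TIFF/OME-TIFF z-stack into a :class:`VoxelGrid`.

    Multi-sample (e.g. RGB) files are rejected: the pipeline operates on one
    fluorescence channel per file.
    """
    with tifffile.TiffFile(str(path)) as tif:
        spp = tif.pages[0].samplesperpixel
        if spp != 1:
            raise ValueError(
                f"{path}: expected a single-channel stack, found {spp} samples per "
                "pixel; split channels into separate files first"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D image or 3D stack, got shape {arr.shape}")
    return VoxelGrid(values=arr, calibration=calibration, name=name or str(path))


def write_stack(grid: VoxelGrid, path) -> None:
    """Write a :class:`VoxelGrid` to TIFF, preserving dtype and pixel values."""
    tifffile.imwrite(str(path), grid.values)


# ---------------------------------------------------------------------------
# Focus selection

_FOCUS_SCORES = {
    "variance": lambda p: float(np.var(p)),
    # Tenengrad: mean squared Sobel gradient magnitude.
    "tenengrad": lambda p: float(
        np.mean(ndi.sobel(p.astype(np.float64), axis=0) ** 2
                + ndi.sobel(p.astype(np.float64), axis=1) ** 2)
    ),
}


def select_focus_plane(grid: VoxelGrid, method: str = "variance") -> int:
    """Index of the most in-focus plane (maximal focus score; ties -> lowest index)."""
    try:
        score = _FOCUS_SCORES[method]
    except KeyError:
        raise ValueError(f"unknown focus method {method!r}; options: {sorted(_FOCUS_SCORES)}")
    scores = np.array([score(grid.values[k]) for k in range(grid.n_planes)])
    return int(np.argmax(scores))


# ---------------------------------------------------------------------------
# Thresholding

_THRESHOLD_METHODS = {
    "otsu": _skfilters.threshold_otsu,
    "isodata": _skfilters.threshold_isodata,
    "li": _skfilters.threshold_li,
    "mean": _skfilters.threshold_mean,
    "triangle": _skfilters.threshold_triangle,
    "yen": _skfilters.threshold_yen,
}


def auto_threshold(
    grid: VoxelGrid, plane: int | None = None, method: str = "otsu"
) -> BinaryVolume:
    """Global auto-threshold: computed on one plane, applied to the whole stack.

    The threshold is derived from the histogram of the stated plane (default:
    the most in-focus plane) with the chosen method (default Otsu), then every
    voxel of the stack with intensity strictly above it becomes foreground.
    """
    if plane is None:
        plane = select_focus_plane(grid)
    if not (0 <= plane < grid.n_planes):
        raise IndexError(f"plane {plane} out of range for {grid.n_planes}-plane stack")
    try:
        thresh_fn = _THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; options: {sorted(_THRESHOLD_METHODS)}"
        )
    p = grid.values[plane]
    if np.min(p) == np.max(p):
        raise DegenerateHistogramError(
            f"plane {plane} is constant (value {p.flat[0]}); no threshold is computable"
        )
    threshold = float(thresh_fn(p))
    # A histogram-based threshold is only determined up to the empty histogram
    # gap it falls in (the between-class criterion is flat there).  Snap it to
    # the gap midpoint: the partition of the reference plane is unchanged and
    # the choice is canonical when the threshold is propagated to the other
    # planes of the stack.
    below = p[p <= threshold]
    above = p[p > threshold]
    if below.size and above.size:
        threshold = float(below.max() + above.min()) / 2.0
    return BinaryVolume(
        mask=grid.values > threshold,
        calibration=grid.calibration,
        threshold_used=threshold,
        name=grid.name,
    )


# ---------------------------------------------------------------------------
# 3D median filtering


def _ball_footprint(radius: int) -> np.ndarray:
    return _ball(radius).astype(bool)


def median_filter_3d(obj, radius: int = 2):
    """3D median filter over a ball neighbourhood of the given voxel radius.

    Accepts a :class:`BinaryVolume` or a :class:`VoxelGrid` and returns the
    same type.  ``radius=0`` is the identity.  For binary input the median is
    evaluated as a strict-majority vote over the (odd-sized) ball, which is
    exactly the median and considerably faster than a rank filter.  Boundaries
    use reflection.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if isinstance(obj, BinaryVolume):
        if radius == 0:
            return replace(obj, mask=obj.mask.copy())
        fp = _ball_footprint(radius)
        counts = ndi.correlate(obj.mask.astype(np.int32), fp.astype(np.int32), mode="reflect")
        out = counts * 2 > int(fp.sum())
        return replace(obj, mask=out)
    if isinstance(obj, VoxelGrid):
        if radius == 0:
            return replace(obj, values=obj.values.copy())
        fp = _ball_footprint(radius)
        out = ndi.median_filter(obj.values, footprint=fp, mode="reflect")
        return replace(obj, values=out)
    raise TypeError(f"expected BinaryVolume or VoxelGrid, got {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Connected components

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}


def label_objects(mask: BinaryVolume, connectivity: int = 26) -> LabeledVolume:
    """Label disconnected foreground objects at 6/18/26 connectivity (default 26)."""
    if connectivity not in _CONNECTIVITY_TO_SKIMAGE:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labels, n = _sklabel(
        mask.mask, connectivity=_CONNECTIVITY_TO_SKIMAGE[connectivity], return_num=True
    )
    return LabeledVolume(
        labels=labels.astype(np.int32),
        n_objects=int(n),
        connectivity=connectivity,
        calibration=mask.calibration,
        name=mask.name,
    )
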