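"""Per-cell fluorescence accounting for knockdown and reporter assays.

Implements the standard background-corrected intensity bookkeeping used to
score siRNA knockdown and nucleocytoplasmic-transport reporters:

* corrected mean nuclear fluorescence  ``cmnf = mean_nuclear - mean_background``
* corrected total nuclear fluorescence ``ctnf = integrated_density - area * mean_background``
  (integrated density = mean_nuclear * area, i.e. the nuclear pixel sum)
* knockdown inclusion gate: a cell is analysed only if its cmnf is *strictly*
  below a fraction (default 50%) of the control group's mean cmnf, i.e. only
  cells with successful knockdown are kept
* nuclear-to-cytoplasmic ratio
  ``nc_ratio = (mean_nuclear - mean_background) / (mean_cytoplasmic - mean_background)``
  with background-corrected means in both numerator and denominator, which
  makes the ratio invariant to global additive offsets and positive rescaling.

ROIs come from a nuclear-reference (DAPI) image: nuclei by thresholding +
hole filling + size filtering; the cytoplasmic ROI is an annulus obtained by
dilating each nucleus (default 5 px) minus all nuclei; background is
everything outside all dilated cell footprints (with a small extra margin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as _sklabel
from skimage.morphology import disk as _disk


@dataclass
class RegionOfInterest:
    """Pairwise-disjoint nuclear / cytoplasmic / background masks for one cell."""

    cell_id: str
    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        n, c, b = (np.asarray(m, dtype=bool) for m in
                   (self.nuclear_mask, self.cytoplasm_mask, self.background_mask))
        if not n.any():
            raise ValueError(f"{self.cell_id}: nuclear mask is empty")
        if (n & c).any() or (n & b).any() or (c & b).any():
            raise ValueError(f"{self.cell_id}: ROI masks must be pairwise disjoint")
        self.nuclear_mask, self.cytoplasm_mask, self.background_mask = n, c, b


@dataclass
class FluorescenceRecord:
    """Intensity accounting for one cell ROI; identities hold exactly."""

    cell_id: str
    mean_nuclear: float
    integrated_density: float
    area: int
    mean_background: float
    cmnf: float
    ctnf: float
    mean_cytoplasmic: float = float("nan")
    nc_ratio: float = float("nan")


@dataclass
class KnockdownGate:
    """Strict sub-fraction gate on corrected mean nuclear fluorescence."""

    control_mean_cmnf: float
    fraction: float
    included: set


@dataclass(frozen=True)
class RoiParams:
    """ROI construction settings (pixels)."""

    threshold_method: str = "otsu"
    min_nucleus_area: int = 30
    fill_holes: bool = True
    cytoplasm_radius: int = 5
    background_margin: int = 2


def build_rois(dapi_image: np.ndarray, params: RoiParams | None = None) -> list[RegionOfInterest]:
    """Segment nuclei from a nuclear-reference image and derive the three ROIs.

    Returns one ROI per detected nucleus (empty list with a warning if none).
    """
    params = params or RoiParams()
    img = np.asarray(dapi_image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D image")
    if img.min() == img.max():
        warnings.warn("blank nuclear-reference image: no nuclei detected")
        return []
    fg = img > threshold_otsu(img)
    if params.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    labels, n = _sklabel(fg, connectivity=2, return_num=True)
    keep = [
        obj for obj in range(1, n + 1)
        if int(np.sum(labels == obj)) >= params.min_nucleus_area
    ]
    if not keep:
        warnings.warn("no nuclei above the minimum area; returning no ROIs")
        return []
    nuclei = [labels == obj for obj in keep]
    all_nuclei = np.logical_or.reduce(nuclei)
    cyto_se = _disk(params.cytoplasm_radius).astype(bool)
    bg_se = _disk(params.cytoplasm_radius + params.background_margin).astype(bool)
    cell_footprints = ndi.binary_dilation(all_nuclei, structure=bg_se)
    background = ~cell_footprints
    rois = []
    for i, nuc in enumerate(nuclei):
        ring = ndi.binary_dilation(nuc, structure=cyto_se) & ~all_nuclei
        rois.append(
            RegionOfInterest(
                cell_id=f"cell_{i:03d}",
                nuclear_mask=nuc,
                cytoplasm_mask=ring,
                background_mask=background,
            )
        )
    return rois


def corrected_fluorescence(image: np.ndarray, roi: RegionOfInterest) -> FluorescenceRecord:
    """Background-corrected mean and total nuclear fluorescence for one ROI."""
    img = np.asarray(image, dtype=np.float64)
    if img.shape != roi.nuclear_mask.shape:
        raise ValueError("image and ROI masks must share a shape")
    if not roi.background_mask.any():
        raise ValueError(f"{roi.cell_id}: background mask is empty")
    area = int(roi.nuclear_mask.sum())
    mean_nuclear = float(img[roi.nuclear_mask].mean())
    integrated_density = mean_nuclear * area
    mean_background = float(img[roi.background_mask].mean())
    return FluorescenceRecord(
        cell_id=roi.cell_id,
        mean_nuclear=mean_nuclear,
        integrated_density=integrated_density,
        area=area,
        mean_background=mean_background,
        cmnf=mean_nuclear - mean_background,
        ctnf=integrated_density - area * mean_background,
    )


def knockdown_gate(cells, control, fraction: float = 0.5) -> KnockdownGate:
    """Keep cells whose cmnf is strictly below ``fraction`` x mean control cmnf."""
    control = list(control)
    if not control:
        raise ValueError("control population must be non-empty")
    control_mean = float(np.mean([c.cmnf for c in control]))
    if control_mean <= 0:
        raise ValueError(f"control mean cmnf must be positive, got {control_mean}")
    cutoff = fraction * control_mean
    included = {c.cell_id for c in cells if c.cmnf < cutoff}
    return KnockdownGate(control_mean_cmnf=control_mean, fraction=fraction, included=included)


def nc_ratio(image: np.ndarray, roi: RegionOfInterest) -> FluorescenceRecord:
    """Nuclear-to-cytoplasmic ratio of background-corrected mean intensities."""
    if not roi.cytoplasm_mask.any():
        raise ValueError(f"{roi.cell_id}: cytoplasm mask is empty")
    rec = corrected_fluorescence(image, roi)
    img = np.asarray(image, dtype=np.float64)
    mean_cyto = float(img[roi.cytoplasm_mask].mean())
    corrected_cyto = mean_cyto - rec.mean_background
    if corrected_cyto <= 0:
        raise ValueError(
            f"{roi.cell_id}: corrected cytoplasmic mean is {corrected_cyto:.3g} <= 0; "
            "nuclear/cytoplasmic ratio is undefined"
        )
    rec.mean_cytoplasmic = mean_cyto
    rec.nc_ratio = rec.cmnf / corrected_cyto
    return rec
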