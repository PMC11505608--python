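"""Seeded synthetic phantoms: 3D nuclear-envelope stains and 2D reporter scenes.

Every downstream module is testable without real microscopy data.  The 3D
generator emits single-nucleus stacks of an ellipsoidal nuclear-envelope
stain in five phenotype classes, each with a known ground-truth mask and
object count:

* ``ring``         — ellipsoidal shell whose upper dome is dim (a fraction of
  the equatorial intensity), so an ideal threshold keeps a bowl;
* ``diffuse``      — complete shell, dome at full intensity (deep staining in z);
* ``punctate``     — ring-like shell plus disconnected bright interior spots;
* ``invagination`` — ring-like shell plus interior planar sheets attached to
  the envelope (lines of staining through the nucleus);
* ``incomplete``   — envelope missing a large top-centred solid-angle
  fraction, leaving a flat partial bowl that does not surround the nucleus.

Intensities are two-level (background, amplitude) before an optional Gaussian
PSF blur and additive Gaussian read noise; the ground truth is always the
pre-noise geometry.  Defaults emulate a cultured neuronal cell line imaged at
high NA: nuclei ~8-13 µm across, flattened in z, 0.25 µm isotropic sampling.

The 2D generator places non-overlapping cells (bright nucleus disk + dimmer
cytoplasm annulus over a uniform background) together with a matching
DAPI-like nuclear image, recording the true nuclear / cytoplasmic /
background intensities and the true nuclear-to-cytoplasmic ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volio import SpatialCalibration, VoxelGrid, write_stack
from skimage.measure import label as _sklabel

#: Documented "default noise" imaging condition (see docs/methods.md):
#: a 0.25 µm PSF blur plus Gaussian read noise at sd 20 on an amplitude-200
#: signal over background 10 (SNR ~ 10).
DEFAULT_NOISE = {"psf_sigma": 0.25, "noise_sd": 20.0}

#: Composition of one control-group replicate (mostly normal envelopes, ~32
#: cells — within the 30-40 cells/replicate design): the population cascade
#: thresholds are calibrated against.
REFERENCE_CONTROL_MIXTURE = {
    "ring": 18,
    "diffuse": 8,
    "punctate": 2,
    "invagination": 2,
    "incomplete": 2,
}

_PHENOTYPES = ("ring", "diffuse", "punctate", "invagination", "incomplete")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of one synthetic nucleus."""

    phenotype: str
    semi_axes: tuple[float, float, float] = (6.0, 5.0, 4.0)  # a >= b >= c, µm
    shell_thickness: float = 0.8  # µm
    n_spots: int = 10  # punctate
    spot_radius: float = 0.45  # µm
    spot_brightness: float = 1.4  # puncta intensity relative to the shell amplitude
    n_sheets: int = 2  # invagination
    sheet_thickness: float = 1.0  # µm
    gap_fraction: float = 0.6  # incomplete: removed solid-angle fraction (top-centred)
    dome_cos: float = 0.45  # shell voxels with direction cosine above this are "dome"
    dome_intensity_fraction: float = 0.2  # ring-like dome intensity / equatorial
    amplitude: float = 200.0
    background: float = 10.0
    psf_sigma: float = 0.0  # µm, Gaussian PSF; 0 = none
    noise_sd: float = 0.0  # additive Gaussian read noise
    shape: tuple[int, int, int] = (44, 64, 64)  # (z, y, x) voxels
    pixel_size_xy: float = 0.25  # µm
    z_step: float = 0.25  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in _PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if not (0 < self.gap_fraction < 1):
            raise ValueError(f"gap_fraction must be in (0, 1), got {self.gap_fraction}")
        if self.phenotype == "punctate" and self.n_spots < 2:
            raise ValueError("punctate phantoms need n_spots >= 2")
        if self.shell_thickness <= 0 or self.shell_thickness >= c:
            raise ValueError("shell thickness must be positive and smaller than c")

    @property
    def calibration(self) -> SpatialCalibration:
        return SpatialCalibration(pixel_size_xy=self.pixel_size_xy, z_step=self.z_step)


@dataclass
class GroundTruth:
    """Pre-noise truth for one phantom: label, ideal mask, object count."""

    phenotype: str
    mask: np.ndarray  # boolean, ideal-threshold foreground
    n_objects: int
    seed: int


def _coords(spec: PhantomSpec):
    """Physical (x, y, z) coordinate grids centred on the stack centre."""
    nz, ny, nx = spec.shape
    z = (np.arange(nz) - (nz - 1) / 2.0) * spec.z_step
    y = (np.arange(ny) - (ny - 1) / 2.0) * spec.pixel_size_xy
    x = (np.arange(nx) - (nx - 1) / 2.0) * spec.pixel_size_xy
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    return xx, yy, zz


def _inside_ellipsoid(xx, yy, zz, semi_axes) -> np.ndarray:
    a, b, c = semi_axes
    return (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Render one phantom stack; deterministic for a fixed spec (incl. seed)."""
    a, b, c = spec.semi_axes
    nz, ny, nx = spec.shape
    t = spec.shell_thickness
    margin = 2.0 * spec.psf_sigma + max(spec.pixel_size_xy, spec.z_step)
    if (2 * a + 2 * margin > nx * spec.pixel_size_xy
            or 2 * b + 2 * margin > ny * spec.pixel_size_xy
            or 2 * c + 2 * margin > nz * spec.z_step):
        raise ValueError(
            f"ellipsoid {spec.semi_axes} µm does not fit a {spec.shape} stack at "
            f"({spec.pixel_size_xy}, {spec.z_step}) µm spacing"
        )
    rng = np.random.default_rng(spec.seed)
    xx, yy, zz = _coords(spec)
    outer = _inside_ellipsoid(xx, yy, zz, (a, b, c))
    inner = _inside_ellipsoid(xx, yy, zz, (a - t, b - t, c - t))
    shell = outer & ~inner
    # Direction cosine of the voxel relative to the normalised vertical axis.
    rnorm = np.sqrt((xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(rnorm > 0, (zz / c) / np.maximum(rnorm, 1e-12), 0.0)

    img = np.full(spec.shape, spec.background, dtype=np.float64)
    if spec.phenotype == "diffuse":
        img[shell] = spec.amplitude
    elif spec.phenotype in ("ring", "punctate", "invagination"):
        img[shell] = spec.amplitude
        dome = shell & (u > spec.dome_cos)
        img[dome] = spec.background + spec.dome_intensity_fraction * (
            spec.amplitude - spec.background
        )
        if spec.phenotype == "punctate":
            spot_val = spec.background + spec.spot_brightness * (
                spec.amplitude - spec.background
            )
            for cx, cy, cz in _spot_centres(spec, rng):
                spot = ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
                        <= spec.spot_radius ** 2)
                img[spot] = spot_val
        elif spec.phenotype == "invagination":
            phi0 = rng.uniform(0, np.pi)
            for k in range(spec.n_sheets):
                phi = phi0 + k * np.pi / max(spec.n_sheets, 1)
                n_x, n_y = -np.sin(phi), np.cos(phi)
                sheet = (np.abs(n_x * xx + n_y * yy) <= spec.sheet_thickness / 2) & outer
                img[sheet] = spec.amplitude
    elif spec.phenotype == "incomplete":
        # Remove a top-centred cap covering gap_fraction of the solid angle:
        # for a sphere, the cap above direction cosine (1 - 2 g).
        keep = shell & (u <= 1.0 - 2.0 * spec.gap_fraction)
        img[keep] = spec.amplitude

    truth_mask = img >= spec.background + 0.5 * (spec.amplitude - spec.background)
    n_objects = int(_sklabel(truth_mask, connectivity=3, return_num=True)[1])

    if spec.psf_sigma > 0:
        sig = (spec.psf_sigma / spec.z_step,
               spec.psf_sigma / spec.pixel_size_xy,
               spec.psf_sigma / spec.pixel_size_xy)
        img = ndi.gaussian_filter(img, sigma=sig)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None).astype(np.float32)

    grid = VoxelGrid(values=img, calibration=spec.calibration, name=f"{spec.phenotype}:{spec.seed}")
    return grid, GroundTruth(
        phenotype=spec.phenotype, mask=truth_mask, n_objects=n_objects, seed=spec.seed
    )


def _spot_centres(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample interior spot centres: clear of the shell and each other."""
    a, b, c = spec.semi_axes
    t, s = spec.shell_thickness, spec.spot_radius
    shell_gap = 0.7  # µm kept between a spot surface and the envelope interior
    pair_gap = 0.55  # µm kept between spot surfaces
    bounds = (a - t - s - shell_gap, b - t - s - shell_gap, c - t - s - shell_gap)
    if min(bounds) <= 0:
        raise ValueError("spots do not fit inside the nuclear interior")
    min_d2 = (2 * s + pair_gap) ** 2
    for _round in range(40):  # restart with fresh positions if packing stalls
        centres: list[tuple[float, float, float]] = []
        for _ in range(3000):
            if len(centres) == spec.n_spots:
                return centres
            p = rng.uniform(-1, 1, size=3) * bounds
            if (p[0] / bounds[0]) ** 2 + (p[1] / bounds[1]) ** 2 + (p[2] / bounds[2]) ** 2 > 1:
                continue
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2 >= min_d2
                   for q in centres):
                centres.append((float(p[0]), float(p[1]), float(p[2])))
        if len(centres) == spec.n_spots:
            return centres
    raise ValueError(
        f"could not place {spec.n_spots} non-touching spots; reduce n_spots or spot_radius"
    )


# ---------------------------------------------------------------------------
# Populations


def sample_spec(
    phenotype: str,
    rng: np.random.Generator,
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
    **overrides,
) -> PhantomSpec:
    """Draw a jittered per-cell spec around the default geometry.

    Nucleus size varies by an overall ±12% scale with a small independent
    per-axis jitter (±4%), keeping axis *ratios* — which the scale-invariant
    shape features respond to — in a realistic narrow band.
    """
    scale = rng.uniform(0.88, 1.12)
    axes = sorted(
        (6.0 * scale * rng.uniform(0.96, 1.04),
         5.0 * scale * rng.uniform(0.96, 1.04),
         4.0 * scale * rng.uniform(0.96, 1.04)),
        reverse=True,
    )
    params = dict(
        phenotype=phenotype,
        semi_axes=tuple(axes),
        # Envelope thickness tracks nucleus size, so the thickness-to-size
        # ratio (which the scale-invariant moments see) stays in a tight band.
        shell_thickness=float(scale * rng.uniform(0.75, 0.85)),
        n_spots=int(rng.integers(8, 13)),
        n_sheets=int(rng.integers(2, 4)),
        sheet_thickness=float(scale * rng.uniform(0.9, 1.2)),
        gap_fraction=float(rng.uniform(0.55, 0.65)),
        dome_cos=float(rng.uniform(0.4, 0.6)),
        psf_sigma=psf_sigma,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return PhantomSpec(**params)


@dataclass
class PhantomCell:
    cell_id: str
    spec: PhantomSpec
    grid: VoxelGrid
    truth: GroundTruth


def sample_population(
    mixture: dict[str, int],
    seed: int = 0,
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
    **overrides,
) -> list[PhantomCell]:
    """Generate an in-memory seeded population with the requested composition."""
    rng = np.random.default_rng(seed)
    cells: list[PhantomCell] = []
    for phenotype in sorted(mixture):
        count = int(mixture[phenotype])
        if count < 0:
            raise ValueError(f"negative count for {phenotype!r}")
        for i in range(count):
            spec = sample_spec(phenotype, rng, psf_sigma=psf_sigma, noise_sd=noise_sd,
                               **overrides)
            grid, truth = make_phantom(spec)
            cells.append(PhantomCell(f"{phenotype}_{i:03d}", spec, grid, truth))
    return cells


def make_population(
    mixture: dict[str, int],
    out_dir,
    seed: int = 0,
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Write one TIFF stack per cell plus a ground-truth CSV and a spec echo.

    Returns the truth table (cell_id, phenotype, n_objects, seed, file).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = sample_population(mixture, seed=seed, psf_sigma=psf_sigma, noise_sd=noise_sd)
    rows = []
    for cell in cells:
        fname = f"{cell.cell_id}.tif"
        write_stack(cell.grid, out / fname)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "phenotype": cell.truth.phenotype,
                "n_objects": cell.truth.n_objects,
                "seed": cell.truth.seed,
                "file": fname,
            }
        )
    truth = pd.DataFrame(rows, columns=["cell_id", "phenotype", "n_objects", "seed", "file"])
    truth.to_csv(out / "truth.csv", index=False)
    echo = {
        "mixture": {k: int(v) for k, v in sorted(mixture.items())},
        "seed": int(seed),
        "psf_sigma": float(psf_sigma),
        "noise_sd": float(noise_sd),
        "pixel_size_xy": 0.25,
        "z_step": 0.25,
    }
    (out / "population.json").write_text(json.dumps(echo, indent=2) + "\n")
    return truth


# ---------------------------------------------------------------------------
# 2D reporter scenes


@dataclass
class ReporterCellTruth:
    cell_id: str
    centre: tuple[int, int]  # (row, col)
    nucleus_radius: int
    nuclear_intensity: float
    cytoplasmic_intensity: float
    background_intensity: float

    @property
    def nc_ratio(self) -> float:
        return (self.nuclear_intensity - self.background_intensity) / (
            self.cytoplasmic_intensity - self.background_intensity
        )


@dataclass
class ReporterScene:
    image: np.ndarray  # reporter channel
    dapi: np.ndarray  # nuclear reference channel
    cells: list[ReporterCellTruth]
    seed: int


def make_reporter_scene(
    n_cells: int,
    shape: tuple[int, int] = (256, 256),
    nuclear_range: tuple[float, float] = (80.0, 160.0),
    cytoplasmic_range: tuple[float, float] = (20.0, 60.0),
    background: float = 5.0,
    nucleus_radius_range: tuple[int, int] = (8, 12),
    annulus_width: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ReporterScene:
    """Place non-overlapping reporter cells with known intensities.

    Each cell is a nucleus disk at its drawn nuclear intensity surrounded by a
    cytoplasm annulus of ``annulus_width`` pixels at its drawn cytoplasmic
    intensity, over a uniform background.  The matching DAPI image carries
    bright nucleus disks only.  Raises if the requested number of cells cannot
    be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    image = np.full(shape, background, dtype=np.float64)
    dapi = np.full(shape, 10.0, dtype=np.float64)
    rr, cc = np.mgrid[0:h, 0:w]
    placed: list[tuple[int, int, int]] = []
    cells: list[ReporterCellTruth] = []
    pad = 2  # background buffer beyond the annulus
    for i in range(n_cells):
        for attempt in range(3000):
            r = int(rng.integers(nucleus_radius_range[0], nucleus_radius_range[1] + 1))
            extent = r + annulus_width + pad
            cy = int(rng.integers(extent, h - extent))
            cx = int(rng.integers(extent, w - extent))
            if all(
                (cy - py) ** 2 + (cx - px) ** 2
                > (extent + pr + annulus_width + pad) ** 2
                for py, px, pr in placed
            ):
                break
        else:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells in {shape}; "
                "use fewer cells or a larger scene"
            )
        placed.append((cy, cx, r))
        nuc_val = float(rng.uniform(*nuclear_range))
        cyt_val = float(rng.uniform(*cytoplasmic_range))
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        nucleus = d2 <= r**2
        annulus = (d2 > r**2) & (d2 <= (r + annulus_width) ** 2)
        image[nucleus] = nuc_val
        image[annulus] = cyt_val
        dapi[nucleus] = 220.0
        cells.append(
            ReporterCellTruth(
                cell_id=f"cell_{i:03d}",
                centre=(cy, cx),
                nucleus_radius=r,
                nuclear_intensity=nuc_val,
                cytoplasmic_intensity=cyt_val,
                background_intensity=background,
            )
        )
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=shape)
        dapi = dapi + rng.normal(0.0, noise_sd, size=shape)
        image = np.clip(image, 0.0, None)
        dapi = np.clip(dapi, 0.0, None)
    return ReporterScene(image=image, dapi=dapi, cells=cells, seed=seed)
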