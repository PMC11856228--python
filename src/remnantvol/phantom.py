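"""Synthetic neck-thyroid phantom generator.

Produces paired SPECT/CT images emulating a physical neck phantom used to
validate small-volume SPECT/CT volumetry: one or two liquid-filled spheres of
known volume (0.5-10 mL) inside a water-equivalent neck cylinder.

CT: the volume cavities read 1050-1090 HU and the surrounding background
1115-1130 HU on an offset scale with water at 1000 (the downstream
thresholding is invariant to the offset convention).  Those ranges describe
the spread across acquisitions: each realization draws one mean HU per region
uniformly from its range, then adds per-voxel Gaussian CT noise and rounds to
integer HU, as a scanner would -- within one image each homogeneous region is
a tight, peaked cluster.  Voxels cut by a sphere or cylinder surface receive
a fraction-weighted HU computed by sub-voxel supersampling before the noise,
emulating the partial volume effect.

SPECT: an activity-concentration map (spheres at ``activity_conc_volume``
MBq/mL, background cylinder at ``pct_bkg`` percent of that) is voxelized at
SPECT resolution, blurred with an isotropic Gaussian point-spread function
whose FWHM stands in for the isotope/collimator combination, scaled to
expected counts, and Poisson-sampled.  The effective-PSF widths (14 mm for
I-131/HEGP, 9 mm for I-123/LEHR) are package defaults standing in for
post-reconstruction resolution, not measured scanner values; reports should
state them.  No projection/reconstruction, scatter, or attenuation physics is
simulated -- those steps are upstream of the volumetry method.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .grid_model import CorrelatedPair, ImageGrid3D, correlate
from .pipeline import RoiSpec

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Effective post-reconstruction PSF FWHM (mm) per isotope/collimator.
#: Package defaults, configurable; not vendor-measured values.
ISOTOPE_FWHM_MM = {"I-131": 14.0, "I-123": 9.0}


def sphere_radius_mm(volume_ml: float) -> float:
    """Radius (mm) of a sphere of the given volume (mL); V = 4/3 pi r^3."""
    return (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def sphere_diameter_cm(volume_ml: float) -> float:
    """Equivalent spherical diameter in cm (10 mL -> 2.7 cm)."""
    return 2.0 * sphere_radius_mm(volume_ml) / 10.0


@dataclass
class SphereSpec:
    """One phantom sphere: center in world mm, volume in mL, and optionally
    its own activity concentration (MBq/mL; defaults to the phantom-wide
    ``activity_conc_volume`` -- physical acquisitions often fill volumes of
    different sizes to different concentrations)."""

    center_mm: tuple[float, float, float]
    volume_ml: float
    activity_conc: Optional[float] = None

    @property
    def radius_mm(self) -> float:
        return sphere_radius_mm(self.volume_ml)


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic phantom realization.

    Defaults follow the validation conditions of the volumetry study: CT at
    512x512 in-plane with 1.1 x 1.1 mm pixels, SPECT at one quarter the
    in-plane resolution (4.4 mm pixels), shared 4.4 mm slice spacing, cavity
    HU 1050-1090 vs background 1115-1130 (water = 1000), activity
    concentration 0.37 MBq/mL in the volumes and 0/5/10 percent of that in
    the background.
    """

    spheres: Sequence[SphereSpec]
    ct_shape: tuple[int, int, int] = (512, 512, 24)
    ct_spacing: tuple[float, float, float] = (1.1, 1.1, 4.4)
    spect_spacing: tuple[float, float, float] = (4.4, 4.4, 4.4)
    neck_center_mm: Optional[tuple[float, float]] = None
    neck_radius_mm: float = 50.0
    hu_water: float = 1000.0
    hu_volume_range: tuple[float, float] = (1050.0, 1090.0)
    hu_background_range: tuple[float, float] = (1115.0, 1130.0)
    hu_noise_sd: float = 5.0
    hu_integer: bool = True
    activity_conc_volume: float = 0.37  # MBq/mL
    pct_bkg: float = 0.0  # background-to-volume activity-concentration ratio, %
    isotope: str = "I-131"
    psf_fwhm_mm: Optional[float] = None  # default from isotope
    counts_per_mbq: float = 5.0e4
    noise: bool = True
    seed: int = 0
    supersample: int = 3

    def __post_init__(self) -> None:
        self.spheres = [
            s if isinstance(s, SphereSpec) else SphereSpec(tuple(s[0]), float(s[1]))
            for s in self.spheres
        ]
        if self.psf_fwhm_mm is None:
            try:
                self.psf_fwhm_mm = ISOTOPE_FWHM_MM[self.isotope]
            except KeyError:
                raise ValueError(
                    f"unknown isotope {self.isotope!r}; give psf_fwhm_mm explicitly"
                )
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.pct_bkg < 0:
            raise ValueError("pct_bkg must be >= 0")
        if any(s.volume_ml <= 0 for s in self.spheres):
            raise ValueError("sphere volumes must be > 0")
        fx = self.spect_spacing[0] / self.ct_spacing[0]
        if abs(fx - round(fx)) > 1e-9 or self.ct_shape[0] % round(fx) or self.ct_shape[1] % round(fx):
            raise ValueError("ct_shape must be divisible by the SPECT/CT spacing ratio")
        if self.neck_center_mm is None:
            self.neck_center_mm = (
                (self.ct_shape[0] - 1) / 2.0 * self.ct_spacing[0],
                (self.ct_shape[1] - 1) / 2.0 * self.ct_spacing[1],
            )
        self._validate_geometry()

    # -- derived geometry ----------------------------------------------------

    @property
    def replication_factor(self) -> int:
        return round(self.spect_spacing[0] / self.ct_spacing[0])

    @property
    def spect_shape(self) -> tuple[int, int, int]:
        f = self.replication_factor
        return (self.ct_shape[0] // f, self.ct_shape[1] // f, self.ct_shape[2])

    @property
    def ct_origin(self) -> tuple[float, float, float]:
        return (0.0, 0.0, 0.0)

    @property
    def spect_origin(self) -> tuple[float, float, float]:
        # Sub-pixel block centers of the replicated SPECT coincide with CT
        # voxel centers; zero alignment shift by construction.
        f = self.replication_factor
        return (
            (f - 1) / 2.0 * self.ct_spacing[0],
            (f - 1) / 2.0 * self.ct_spacing[1],
            0.0,
        )

    def grid_center_mm(self) -> tuple[float, float, float]:
        return (
            (self.ct_shape[0] - 1) / 2.0 * self.ct_spacing[0],
            (self.ct_shape[1] - 1) / 2.0 * self.ct_spacing[1],
            (self.ct_shape[2] - 1) / 2.0 * self.ct_spacing[2],
        )

    def surface_separations_mm(self) -> list[float]:
        """Pairwise surface-to-surface separations between spheres."""
        out = []
        for i in range(len(self.spheres)):
            for j in range(i + 1, len(self.spheres)):
                a, b = self.spheres[i], self.spheres[j]
                d = float(np.linalg.norm(np.subtract(a.center_mm, b.center_mm)))
                out.append(d - a.radius_mm - b.radius_mm)
        return out

    def _validate_geometry(self) -> None:
        cx, cy = self.neck_center_mm
        z_extent = self.ct_shape[2] * self.ct_spacing[2]
        for s in self.spheres:
            r = s.radius_mm
            radial = math.hypot(s.center_mm[0] - cx, s.center_mm[1] - cy)
            if radial + r > self.neck_radius_mm:
                raise GeometryError(
                    f"sphere at {s.center_mm} (r={r:.1f} mm) exits the neck "
                    f"cylinder (radius {self.neck_radius_mm} mm)"
                )
            if s.center_mm[2] - r < -self.ct_spacing[2] / 2 or s.center_mm[2] + r > z_extent:
                raise GeometryError(f"sphere at {s.center_mm} exits the axial extent")
        for sep in self.surface_separations_mm():
            if sep < 0:
                raise GeometryError(f"spheres overlap (surface separation {sep:.1f} mm)")


# -- supersampled voxelization ----------------------------------------------


def _subcenter_coords(n: int, origin: float, spacing: float, lo: int, hi: int, ss: int):
    """World coords of ss sub-centers per voxel for indices lo..hi inclusive."""
    idx = np.arange(lo, hi + 1)
    off = (np.arange(ss) + 0.5) / ss - 0.5
    return origin + (idx[:, None] + off[None, :]) * spacing  # (n_vox, ss)


def sphere_fractions(
    origin: Sequence[float],
    spacing: Sequence[float],
    shape: Sequence[int],
    sphere: SphereSpec,
    supersample: int = 3,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Inside-sphere fraction per voxel over the sphere's bounding box.

    Each voxel is subdivided into ``supersample**3`` sub-voxels; the fraction
    is the share of sub-voxel centers inside the sphere.
    """
    ss = supersample
    lo, hi = [], []
    for a in range(3):
        l = int(np.floor((sphere.center_mm[a] - sphere.radius_mm - origin[a]) / spacing[a])) - 1
        h = int(np.ceil((sphere.center_mm[a] + sphere.radius_mm - origin[a]) / spacing[a])) + 1
        lo.append(max(l, 0))
        hi.append(min(h, shape[a] - 1))
    if any(hi[a] < lo[a] for a in range(3)):
        box = tuple(slice(lo[a], lo[a]) for a in range(3))
        return box, np.zeros((0, 0, 0))
    xs = _subcenter_coords(shape[0], origin[0], spacing[0], lo[0], hi[0], ss)
    ys = _subcenter_coords(shape[1], origin[1], spacing[1], lo[1], hi[1], ss)
    zs = _subcenter_coords(shape[2], origin[2], spacing[2], lo[2], hi[2], ss)
    dx2 = (xs - sphere.center_mm[0]) ** 2  # (nx, ss)
    dy2 = (ys - sphere.center_mm[1]) ** 2
    dz2 = (zs - sphere.center_mm[2]) ** 2
    r2 = sphere.radius_mm**2
    inside = (
        dx2[:, :, None, None, None, None]
        + dy2[None, None, :, :, None, None]
        + dz2[None, None, None, None, :, :]
    ) <= r2
    frac = inside.mean(axis=(1, 3, 5))
    box = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
    return box, frac


def cylinder_fractions_2d(
    origin: Sequence[float],
    spacing: Sequence[float],
    shape: Sequence[int],
    center_mm: Sequence[float],
    radius_mm: float,
    supersample: int = 3,
) -> np.ndarray:
    """In-plane inside-cylinder fraction per (x, y) pixel (axis along z)."""
    ss = supersample
    xs = _subcenter_coords(shape[0], origin[0], spacing[0], 0, shape[0] - 1, ss)
    ys = _subcenter_coords(shape[1], origin[1], spacing[1], 0, shape[1] - 1, ss)
    dx2 = (xs - center_mm[0]) ** 2
    dy2 = (ys - center_mm[1]) ** 2
    inside = (
        dx2[:, :, None, None] + dy2[None, None, :, :]
    ) <= radius_mm**2
    return inside.mean(axis=(1, 3))


# -- generators --------------------------------------------------------------


def generate_ct(spec: PhantomSpec) -> ImageGrid3D:
    """CT volume: water outside the neck cylinder, background tissue inside,
    cavity HU inside the spheres, fraction-weighted HU at every boundary.

    One mean HU per region is drawn uniformly from the configured range (all
    cavities share a mean: they are filled from the same solution); per-voxel
    Gaussian noise of ``hu_noise_sd`` is added after the partial-volume
    mixing, and values are rounded to integer HU if ``hu_integer``.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 11])
    shape = spec.ct_shape
    cavity_mean = float(rng.uniform(*spec.hu_volume_range))
    bg_mean = float(rng.uniform(*spec.hu_background_range))
    hu = np.full(shape, spec.hu_water, dtype=float)
    frac_cyl = cylinder_fractions_2d(
        spec.ct_origin, spec.ct_spacing, shape, spec.neck_center_mm,
        spec.neck_radius_mm, spec.supersample,
    )
    hu = hu * (1.0 - frac_cyl[:, :, None]) + bg_mean * frac_cyl[:, :, None]
    for sphere in spec.spheres:
        box, frac = sphere_fractions(
            spec.ct_origin, spec.ct_spacing, shape, sphere, spec.supersample
        )
        hu[box] = frac * cavity_mean + (1.0 - frac) * hu[box]
    if spec.hu_noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=shape)
    if spec.hu_integer:
        hu = np.round(hu)
    return ImageGrid3D(hu, spec.ct_spacing, spec.ct_origin, "CT")


def generate_spect(spec: PhantomSpec) -> ImageGrid3D:
    """SPECT volume: voxelized activity, Gaussian spillover, Poisson noise.

    Expected counts = activity(MBq per voxel) x counts_per_mbq, blurred with
    a sum-preserving isotropic Gaussian of FWHM ``psf_fwhm_mm``.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 22])
    shape = spec.spect_shape
    spacing = spec.spect_spacing
    origin = spec.spect_origin
    vox_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0

    frac_cyl = cylinder_fractions_2d(
        origin, spacing, shape, spec.neck_center_mm, spec.neck_radius_mm,
        spec.supersample,
    )
    frac_spheres = np.zeros(shape, dtype=float)
    conc_spheres = np.zeros(shape, dtype=float)
    for sphere in spec.spheres:
        box, frac = sphere_fractions(origin, spacing, shape, sphere, spec.supersample)
        frac_spheres[box] += frac
        conc = (
            sphere.activity_conc
            if sphere.activity_conc is not None
            else spec.activity_conc_volume
        )
        conc_spheres[box] += conc * frac
    frac_spheres = np.clip(frac_spheres, 0.0, 1.0)
    frac_bg = np.clip(frac_cyl[:, :, None] - frac_spheres, 0.0, 1.0)

    # The background is filled to pct_bkg percent of the phantom-wide volume
    # concentration (the background-to-volume activity-concentration ratio).
    activity_mbq = vox_ml * (
        conc_spheres
        + (spec.pct_bkg / 100.0) * spec.activity_conc_volume * frac_bg
    )
    expected = activity_mbq * spec.counts_per_mbq
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spacing]
        expected = ndimage.gaussian_filter(
            expected, sigma=sigma_vox, mode="constant", truncate=6.0
        )
    counts = rng.poisson(expected).astype(float) if spec.noise else expected
    return ImageGrid3D(counts, spacing, origin, "SPECT")


@dataclass
class PhantomTruth:
    """Ground truth accompanying one generated pair."""

    spheres: list[SphereSpec]
    voxelized_volumes_ml: list[float]
    surface_separations_mm: list[float]
    rois_single: list[RoiSpec]
    roi_combined: RoiSpec
    seed: int
    psf_fwhm_mm: float
    isotope: str
    pct_bkg: float

    def truth_records(self) -> list[tuple[tuple[float, float, float], float]]:
        """(center_mm, volume_ml) pairs for pipeline truth matching."""
        return [(s.center_mm, s.volume_ml) for s in self.spheres]

    def to_dict(self) -> dict:
        return {
            "spheres": [
                {"center_mm": list(s.center_mm), "volume_ml": s.volume_ml,
                 "radius_mm": s.radius_mm}
                for s in self.spheres
            ],
            "voxelized_volumes_ml": [round(v, 4) for v in self.voxelized_volumes_ml],
            "surface_separations_mm": [round(d, 2) for d in self.surface_separations_mm],
            "rois_single": [r.to_dict() for r in self.rois_single],
            "roi_combined": self.roi_combined.to_dict(),
            "seed": self.seed,
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "isotope": self.isotope,
            "pct_bkg": self.pct_bkg,
        }


def _sphere_roi_bounds(
    spec: PhantomSpec, spheres: Sequence[SphereSpec], margin_mm: float
) -> tuple[float, float, float, float, int, int]:
    dx, dy, dz = spec.ct_spacing
    nx, ny, nz = spec.ct_shape
    x0 = min(s.center_mm[0] - s.radius_mm for s in spheres) - margin_mm
    x1 = max(s.center_mm[0] + s.radius_mm for s in spheres) + margin_mm
    y0 = min(s.center_mm[1] - s.radius_mm for s in spheres) - margin_mm
    y1 = max(s.center_mm[1] + s.radius_mm for s in spheres) + margin_mm
    # Slices on which a sphere is observed: slice center within r + dz/2.
    z0 = min(
        int(np.ceil((s.center_mm[2] - s.radius_mm - dz / 2) / dz)) for s in spheres
    )
    z1 = max(
        int(np.floor((s.center_mm[2] + s.radius_mm + dz / 2) / dz)) for s in spheres
    )
    ix0 = max(x0 / dx, 0.0)
    ix1 = min(x1 / dx, nx - 1.0)
    iy0 = max(y0 / dy, 0.0)
    iy1 = min(y1 / dy, ny - 1.0)
    return ix0, iy0, ix1, iy1, max(z0, 0), min(z1, nz - 1)


def default_rois(spec: PhantomSpec, margin_mm: Optional[float] = None) -> tuple[list[RoiSpec], RoiSpec]:
    """Per-sphere and combined box ROIs around the high-uptake regions.

    The in-plane margin defaults to 1.5x the PSF FWHM so that spillover and
    surrounding background are enclosed, as a user would draw it.  The
    combined ROI is grown, if necessary, to at least twice the area of the
    largest single-sphere ROI (two-volume ROIs are drawn generously).
    """
    if margin_mm is None:
        margin_mm = max(8.0, 1.5 * spec.psf_fwhm_mm)
    singles = []
    for i, s in enumerate(spec.spheres):
        ix0, iy0, ix1, iy1, z0, z1 = _sphere_roi_bounds(spec, [s], margin_mm)
        # A user drawing around one volume keeps the ROI on this side of any
        # neighboring volume: clamp at the midline between sphere surfaces
        # along the dominant separation axis.
        for j, other in enumerate(spec.spheres):
            if j == i:
                continue
            delta = np.subtract(other.center_mm[:2], s.center_mm[:2])
            axis = int(np.argmax(np.abs(delta)))
            d = spec.ct_spacing[axis]
            mid = 0.5 * (
                s.center_mm[axis] + s.radius_mm + other.center_mm[axis] - other.radius_mm
            ) if delta[axis] > 0 else 0.5 * (
                s.center_mm[axis] - s.radius_mm + other.center_mm[axis] + other.radius_mm
            )
            if axis == 0:
                ix0, ix1 = (ix0, min(ix1, mid / d)) if delta[axis] > 0 else (max(ix0, mid / d), ix1)
            else:
                iy0, iy1 = (iy0, min(iy1, mid / d)) if delta[axis] > 0 else (max(iy0, mid / d), iy1)
        singles.append(RoiSpec.from_box(ix0, iy0, ix1, iy1, z0, z1))
    ix0, iy0, ix1, iy1, z0, z1 = _sphere_roi_bounds(spec, spec.spheres, margin_mm)
    max_single_area = max(
        (r.polygon[:, 0].max() - r.polygon[:, 0].min())
        * (r.polygon[:, 1].max() - r.polygon[:, 1].min())
        for r in singles
    )
    area = (ix1 - ix0 + 1) * (iy1 - iy0 + 1)
    if area < 2.0 * max_single_area:
        grow = math.sqrt(2.0 * max_single_area / ((ix1 - ix0) * (iy1 - iy0)))
        cx, cy = (ix0 + ix1) / 2.0, (iy0 + iy1) / 2.0
        hx, hy = grow * (ix1 - ix0) / 2.0, grow * (iy1 - iy0) / 2.0
        nx, ny = spec.ct_shape[0], spec.ct_shape[1]
        ix0, ix1 = max(cx - hx, 0.0), min(cx + hx, nx - 1.0)
        iy0, iy1 = max(cy - hy, 0.0), min(cy + hy, ny - 1.0)
    combined = RoiSpec.from_box(ix0, iy0, ix1, iy1, z0, z1)
    return singles, combined


def generate_pair(spec: PhantomSpec) -> tuple[CorrelatedPair, PhantomTruth]:
    """Generate CT + SPECT, correlate them, and return ground truth."""
    ct = generate_ct(spec)
    spect = generate_spect(spec)
    pair = correlate(spect, ct)
    voxelized = []
    vox_ml = ct.voxel_volume_ml
    for s in spec.spheres:
        _, frac = sphere_fractions(
            spec.ct_origin, spec.ct_spacing, spec.ct_shape, s, spec.supersample
        )
        voxelized.append(float(frac.sum()) * vox_ml)
    singles, combined = default_rois(spec)
    truth = PhantomTruth(
        spheres=list(spec.spheres),
        voxelized_volumes_ml=voxelized,
        surface_separations_mm=spec.surface_separations_mm(),
        rois_single=singles,
        roi_combined=combined,
        seed=spec.seed,
        psf_fwhm_mm=spec.psf_fwhm_mm,
        isotope=spec.isotope,
        pct_bkg=spec.pct_bkg,
    )
    return pair, truth
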