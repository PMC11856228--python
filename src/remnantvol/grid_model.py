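"""Image containers and SPECT-to-CT grid correlation.

A reconstructed SPECT study (typically 128x128 in-plane, ~4.4 mm pixels) and
its companion CT (512x512, ~1.1 mm pixels) live on different lattices.  Before
any thresholding, the SPECT matrix is *block-replicated* onto the CT in-plane
lattice -- each native SPECT pixel becomes factor x factor sub-pixels carrying
the identical uptake value (no interpolation, counts-per-unit-area preserved in
shape, total counts scale by factor^2) -- and then aligned with an integer
circular shift derived from the world origins of the two series.  The result
is a voxel-to-voxel correlated pair: every SPECT voxel corresponds to exactly
one CT voxel of 1.1 x 1.1 x 4.4 mm.

Only integer shifts are applied; sub-voxel residual offsets are reported, never
interpolated away, so uptake values are preserved bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import MissingGeometry, NonIntegerFactor, ShapeMismatch

logger = logging.getLogger(__name__)

_MODALITIES = ("SPECT", "CT")

#: Relative tolerance for deciding that a spacing ratio is an integer.
SPACING_RTOL = 1e-6

#: Fraction of the axis extent beyond which a circular shift is suspicious
#: (wraparound would carry anatomy across the field of view).
WRAP_WARN_FRACTION = 0.10


@dataclass
class ImageGrid3D:
    """A 3D scalar field (SPECT counts or CT HU) on a regular lattice.

    Values are indexed ``(x, y, z)``; the world position of voxel-center
    ``(i, j, k)`` is ``origin + (i*dx, j*dy, k*dz)``.

    Parameters
    ----------
    values
        3D array; counts (>= 0) for SPECT, Hounsfield units for CT.  An
        offset HU convention (water = 1000) is accepted: all downstream
        thresholding is invariant to a constant HU shift.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    modality
        Either ``"SPECT"`` or ``"CT"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "SPECT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        self.modality = str(self.modality).upper()
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")
        if self.modality == "SPECT" and np.any(self.values < 0):
            raise ValueError("SPECT counts must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def world_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def with_values(self, values: np.ndarray, **overrides) -> "ImageGrid3D":
        kw = dict(spacing=self.spacing, origin=self.origin, modality=self.modality)
        kw.update(overrides)
        return ImageGrid3D(values, **kw)


@dataclass
class AlignmentShift:
    """Integer voxel shift between two series plus the sub-voxel remainder."""

    shift: tuple[int, int, int]
    residual_mm: tuple[float, float, float]


@dataclass
class CorrelatedPair:
    """SPECT resampled and aligned onto the CT lattice.

    After correlation every SPECT voxel corresponds to one CT voxel; both
    grids share shape and spacing (the "elementary voxel", by default
    1.1 x 1.1 x 4.4 mm).
    """

    spect: ImageGrid3D
    ct: ImageGrid3D
    replication_factor: int
    applied_shift: tuple[int, int, int] = (0, 0, 0)
    residual_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spect.shape != self.ct.shape:
            raise ShapeMismatch(
                f"correlated shapes differ: {self.spect.shape} vs {self.ct.shape}"
            )
        if not np.allclose(self.spect.spacing, self.ct.spacing, rtol=SPACING_RTOL):
            raise ShapeMismatch(
                f"correlated spacings differ: {self.spect.spacing} vs {self.ct.spacing}"
            )
        if self.replication_factor < 1:
            raise ValueError("replication_factor must be a positive integer")


def _integer_factor(coarse: float, fine: float) -> int:
    ratio = coarse / fine
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > SPACING_RTOL * max(1.0, abs(ratio)):
        raise NonIntegerFactor(
            f"spacing ratio {coarse}/{fine} = {ratio} is not an integer"
        )
    return int(factor)


def resample_spect_to_ct(spect: ImageGrid3D, ct: ImageGrid3D) -> ImageGrid3D:
    """Block-replicate the SPECT matrix onto the CT in-plane lattice.

    Each native SPECT pixel of size ``factor*dx_ct x factor*dy_ct`` is copied
    into ``factor x factor`` sub-pixels, all carrying the same uptake value
    (for the standard 4.4 mm -> 1.1 mm case, 16 sub-pixels per pixel).  The
    sum of values therefore scales exactly by ``factor**2``.

    Raises
    ------
    NonIntegerFactor
        If an in-plane spacing ratio is not an integer within tolerance.
    ShapeMismatch
        If z spacings differ or the replicated extent does not match the CT.
    """
    fx = _integer_factor(spect.spacing[0], ct.spacing[0])
    fy = _integer_factor(spect.spacing[1], ct.spacing[1])
    if fx != fy:
        raise NonIntegerFactor(
            f"anisotropic in-plane replication factors ({fx}, {fy}) not supported"
        )
    if abs(spect.spacing[2] - ct.spacing[2]) > SPACING_RTOL * ct.spacing[2]:
        raise ShapeMismatch(
            f"z spacings differ: SPECT dz={spect.spacing[2]}, CT dz={ct.spacing[2]}"
            " (resample the CT onto the SPECT z lattice first)"
        )
    values = np.repeat(np.repeat(spect.values, fx, axis=0), fy, axis=1)
    if values.shape != ct.shape:
        raise ShapeMismatch(
            f"replicated SPECT shape {values.shape} does not cover CT shape {ct.shape}"
        )
    # The block of sub-pixel centers is symmetric about the native pixel
    # center, so the first sub-pixel center sits (factor-1)/2 fine pixels
    # before the native center.
    origin = (
        spect.origin[0] - (fx - 1) / 2.0 * ct.spacing[0],
        spect.origin[1] - (fy - 1) / 2.0 * ct.spacing[1],
        spect.origin[2],
    )
    return ImageGrid3D(values, ct.spacing, origin, "SPECT")


def _round_half_away(x: float) -> int:
    """Round half away from zero (bit-stable across platforms)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def _origin_of(record) -> Sequence[float]:
    origin = getattr(record, "origin", None)
    if origin is None and isinstance(record, dict):
        origin = record.get("origin")
    if origin is None:
        raise MissingGeometry(f"record {record!r} lacks an origin")
    origin = tuple(float(v) for v in origin)
    if len(origin) != 3:
        raise MissingGeometry(f"origin must have 3 components, got {origin}")
    return origin


def compute_alignment_shift(spect_meta, ct_meta, spacing) -> AlignmentShift:
    """Integer voxel shift that best explains the world-origin offset.

    Per axis the shift minimizes ``|offset - shift*spacing|`` where
    ``offset = spect_origin - ct_origin`` (rounding half away from zero);
    the sub-voxel residual is reported, not corrected.
    """
    if spacing is None or any(s <= 0 for s in spacing):
        raise MissingGeometry(f"invalid spacing {spacing}")
    s_origin = _origin_of(spect_meta)
    c_origin = _origin_of(ct_meta)
    shift = []
    residual = []
    for axis in range(3):
        offset = s_origin[axis] - c_origin[axis]
        n = _round_half_away(offset / spacing[axis])
        shift.append(n)
        residual.append(offset - n * spacing[axis])
    return AlignmentShift(tuple(shift), tuple(residual))


def apply_circular_shift(grid: ImageGrid3D, shift: Sequence[int]) -> ImageGrid3D:
    """Circularly shift the grid values per axis (shape/spacing preserved).

    ``out[i] = in[i - shift]`` with wraparound; shifting an axis by its own
    length is the identity.  The multiset of values is conserved.
    """
    shift = tuple(int(s) for s in shift)
    if len(shift) != 3:
        raise ValueError("shift must have 3 components")
    for axis, (s, n) in enumerate(zip(shift, grid.shape)):
        if 0 < n and abs(s % n if s >= 0 else -((-s) % n)) > WRAP_WARN_FRACTION * n:
            logger.warning(
                "circular shift %d on axis %d exceeds %.0f%% of extent %d; "
                "wraparound may carry anatomy across the field of view",
                s, axis, 100 * WRAP_WARN_FRACTION, n,
            )
    values = np.roll(grid.values, shift, axis=(0, 1, 2))
    return grid.with_values(values)


def resample_ct_axial(
    ct: ImageGrid3D, z_origin: float, dz: float, nz: int
) -> ImageGrid3D:
    """Nearest-slice resampling of the CT onto a target z lattice.

    CT series are often acquired at a different slice thickness (e.g. 5 mm)
    than the SPECT (4.4 mm); the correlated pair uses the SPECT z lattice, so
    each target slice takes the nearest acquired CT slice.  No interpolation.
    """
    if dz <= 0 or nz < 1:
        raise ValueError("target lattice must have dz > 0 and nz >= 1")
    z_world = z_origin + np.arange(nz) * dz
    src = np.round((z_world - ct.origin[2]) / ct.spacing[2]).astype(int)
    if src.min() < 0 or src.max() >= ct.shape[2]:
        raise ShapeMismatch(
            "target z lattice extends beyond the CT axial extent "
            f"(source slices {src.min()}..{src.max()} of {ct.shape[2]})"
        )
    values = ct.values[:, :, src]
    return ImageGrid3D(
        values,
        (ct.spacing[0], ct.spacing[1], dz),
        (ct.origin[0], ct.origin[1], z_origin),
        ct.modality,
    )


def correlate(spect: ImageGrid3D, ct: ImageGrid3D) -> CorrelatedPair:
    """Produce a voxel-to-voxel correlated SPECT/CT pair.

    Steps: (1) if the CT z lattice differs from the SPECT one, reassign CT
    slices to the SPECT z lattice by nearest neighbor; (2) block-replicate the
    SPECT in-plane onto the CT lattice; (3) apply the integer circular shift
    derived from the world origins.  The returned SPECT grid inherits the CT
    origin; the sub-voxel residual is recorded on the pair.
    """
    if abs(ct.spacing[2] - spect.spacing[2]) > SPACING_RTOL * spect.spacing[2] or (
        ct.shape[2] != spect.shape[2]
    ):
        nz = spect.shape[2]
        # Choose the CT slice lattice that covers the SPECT extent.
        ct = resample_ct_axial(ct, spect.origin[2], spect.spacing[2], nz)
    resampled = resample_spect_to_ct(spect, ct)
    alignment = compute_alignment_shift(resampled, ct, ct.spacing)
    aligned = apply_circular_shift(resampled, alignment.shift)
    aligned = aligned.with_values(aligned.values, origin=ct.origin)
    factor = _integer_factor(spect.spacing[0], ct.spacing[0])
    logger.info(
        "correlated SPECT onto CT lattice: factor=%d shift=%s residual=%s mm",
        factor, alignment.shift, tuple(round(r, 3) for r in alignment.residual_mm),
    )
    return CorrelatedPair(
        spect=aligned,
        ct=ct,
        replication_factor=factor,
        applied_shift=alignment.shift,
        residual_mm=alignment.residual_mm,
    )
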