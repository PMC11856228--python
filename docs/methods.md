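# Methods

## The volumetry procedure

`remnantvol` sizes small hot volumes from a correlated SPECT/CT pair by
applying a gray-level-histogram (GLH) threshold twice.

**Correlation.** The SPECT matrix is resampled onto the CT in-plane lattice by
block replication: with 4.4 mm SPECT pixels and 1.1 mm CT pixels each pixel
becomes 4×4 = 16 sub-pixels carrying the unchanged uptake value. No
interpolation is performed anywhere: replication preserves values exactly (the
array total scales by the factor squared), and alignment uses only integer
circular shifts computed from the world origins, rounding half away from zero;
sub-voxel residuals are reported but never resampled away. When the CT was
acquired at a different slice thickness, its slices are first reassigned to
the SPECT z lattice by nearest neighbor, so the correlated elementary voxel is
1.1 × 1.1 × 4.4 mm. A shift larger than 10% of an axis is logged as a
wraparound warning.

**First pass (SPECT).** Otsu's threshold — the exhaustive maximizer of the
between-class variance over candidate thresholds — is computed from the uptake
values inside the user VOI (ROI polygon rasterized by a voxel-center-in-polygon
test, extruded over the inclusive slice range; the middle slice of an even
range is the floor midpoint). Candidates are the sorted distinct values when
there are ≤ 4096 of them, otherwise 256-bin histogram midpoints; both paths
are verified against a brute-force oracle. Ties take the smallest qualifying
threshold. Voxels strictly above threshold form the SPECT mask. The selection
is invariant under adding a constant to all values and equivariant under
positive scaling, so the HU offset convention (water at 0 or at 1000) and the
count scale are immaterial.

**Second pass (CT).** The HU values inside the SPECT mask are split into two
"similar HU regions" by a second Otsu pass. The region on the configured
polarity side (default `lower`: a colloid/water-filled cavity reads below the
soft-tissue surround) is selected, and its minimum-to-maximum HU range becomes
the inclusive classification band. The default percentiles are (0, 100);
inner percentiles (e.g. 2.5/97.5) can be configured to trim outliers in noisy
clinical data, at the cost of a deliberate negative bias — a count-based trim
always discards that fraction of the region's voxels. The band and the
selected class mean are logged and serialized so the decision is auditable.

**Volume splitting.** Distinct volumes are the 3D connected components
(default 26-connectivity, components under 2 voxels dropped) of the **CT**
mask. This choice matters: at ~1 cm separations under I-131-like blur the
SPECT masks of neighboring volumes merge into one component, while their CT
masks remain separate. Each CT component is mapped back to the SPECT component
containing it; when two volumes share one SPECT component the shared
`V_SPECT` is reported for both and flagged (`spect_component_shared`), making
the per-volume ratio R an upper bound in that case. Separations clearly below
1 cm remain a limitation: the merged SPECT mask can also defeat the CT split
when the gap voxels' HU resembles the cavities'.

**Reporting.** Volumes are voxel counts times the elementary voxel volume
(5.324 mm³ = 5.324×10⁻³ mL), printed at 3 decimals. `%ΔV` uses the actual
volume as denominator; `%ΔV₁₋₂ = 100(V₂ − V₁)/V₁` uses the one-volume-ROI
estimate V₁ (this convention reproduces the standard published pairs, e.g.
(1.621, 1.655) → 2.1%). Repeated calculations are summarized as mean ±
sample SD (n − 1). `run_repeated` emulates the manual-ROI variability by
rescaling the polygon about its centroid by a uniform factor in ±10%.

## The synthetic phantom

The generator emulates an anthropomorphic neck phantom: a water-equivalent
cylinder (default radius 50 mm) holding one or two spheres of known volume,
with volume converted to radius by r = (3V/4π)^⅓.

*CT.* Each realization draws one mean HU per tissue class — cavity mean
uniform in 1050–1090 HU, background mean in 1115–1130 HU (offset scale, water
= 1000); both cavities share a mean since they are filled from the same
solution. Voxels cut by a surface get a fraction-weighted HU from 3×3×3
sub-voxel supersampling (27 sub-samples), then per-voxel Gaussian noise
(default SD 5 HU, a low-dose soft-tissue figure) is added and values are
rounded to integer HU as a scanner would. The stated ranges therefore
describe the spread *across* realizations; within one image each homogeneous
region is a tight, peaked cluster, which is what makes a histogram split
meaningful at a 25–80 HU class distance. Making every voxel independently
uniform across the full 40-HU range would instead hand Otsu a broad class it
prefers to split internally, and no threshold method could work on such data.

*SPECT.* An activity map (each sphere at its own concentration, default
0.37 MBq/mL; background at `pct_bkg` percent of the phantom-wide volume
concentration) is voxelized at SPECT resolution with the same supersampling,
convolved with an isotropic Gaussian point-spread function, scaled by
`counts_per_mbq` (default 5×10⁴, giving cavity voxels on the order of 10³
counts), and Poisson-sampled. The effective FWHM stands in for the whole
post-reconstruction resolution of an isotope/collimator combination —
defaults 14 mm for I-131/HEGP and 9 mm for I-123/LEHR. These widths are
package defaults, not measured scanner values, and reports should state them.
Per-sphere concentrations matter for mixed phantoms: diagnostic fills give a
0.5 mL volume roughly 3× the concentration of a 10 mL one, and without that
a small sphere next to a large one falls below the SPECT threshold entirely.

A `generate_pair` call returns the correlated pair plus ground truth: nominal
and voxelized sphere volumes, surface separations, per-sphere box ROIs (with
an in-plane margin of 1.5× FWHM, clamped at the midline toward any neighbor,
as a user would draw them) and a combined ROI grown to at least twice the
area of the largest single ROI. All randomness flows from a single integer
seed; identical seeds reproduce arrays bit-for-bit.

### What the phantom does *not* emulate

No projection/reconstruction chain (OSEM artifacts, reconstruction speckle),
no scatter or attenuation physics, no septal penetration tails, no dead time.
Consequences, verified by measurement:

- Real I-131 images show larger spillover masks (R ≈ 2.4 for 10 mL) than a
  clean Gaussian produces here (R ≈ 1.4, partly because the VOI slice range
  caps axial growth). Since the CT pass sees exactly the voxels the SPECT
  mask supplies, its residual bias tracks that mask's background fraction:
  the emulation underestimates a grid-centered isolated 10 mL sphere by
  ≈ 2–3% where physical acquisitions reach ≈ 1.2–1.4%. Small volumes
  (0.5 mL), dominated by partial-volume error, agree well (≈ 9–12% here vs
  ≈ 15–16% physically).
- An adaptive threshold is shift- and scale-invariant, so a uniform
  background pedestal or a global activity change cancels out of the
  classification in the deterministic limit. The emulated `V_SPECT` is
  therefore *flat* in the background ratio and only weakly (and not
  monotonically — threshold hopping between discrete count levels) dependent
  on administered activity, whereas physical acquisitions show clear
  increases driven by count-rate and scatter effects outside this model.
  `V_SPECT-CT`, the method's actual output, is insensitive to both knobs here
  exactly as it is physically.

Passing tests on this phantom therefore validate the correlation,
thresholding, splitting, and reporting machinery and the CT pass's
insensitivity to activity conditions; they do not certify accuracy on real
reconstructed data, where the SPECT-side texture differs.

## Numerical choices

- Spacing-ratio integrality tolerance 1e-6 (relative); alignment rounding
  half away from zero, documented for bit-stability.
- Otsu: exact candidates ≤ 4096 distinct values, else 256 bins; first-maximum
  (smallest-threshold) tie-break; between-class variance computed with
  probability weights.
- Percentiles: linear interpolation between order statistics.
- Point-in-polygon: shapely `intersects_xy` (boundary-inclusive) on voxel
  centers; polygons must be simple with positive area.
- Degenerate inputs raise typed errors (`DegenerateHistogram` for a uniform
  VOI, `EmptyRoi`, `GeometryError` for overlapping/escaping spheres, ...)
  rather than returning sentinel values.
- Problem sizes: the bundled tests and the acceptance script run on reduced
  fields of view (e.g. 128–160 px in-plane CT covering the neck) at the
  native voxel sizes; the geometry, HU classes, activities, and PSF widths
  are unchanged, and the pipeline is resolution-agnostic up to the stated
  integer spacing ratio.
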