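# remnantvol

Small-volume (≥ 0.5 mL) volumetry for co-registered SPECT/CT, aimed at
postsurgical thyroid imaging: measuring thyroid remnants and small iodine-avid
lesions from I-131 or I-123 SPECT with its companion low-dose CT, without any
additional modality.

## The problem and the method

SPECT alone cannot size sub-10-mL objects: counts from a hot volume spill into
neighboring voxels (radiation spillover), and the coarse lattice (4.4 mm
pixels) adds a large partial volume effect. `remnantvol` implements a
successive *gray-level-histogram* (GLH) procedure that removes the spillover
by handing the final decision to the CT:

1. **Correlate.** The SPECT matrix (128×128, 4.4 mm pixels) is
   block-replicated onto the CT in-plane lattice — each pixel becomes 4×4
   sub-pixels with the identical uptake value — and aligned by an integer
   circular shift derived from the DICOM world origins. Every SPECT voxel now
   corresponds to one CT voxel of 1.1 × 1.1 × 4.4 mm.
2. **VOI.** The user draws an ROI around the high-uptake region on the fused
   middle slice and picks the first/last slices on which the volume is seen;
   the ROI is extruded over that slice range.
3. **GLH on SPECT.** Otsu's criterion — the threshold `t` maximizing the
   between-class variance `σ_b²(t) = w₀w₁(μ₀ − μ₁)²` of the two-class split —
   is applied to the uptake values inside the VOI. Voxels strictly above the
   threshold form the SPECT mask, and
   `V_SPECT = N_vox × (1.1 × 1.1 × 4.4 mm³)`.
4. **GLH on CT.** The HU distribution inside that mask is split into two
   similar-HU regions by a second Otsu pass; the volume-side region's
   minimum-to-maximum range (optionally inner percentiles) becomes an
   adaptive HU band, and voxels whose HU falls inside it form the final,
   spillover-free estimate `V_SPECT-CT`.
5. **Split & report.** Distinct volumes are separated as 3D connected
   components of the CT mask; the report carries per-volume `V_SPECT`,
   `V_SPECT-CT`, the ratio `R = V_SPECT / V_SPECT-CT ≥ 1`, and, when ground
   truth is known, `%ΔV = 100·|V_SPECT-CT − V|/V`.

The package also ships a **synthetic neck–thyroid phantom generator**
(`remnantvol.phantom`): spheres of known volume (0.5–10 mL) in a
water-equivalent neck cylinder, two-tissue CT with partial-volume boundary
mixing (cavities ~1050–1090 HU, background ~1115–1130 HU on a water = 1000
offset scale), isotope-dependent Gaussian spillover (effective FWHM 14 mm for
I-131/HEGP, 9 mm for I-123/LEHR), Poisson counting noise, and configurable
background-to-volume activity ratios — so the entire pipeline is testable
with no external data.

## Worked example

```sh
python examples/segment_two_volumes.py
```

builds a phantom with 1.5 and 3 mL spheres 1 cm apart (I-131-like blur,
Poisson noise), runs the pipeline with one ROI around both, and prints:

```
SPECT threshold: 178.0 counts
adaptive HU band: [1063, 1098]
 true (mL)  V_SPECT  V_SPECT-CT      R    %dV
       1.5   16.696       1.480  11.28    1.3
       3.0   16.696       3.109   5.37    3.6
```

Reading: the SPECT-only mask is inflated several-fold by spillover (here the
two spheres' masks even merge into one 16.7 mL component, so both rows show
the shared `V_SPECT`), while the CT-refined volumes land within a few percent
of the true 1.5 and 3 mL. The other scripts in `examples/` demonstrate the
phantom generator, the insensitivity of `V_SPECT-CT` to background activity,
and the metric conventions.

A thin CLI wraps the same library:

```sh
remnantvol simulate --config phantom.yaml --out sim/
remnantvol segment --spect sim/spect.npz --ct sim/ct.npz \
    --roi roi.json --truth sim/truth.json --out seg/
remnantvol report --in seg/
```

Input images may be DICOM series directories, NIfTI files, or NPZ archives.

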